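"""Recombination-rate assignment, rate classes, and diversity correlations.

Recombination rates (cM/Mb) come from two independent testcrosses estimated
over ordered chromosome segments; where both maps cover a position the
average of the two rates is used.  Sites are binned into 0.25-cM/Mb-wide
classes up to 6 cM/Mb plus an open top class, and per-class or per-segment
Watterson theta and F_op are compared with rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import watterson_theta


@dataclass
class RecombinationMap:
    """Ordered non-overlapping segments with per-testcross rates.

    ``segments`` columns: chrom, start, end, rate_a, rate_b (either may be
    NaN where a testcross does not cover the segment).  Physical intervals
    are half-open (start, end] to mirror the upper-closed rate classes.
    """

    segments: pd.DataFrame

    REQUIRED = ("chrom", "start", "end", "rate_a", "rate_b")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.segments.columns)
        if missing:
            raise ValueError(f"map missing columns: {sorted(missing)}")
        seg = self.segments.sort_values(["chrom", "start"]).reset_index(drop=True)
        for _, grp in seg.groupby("chrom"):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError("overlapping segments within a chromosome")
        if "segment_id" not in seg.columns:
            seg["segment_id"] = [f"seg{i:04d}" for i in range(len(seg))]
        self.segments = seg

    def averaged_rate(self) -> pd.Series:
        """Mean of the two testcross rates; NaN unless both maps cover."""
        return (self.segments["rate_a"] + self.segments["rate_b"]) / 2.0

    @classmethod
    def from_tsv(cls, path) -> "RecombinationMap":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.segments.to_csv(path, sep="\t", index=False)


def assign_rate(
    positions,
    rmap: RecombinationMap,
    chrom: str | None = None,
    allow_single_map: bool = False,
) -> pd.DataFrame:
    """Segment id and rate for each position; NaN where unmapped.

    Positions falling in no segment, or in a segment covered by only one
    testcross (unless ``allow_single_map``), are flagged rate-missing (NaN).
    Boundary positions belong to the lower segment ((start, end] convention).
    """
    seg = rmap.segments
    if chrom is not None:
        seg = seg[seg["chrom"] == chrom]
    seg = seg.sort_values("start")
    starts = seg["start"].to_numpy()
    ends = seg["end"].to_numpy()
    avg = ((seg["rate_a"] + seg["rate_b"]) / 2.0).to_numpy()
    single = np.where(
        np.isnan(seg["rate_a"].to_numpy()), seg["rate_b"].to_numpy(), seg["rate_a"].to_numpy()
    )
    ids = seg["segment_id"].to_numpy()
    pos = np.asarray(positions)
    idx = np.searchsorted(starts, pos, side="left") - 1
    # position p belongs to segment i iff starts[i] < p <= ends[i]
    idx = np.where((idx >= 0) & (pos > starts.take(idx, mode="clip")) &
                   (pos <= ends.take(idx, mode="clip")), idx, -1)
    rate = np.full(pos.shape, np.nan)
    segid = np.full(pos.shape, None, dtype=object)
    ok = idx >= 0
    rate[ok] = avg[idx[ok]]
    segid[ok] = ids[idx[ok]]
    if allow_single_map:
        fallback = ok & np.isnan(rate)
        rate[fallback] = single[idx[fallback]]
    return pd.DataFrame({"position": pos, "segment_id": segid, "rate": rate})


def bin_rate_classes(rates, width: float = 0.25, top: float = 6.0) -> pd.Series:
    """Rate-class index for each rate: (0, .25], (.25, .5], ..., plus >top.

    Class 0 is closed at 0 ([0, 0.25]); the final class collects all rates
    above ``top``.  With the defaults this yields 25 classes (0..24).
    Negative rates raise; NaN rates map to -1 (unassigned).
    """
    r = np.asarray(rates, dtype=float)
    if np.nanmin(r) < 0 if r.size else False:
        raise ValueError("negative recombination rate")
    n_regular = int(round(top / width))
    cls = np.ceil(r / width).astype(float) - 1
    cls = np.where(r == 0.0, 0, cls)
    cls = np.where(r > top, n_regular, cls)
    cls = np.where(np.isnan(r), -1, cls)
    return pd.Series(cls.astype(int), name="rate_class")


def rate_class_label(cls: int, width: float = 0.25, top: float = 6.0) -> str:
    n_regular = int(round(top / width))
    if cls == n_regular:
        return f">{top:.2f}"
    lo, hi = cls * width, (cls + 1) * width
    return f"{lo:.2f}-{hi:.2f}"


def class_summaries(
    sites: pd.DataFrame,
    totals: pd.DataFrame,
    k: int = 11,
    width: float = 0.25,
    top: float = 6.0,
) -> pd.DataFrame:
    """Per-rate-class theta_W (and F_op when available).

    ``sites`` needs columns ``rate`` (cM/Mb) and, optionally, ``preferred``
    (0/1 for the derived codon) for a class-level F_op over polymorphic
    codons.  ``totals`` maps each rate class to its resolved site total L
    (columns ``rate_class``, ``L``).  Empty classes are omitted.
    """
    sites = sites.dropna(subset=["rate"]).copy()
    sites["rate_class"] = bin_rate_classes(sites["rate"], width, top).to_numpy()
    s_by_class = sites.groupby("rate_class").size()
    rows = []
    for _, row in totals.iterrows():
        cls = int(row["rate_class"])
        L = float(row["L"])
        if L <= 0:
            continue
        S = int(s_by_class.get(cls, 0))
        entry = {
            "rate_class": cls,
            "label": rate_class_label(cls, width, top),
            "upper_rate": (cls + 1) * width if cls < int(round(top / width)) else top + width,
            "S": S,
            "L": L,
            "theta_w_per_bp": watterson_theta(S, L, k),
        }
        if "preferred" in sites.columns:
            grp = sites[sites["rate_class"] == cls]
            entry["fop"] = float(grp["preferred"].mean()) if len(grp) else np.nan
        rows.append(entry)
    return pd.DataFrame(rows)


def correlate(x, y, tail: int = 1) -> tuple[float, int, float]:
    """Pearson r with df = n-2 and a t-transform p-value.

    ``tail`` 1 gives the one-tailed p for the observed sign of r; 2 the
    two-tailed p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p_two = stats.pearsonr(x, y)
    p = p_two / 2 if tail == 1 else p_two
    return float(r), x.size - 2, float(p)


def segment_summaries(
    sites: pd.DataFrame,
    totals: pd.DataFrame,
    rmap: RecombinationMap,
    k: int = 11,
    min_sites: float = 5000,
) -> pd.DataFrame:
    """Per-segment theta_W and F_op, with a ``well_sampled`` >= min_sites flag.

    ``totals`` maps segment_id to resolved site total L.  Segments outside
    the rate maps (flanking regions) are retained with NaN rate.
    """
    s_by_seg = sites.dropna(subset=["segment_id"]).groupby("segment_id").size()
    fop_by_seg = (
        sites.dropna(subset=["segment_id"]).groupby("segment_id")["preferred"].mean()
        if "preferred" in sites.columns
        else pd.Series(dtype=float)
    )
    avg = dict(zip(rmap.segments["segment_id"], rmap.averaged_rate()))
    rows = []
    for _, row in totals.iterrows():
        seg = row["segment_id"]
        L = float(row["L"])
        if L <= 0:
            continue
        S = int(s_by_seg.get(seg, 0))
        rows.append(
            {
                "segment_id": seg,
                "rate": avg.get(seg, np.nan),
                "S": S,
                "L": L,
                "theta_w_per_bp": watterson_theta(S, L, k),
                "fop": float(fop_by_seg.get(seg, np.nan)),
                "well_sampled": L >= min_sites,
            }
        )
    return pd.DataFrame(rows)


def plot_rate_relationships(class_summary: pd.DataFrame, path) -> None:
    """Diversity and codon bias against the rate-class upper bound."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ncols = 2 if "fop" in class_summary.columns else 1
    fig, axes = plt.subplots(1, ncols, figsize=(5 * ncols, 4), squeeze=False)
    ax = axes[0][0]
    ax.plot(class_summary["upper_rate"], class_summary["theta_w_per_bp"], "o-")
    ax.set_xlabel("recombination rate (cM/Mb, class upper bound)")
    ax.set_ylabel(r"Watterson $\theta$ / bp")
    if ncols == 2:
        ax2 = axes[0][1]
        ax2.plot(class_summary["upper_rate"], class_summary["fop"], "o-")
        ax2.set_xlabel("recombination rate (cM/Mb, class upper bound)")
        ax2.set_ylabel(r"$F_{op}$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
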