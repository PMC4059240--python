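"""Watterson's theta and outgroup divergence per site, summarized by class.

Synonymous site totals L are fractional (degeneracy-weighted); intron totals
count each site as one full site, so intron estimates are systematically
diluted relative to synonymous ones when constraint differs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .neutral import harmonic


@dataclass
class DiversitySummary:
    label: str
    S: int
    L: float
    theta_w: float
    D_count: int | None = None
    D_per_site: float | None = None


def watterson_theta(S: int, L: float, k: int = 11) -> float:
    """theta_W = S / (a_k * L), per site."""
    if L <= 0:
        raise ValueError("site total L must be positive")
    if S < 0:
        raise ValueError("segregating-site count S must be >= 0")
    return S / (harmonic(k) * L)


def divergence_per_site(D_count: int, L: float) -> float:
    if L <= 0:
        raise ValueError("site total L must be positive")
    return D_count / L


def summarize_by_class(
    sites: pd.DataFrame,
    totals: pd.DataFrame,
    class_key: str,
    k: int = 11,
) -> list[DiversitySummary]:
    """One DiversitySummary per level of ``class_key``.

    ``sites`` is the site table (one row per biallelic polymorphic site) and
    ``totals`` carries one row per class level with columns ``L`` (resolved
    site total, fractional for synonymous classes) and optionally
    ``D_count`` (divergent sites).  Classes present in ``totals`` but with no
    polymorphic sites get S = 0; classes with no resolved sites are omitted.
    """
    if class_key not in totals.columns:
        raise KeyError(f"totals has no column {class_key!r}")
    s_counts = (
        sites.groupby(class_key).size() if class_key in sites.columns else pd.Series(dtype=int)
    )
    out: list[DiversitySummary] = []
    for _, row in totals.iterrows():
        label = row[class_key]
        L = float(row["L"])
        if L <= 0:
            continue
        S = int(s_counts.get(label, 0))
        D_count = int(row["D_count"]) if "D_count" in totals.columns else None
        out.append(
            DiversitySummary(
                label=str(label),
                S=S,
                L=L,
                theta_w=watterson_theta(S, L, k),
                D_count=D_count,
                D_per_site=divergence_per_site(D_count, L) if D_count is not None else None,
            )
        )
    return out


def summaries_to_frame(summaries: list[DiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": [s.label for s in summaries],
            "S": [s.S for s in summaries],
            "L": [s.L for s in summaries],
            "theta_w_per_bp": [s.theta_w for s in summaries],
            "D_count": [s.D_count for s in summaries],
            "D_per_bp": [s.D_per_site for s in summaries],
        }
    )
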