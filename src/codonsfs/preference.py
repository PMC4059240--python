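"""Inference of preferred codons by factor analysis on per-gene codon usage.

Each gene contributes a row of within-amino-acid relative codon usage over the
59 degenerate codons.  The primary factor of that matrix separates genes by
how strongly their usage is skewed toward a shared set of codons; it is
polarized so that per-gene factor scores correlate positively with the scaled
chi-square (Chi/L) and negatively with the effective number of codons (ENC),
both measures of uneven usage.  A codon's preference score is its loading on
the polarized factor, and codons with positive loadings are "preferred".

Delta-pref of a polymorphic site is score(derived) - score(ancestral); sites
with positive delta-pref are unpreferred-to-preferred (U->P) changes and
sites with negative delta-pref are P->U.

A table of published preference scores for D. pseudoobscura chromosome 2 is
bundled (``load_reference_scores``) so downstream analyses can run with fixed
scores instead of re-inferred ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .genetic_code import (
    CodonError,
    DEGENERACY,
    DEGENERATE_AMINO_ACIDS,
    DEGENERATE_CODONS,
    SYNONYMS,
    amino_acid,
)

# Degeneracy classes entering the ENC formula: 9 twofold, 1 threefold (Ile),
# 5 fourfold, 3 sixfold amino acids.
_ENC_CLASS_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass
class GeneUsageProfile:
    """Per-gene codon usage over the 59 degenerate codons."""

    gene: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(DEGENERATE_CODONS)
        if unknown:
            raise CodonError(f"non-degenerate or unknown codons in profile: {unknown}")

    def amino_acid_counts(self) -> dict[str, int]:
        out = {aa: 0 for aa in DEGENERATE_AMINO_ACIDS}
        for codon, n in self.counts.items():
            out[amino_acid(codon)] += n
        return out

    def uses_all_amino_acids(self) -> bool:
        return all(n > 0 for n in self.amino_acid_counts().values())

    def relative_usage(self) -> np.ndarray:
        """Within-amino-acid relative usage, ordered as DEGENERATE_CODONS.

        Codons of amino acids absent from the gene get NaN (genes entering
        the factor analysis are required to use all 18 amino acids, so this
        only matters for excluded genes).
        """
        aa_counts = self.amino_acid_counts()
        rel = np.empty(len(DEGENERATE_CODONS))
        for i, codon in enumerate(DEGENERATE_CODONS):
            tot = aa_counts[amino_acid(codon)]
            rel[i] = self.counts.get(codon, 0) / tot if tot > 0 else np.nan
        return rel

    @property
    def L(self) -> int:
        """Total number of degenerate-amino-acid codons in the gene."""
        return sum(self.counts.values())


def enc(profile: GeneUsageProfile) -> float:
    """Effective number of codons, from class-averaged codon homozygosities.

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 where F_c is the mean within-amino-
    acid homozygosity (sum of squared relative usages) over amino acids of
    degeneracy c.  Perfectly even usage gives 61; one codon per amino acid
    gives 20.  Amino acids with zero count are skipped and the class weight
    renormalized; a class with no usable amino acid falls back to the even-
    usage homozygosity 1/c.
    """
    aa_counts = profile.amino_acid_counts()
    value = 2.0  # Met + Trp
    for deg, n_aa in _ENC_CLASS_WEIGHTS.items():
        homs = []
        for aa in DEGENERATE_AMINO_ACIDS:
            if DEGENERACY[aa] != deg:
                continue
            tot = aa_counts[aa]
            if tot == 0:
                continue
            p = np.array([profile.counts.get(c, 0) / tot for c in SYNONYMS[aa]])
            homs.append(float((p**2).sum()))
        F = float(np.mean(homs)) if homs else 1.0 / deg
        value += n_aa / F
    return value


def scaled_chi(profile: GeneUsageProfile) -> float:
    """Chi/L: per-codon chi-square of observed vs. even within-amino-acid usage.

    Chi = sum over degenerate codons of (obs - exp)^2 / exp with
    exp = amino-acid count / degeneracy, divided by the number L of codons
    of degenerate amino acids in the gene.
    """
    L = profile.L
    if L == 0:
        raise ValueError("gene has no degenerate codons")
    aa_counts = profile.amino_acid_counts()
    chi = 0.0
    for aa in DEGENERATE_AMINO_ACIDS:
        tot = aa_counts[aa]
        if tot == 0:
            continue
        expected = tot / DEGENERACY[aa]
        for codon in SYNONYMS[aa]:
            obs = profile.counts.get(codon, 0)
            chi += (obs - expected) ** 2 / expected
    return chi / L


@dataclass
class PreferenceTable:
    """Signed per-codon preference scores; positive = preferred."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(DEGENERATE_CODONS) - set(self.scores)
        if missing:
            raise CodonError(f"preference table missing codons: {sorted(missing)}")

    def score(self, codon: str) -> float:
        codon = codon.upper()
        if codon not in self.scores:
            raise CodonError(f"{codon} is not a degenerate sense codon")
        return self.scores[codon]

    def preferred(self, codon: str) -> bool:
        return self.score(codon) > 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "amino_acid": amino_acid(c),
                "score": self.scores[c],
                "preferred": self.scores[c] > 0,
            }
            for c in DEGENERATE_CODONS
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PreferenceTable":
        return cls(scores=dict(zip(df["codon"].str.upper(), df["score"].astype(float))))

    @classmethod
    def from_tsv(cls, path) -> "PreferenceTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def load_reference_scores() -> PreferenceTable:
    """Bundled published preference scores for D. pseudoobscura chromosome 2."""
    with resources.files("codonsfs.data").joinpath("dpse_preference_scores.tsv").open() as fh:
        return PreferenceTable.from_frame(pd.read_csv(fh, sep="\t"))


class PolarizationError(RuntimeError):
    """The two codon-bias anchors disagree about the factor's sign."""


def infer_preference_table(
    profiles: list[GeneUsageProfile],
    method: str = "pca",
) -> PreferenceTable:
    """First-factor loadings of the genes x 59 relative-usage matrix.

    Genes must use all 18 degenerate amino acids.  The matrix of within-
    amino-acid relative usages is column-standardized and its first
    principal component extracted (``method="pca"``, the default and only
    extraction currently implemented); loadings are the correlations between
    per-gene component scores and each codon's relative usage, so the two
    codons of a twofold amino acid always load with equal magnitude and
    opposite sign.  The factor is polarized so gene scores correlate
    positively with Chi/L and negatively with ENC; if the two anchors
    disagree a PolarizationError is raised with both correlations.
    """
    if method != "pca":
        raise ValueError(f"unknown extraction method {method!r}")
    usable = [p for p in profiles if p.uses_all_amino_acids()]
    if len(usable) < 2:
        raise ValueError(
            "need >= 2 genes using all 18 degenerate amino acids "
            f"(got {len(usable)})"
        )
    X = np.vstack([p.relative_usage() for p in usable])
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    informative = sd > 0
    if not informative.any():
        raise ValueError("all codon-usage columns are constant; no factor to extract")
    Z = (X[:, informative] - mu[informative]) / sd[informative]
    # First principal component of the standardized matrix.
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    scores = Z @ vt[0]

    chi = np.array([scaled_chi(p) for p in usable])
    encs = np.array([enc(p) for p in usable])
    r_chi = _safe_corr(scores, chi)
    r_enc = _safe_corr(scores, encs)
    if r_chi == 0.0 and r_enc == 0.0:
        raise PolarizationError("factor scores uncorrelated with both anchors")
    if r_chi * r_enc > 0:
        raise PolarizationError(
            f"polarization anchors disagree: corr(score, Chi/L)={r_chi:.3f}, "
            f"corr(score, ENC)={r_enc:.3f}"
        )
    sign = 1.0 if (r_chi > 0 or r_enc < 0) else -1.0
    scores = sign * scores

    # Loadings as correlations of each (informative) column with the scores.
    loadings = np.zeros(X.shape[1])
    zs = (scores - scores.mean()) / scores.std(ddof=0)
    loadings[informative] = (Z * zs[:, None]).mean(axis=0)
    return PreferenceTable(scores=dict(zip(DEGENERATE_CODONS, loadings)))


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def fop(profile: GeneUsageProfile, table: PreferenceTable) -> float:
    """Frequency of optimal codons: preferred / all degenerate-aa codons."""
    L = profile.L
    if L == 0:
        raise ValueError("gene has no degenerate codons")
    preferred = sum(n for c, n in profile.counts.items() if table.preferred(c))
    return preferred / L


def delta_pref(ancestral: str, derived: str, table: PreferenceTable) -> float:
    """score(derived) - score(ancestral) for a synonymous codon pair."""
    if amino_acid(ancestral) != amino_acid(derived):
        raise CodonError(f"{ancestral}->{derived} is not synonymous")
    return table.score(derived) - table.score(ancestral)


def direction_label(dpref: float) -> str:
    """"U->P" for positive delta-pref, "P->U" for negative, "none" for zero."""
    if dpref > 0:
        return "U->P"
    if dpref < 0:
        return "P->U"
    return "none"
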