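"""Gene/site inclusion filters, biallelic site calling, and polarization.

The unit of data is a per-gene alignment of k ingroup sequences (reference
strain first) plus one outgroup sequence, with per-base phred consensus
quality and coverage for the non-reference ingroup strains.  Bases failing
quality >= 30 or coverage >= 15 are treated as unresolved; a codon (all three
positions) or intron site enters the analysis only if fully resolved in all
k + 1 sequences.  Synonymous polymorphic sites are codons at which the
ingroup segregates exactly two synonymous codons differing at one position;
polarity (ancestral vs. derived) is assigned by parsimony against the
outgroup base at the varying position.

Coordinates are 0-based half-open internally; the site table reports 1-based
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_code import (
    CODON_TABLE,
    CodonError,
    DEGENERACY,
    START_CODON,
    STOP_CODONS,
    amino_acid,
    classify_pair,
    synonymous_site_count,
)
from .preference import PreferenceTable, direction_label

_UNRESOLVED = "N"
_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

QUALITY_MIN = 30
COVERAGE_MIN = 15


@dataclass
class GeneModel:
    """CDS and intron blocks of one gene, in gene-local coordinates."""

    gene: str
    strand: str
    cds_blocks: list[tuple[int, int]]
    intron_blocks: list[tuple[int, int]] = field(default_factory=list)
    chrom: str = "chr2"
    chrom_start: int = 0

    def coding_length(self) -> int:
        return sum(e - s for s, e in self.cds_blocks)

    def coding_sequence(self, seq: str) -> str:
        cds = "".join(seq[s:e] for s, e in self.cds_blocks)
        if self.strand == "-":
            cds = cds.translate(_COMPLEMENT)[::-1]
        return cds

    def coding_positions(self) -> np.ndarray:
        pos = np.concatenate(
            [np.arange(s, e) for s, e in self.cds_blocks]
        ) if self.cds_blocks else np.array([], dtype=int)
        return pos[::-1] if self.strand == "-" else pos


@dataclass
class StrainAlignment:
    """Aligned sequences of one gene: k ingroup strains plus one outgroup.

    ``ingroup`` holds the reference strain first.  ``quality`` and
    ``coverage`` are (k-1, L) arrays for the non-reference strains, aligned
    to sequence coordinates; the reference strain carries no mask.
    """

    gene: str
    names: list[str]
    ingroup: list[str]
    outgroup: str
    quality: np.ndarray | None = None
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        L = len(self.ingroup[0])
        if any(len(s) != L for s in self.ingroup) or len(self.outgroup) != L:
            raise ValueError(f"{self.gene}: unequal sequence lengths")
        n_nonref = len(self.ingroup) - 1
        for arr, what in ((self.quality, "quality"), (self.coverage, "coverage")):
            if arr is not None and arr.shape != (n_nonref, L):
                raise ValueError(f"{self.gene}: {what} mask shape {arr.shape} != ({n_nonref}, {L})")

    @property
    def k(self) -> int:
        return len(self.ingroup)


def validate_gene(model: GeneModel, ref_seq: str) -> tuple[bool, str]:
    """Apply the gene inclusion filters to the reference sequence.

    Excluded if: start codon is not ATG; stop codon not in {TAA, TAG, TGA};
    any codon incompletely resolved; an in-frame premature stop; or intron
    boundaries that are not GT..AG.  Returns (include, reason).
    """
    L = len(ref_seq)
    for s, e in model.cds_blocks + model.intron_blocks:
        if not (0 <= s < e <= L):
            raise ValueError(f"{model.gene}: block ({s}, {e}) outside sequence of length {L}")
    cds = model.coding_sequence(ref_seq)
    if len(cds) % 3 != 0:
        return False, "frame"
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons[0] != START_CODON:
        return False, "start"
    if codons[-1] not in STOP_CODONS:
        return False, "stop"
    for codon in codons[:-1]:
        if not set(codon) <= _DNA:
            return False, "unresolved codon"
        if codon in STOP_CODONS:
            return False, "premature stop"
    for s, e in model.intron_blocks:
        intron = ref_seq[s:e]
        if model.strand == "-":
            intron = intron.translate(_COMPLEMENT)[::-1]
        if not (intron.startswith("GT") and intron.endswith("AG")):
            return False, "noncanonical intron"
    return True, "ok"


def apply_masks(
    aln: StrainAlignment,
    quality_min: int = QUALITY_MIN,
    coverage_min: int = COVERAGE_MIN,
) -> StrainAlignment:
    """Blank bases failing the quality/coverage thresholds to 'N'.

    Thresholds are strict "below" cutoffs: quality 30 / coverage 15 are
    kept.  The reference strain (first ingroup sequence) is never masked;
    a strain with no mask data is treated as entirely unresolved.
    """
    masked = [aln.ingroup[0]]
    L = len(aln.ingroup[0])
    for i, seq in enumerate(aln.ingroup[1:]):
        if aln.quality is None or aln.coverage is None:
            masked.append(_UNRESOLVED * L)
            continue
        bad = (aln.quality[i] < quality_min) | (aln.coverage[i] < coverage_min)
        if bad.any():
            chars = np.frombuffer(seq.encode(), dtype="S1").copy()
            chars[bad] = b"N"
            masked.append(chars.tobytes().decode())
        else:
            masked.append(seq)
    return StrainAlignment(
        gene=aln.gene,
        names=aln.names,
        ingroup=masked,
        outgroup=aln.outgroup,
        quality=aln.quality,
        coverage=aln.coverage,
    )


def polarize(states: list[str], outgroup_state: str) -> tuple[str, str, int]:
    """Parsimony polarization of a biallelic column.

    ``states`` are the per-ingroup-sequence alleles (two distinct values);
    the outgroup state must equal one of them, which becomes the ancestral
    state.  Returns (ancestral, derived, derived count d).
    """
    alleles = sorted(set(states))
    if len(alleles) != 2:
        raise ValueError(f"expected 2 segregating states, got {alleles}")
    if outgroup_state not in alleles:
        raise ValueError("unpolarizable: outgroup matches neither state")
    ancestral = outgroup_state
    derived = alleles[0] if alleles[1] == ancestral else alleles[1]
    d = sum(1 for s in states if s == derived)
    return ancestral, derived, d


@dataclass
class CallResult:
    """Site calls plus the resolved-site accounting for one gene."""

    sites: pd.DataFrame
    totals: pd.DataFrame  # columns: class, L, D_count
    dropped: pd.DataFrame  # columns: gene, position, site_type, reason
    codon_counts: pd.DataFrame | None = None  # columns: codon, count (resolved, by reference codon)


_SITE_COLUMNS = [
    "gene", "position", "chrom_position", "site_type", "amino_acid",
    "ancestral", "derived", "anc_base", "der_base", "d", "delta_pref",
    "direction", "pair", "pair_subclass", "preferred", "intron_len",
    "intron_pos",
]


def call_sites(
    aln: StrainAlignment,
    model: GeneModel,
    table: PreferenceTable | None = None,
) -> CallResult:
    """Call biallelic synonymous and intron polymorphic sites for one gene.

    Returns the per-site table, per-class resolved totals (fractional
    synonymous L per amino acid and overall, integer intron L) with
    reference-vs-outgroup divergence counts, and a log of dropped columns.
    """
    coding = [model.coding_sequence(s) for s in aln.ingroup]
    coding_out = model.coding_sequence(aln.outgroup)
    coding_pos = model.coding_positions()
    if len(coding[0]) % 3 != 0:
        raise ValueError(f"{model.gene}: coding length not a multiple of 3")
    n_codons = len(coding[0]) // 3

    rows: list[dict] = []
    drops: list[dict] = []
    L_syn = 0.0
    D_syn = 0
    aa_L: dict[str, float] = {}
    aa_D: dict[str, int] = {}
    codon_counts: dict[str, int] = {}

    for ci in range(n_codons - 1):  # skip the stop codon
        lo = 3 * ci
        codons = [s[lo:lo + 3] for s in coding]
        out_codon = coding_out[lo:lo + 3]
        if any(not set(c) <= _DNA for c in codons) or not set(out_codon) <= _DNA:
            continue  # not fully resolved in all k+1 sequences
        ref_codon = codons[0]
        if ref_codon in STOP_CODONS:
            raise ValueError(f"{model.gene}: in-frame stop at codon {ci}")
        ssc = synonymous_site_count(ref_codon)
        L_syn += ssc
        codon_counts[ref_codon] = codon_counts.get(ref_codon, 0) + 1
        aa = amino_acid(ref_codon)
        if DEGENERACY[aa] > 1:
            aa_L[aa] = aa_L.get(aa, 0.0) + ssc
        # Divergence: reference vs. outgroup, synonymous single-position.
        if out_codon != ref_codon and out_codon not in STOP_CODONS:
            ndiff = sum(a != b for a, b in zip(ref_codon, out_codon))
            if ndiff == 1 and CODON_TABLE.get(out_codon) == aa:
                D_syn += 1
                aa_D[aa] = aa_D.get(aa, 0) + 1
        distinct = sorted(set(codons))
        if len(distinct) == 1:
            continue
        if len(distinct) > 2:
            drops.append({"gene": model.gene, "position": ci, "site_type": "synonymous",
                          "reason": "multiallelic"})
            continue
        c1, c2 = distinct
        diffs = [i for i in range(3) if c1[i] != c2[i]]
        if CODON_TABLE[c1] != CODON_TABLE[c2]:
            drops.append({"gene": model.gene, "position": ci, "site_type": "synonymous",
                          "reason": "nonsynonymous"})
            continue
        if len(diffs) != 1:
            drops.append({"gene": model.gene, "position": ci, "site_type": "synonymous",
                          "reason": "multi-position"})
            continue
        pos = diffs[0]
        out_base = out_codon[pos]
        bases = [c[pos] for c in codons]
        if out_base not in (c1[pos], c2[pos]):
            drops.append({"gene": model.gene, "position": ci, "site_type": "synonymous",
                          "reason": "unpolarizable"})
            continue
        anc_base, der_base, d = polarize(bases, out_base)
        anc_codon = c1 if c1[pos] == anc_base else c2
        der_codon = c2 if anc_codon == c1 else c1
        pair = classify_pair(anc_codon, der_codon)
        dpref = None
        direction = ""
        preferred = None
        if table is not None:
            dpref = table.score(der_codon) - table.score(anc_codon)
            direction = direction_label(dpref)
            preferred = table.preferred(der_codon)
        local = int(coding_pos[lo + pos])
        rows.append({
            "gene": model.gene,
            "position": local + 1,
            "chrom_position": model.chrom_start + local + 1,
            "site_type": "synonymous",
            "amino_acid": CODON_TABLE[c1],
            "ancestral": anc_codon,
            "derived": der_codon,
            "anc_base": anc_base,
            "der_base": der_base,
            "d": d,
            "delta_pref": dpref,
            "direction": direction,
            "pair": pair.pair,
            "pair_subclass": pair.subclass,
            "preferred": preferred,
            "intron_len": None,
            "intron_pos": None,
        })

    L_intron = 0
    D_intron = 0
    for s, e in model.intron_blocks:
        ilen = e - s
        for j in range(s, e):
            col = [seq[j] for seq in aln.ingroup]
            out_base = aln.outgroup[j]
            if any(b not in _DNA for b in col) or out_base not in _DNA:
                continue
            L_intron += 1
            if out_base != col[0]:
                D_intron += 1
            alleles = sorted(set(col))
            if len(alleles) == 1:
                continue
            if len(alleles) > 2:
                drops.append({"gene": model.gene, "position": j, "site_type": "intron",
                              "reason": "multiallelic"})
                continue
            if out_base not in alleles:
                drops.append({"gene": model.gene, "position": j, "site_type": "intron",
                              "reason": "unpolarizable"})
                continue
            anc, der, d = polarize(col, out_base)
            rows.append({
                "gene": model.gene,
                "position": j + 1,
                "chrom_position": model.chrom_start + j + 1,
                "site_type": "intron",
                "amino_acid": "",
                "ancestral": anc,
                "derived": der,
                "anc_base": anc,
                "der_base": der,
                "d": d,
                "delta_pref": None,
                "direction": "",
                "pair": "",
                "pair_subclass": "",
                "preferred": None,
                "intron_len": ilen,
                "intron_pos": j - s + 1,
            })

    totals_rows = [{"class": "synonymous", "L": L_syn, "D_count": D_syn},
                   {"class": "intron", "L": float(L_intron), "D_count": D_intron}]
    totals_rows += [{"class": aa, "L": aa_L[aa], "D_count": aa_D.get(aa, 0)}
                    for aa in sorted(aa_L)]
    sites = pd.DataFrame(rows, columns=_SITE_COLUMNS)
    # consistent dtypes so per-gene frames concatenate cleanly
    sites = sites.astype(
        {"delta_pref": "float64", "preferred": "float64",
         "intron_len": "float64", "intron_pos": "float64"}
    )
    return CallResult(
        sites=sites,
        totals=pd.DataFrame(totals_rows),
        dropped=pd.DataFrame(drops, columns=["gene", "position", "site_type", "reason"]),
        codon_counts=pd.DataFrame(
            sorted(codon_counts.items()), columns=["codon", "count"]
        ),
    )


def combine_results(results: list[CallResult]) -> CallResult:
    """Concatenate per-gene calls and sum the per-class totals."""
    site_frames = [r.sites for r in results if len(r.sites)] or [results[0].sites]
    sites = pd.concat(site_frames, ignore_index=True)
    totals = (
        pd.concat([r.totals for r in results], ignore_index=True)
        .groupby("class", as_index=False)
        .sum()
    )
    drop_frames = [r.dropped for r in results if len(r.dropped)] or [results[0].dropped]
    dropped = pd.concat(drop_frames, ignore_index=True)
    counts = [r.codon_counts for r in results if r.codon_counts is not None]
    codon_counts = (
        pd.concat(counts, ignore_index=True).groupby("codon", as_index=False).sum()
        if counts
        else None
    )
    return CallResult(sites=sites, totals=totals, dropped=dropped, codon_counts=codon_counts)


def short_intron_filter(
    sites: pd.DataFrame,
    max_len: int = 80,
    head: int = 9,
    tail: int = 8,
) -> pd.DataFrame:
    """Intron sites in introns <= max_len bp, trimming splice-adjacent bases.

    The first ``head`` and last ``tail`` positions of each intron (1-based
    within the intron) are excluded, leaving max_len - head - tail eligible
    positions in an intron of maximal length.
    """
    intron = sites[sites["site_type"] == "intron"]
    keep = (
        (intron["intron_len"] <= max_len)
        & (intron["intron_pos"] > head)
        & (intron["intron_pos"] <= intron["intron_len"] - tail)
    )
    return intron[keep]


def write_site_table(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("amino_acid", "direction", "pair", "pair_subclass"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df
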