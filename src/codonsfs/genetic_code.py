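"""Standard genetic-code facts used by every downstream stage.

The analyses concern the 59 sense codons that encode the 18 degenerate amino
acids of the standard nuclear code (Met and Trp are excluded because they have
no synonyms).  Synonymous *sites* are counted fractionally: each codon position
contributes the fraction of its three possible single-base changes that are
synonymous, so a fourfold-degenerate third position is one full synonymous
site and a twofold-degenerate third position is 1/3 of a site.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

BASES = "TCAG"

# Standard nuclear genetic code, three-letter DNA codons.
CODON_TABLE: dict[str, str] = {}
_AA_BY_BLOCK = [
    ("TTT", "phe"), ("TTC", "phe"), ("TTA", "leu"), ("TTG", "leu"),
    ("CTT", "leu"), ("CTC", "leu"), ("CTA", "leu"), ("CTG", "leu"),
    ("ATT", "ile"), ("ATC", "ile"), ("ATA", "ile"), ("ATG", "met"),
    ("GTT", "val"), ("GTC", "val"), ("GTA", "val"), ("GTG", "val"),
    ("TCT", "ser"), ("TCC", "ser"), ("TCA", "ser"), ("TCG", "ser"),
    ("CCT", "pro"), ("CCC", "pro"), ("CCA", "pro"), ("CCG", "pro"),
    ("ACT", "thr"), ("ACC", "thr"), ("ACA", "thr"), ("ACG", "thr"),
    ("GCT", "ala"), ("GCC", "ala"), ("GCA", "ala"), ("GCG", "ala"),
    ("TAT", "tyr"), ("TAC", "tyr"),
    ("CAT", "his"), ("CAC", "his"), ("CAA", "gln"), ("CAG", "gln"),
    ("AAT", "asn"), ("AAC", "asn"), ("AAA", "lys"), ("AAG", "lys"),
    ("GAT", "asp"), ("GAC", "asp"), ("GAA", "glu"), ("GAG", "glu"),
    ("TGT", "cys"), ("TGC", "cys"), ("TGG", "trp"),
    ("CGT", "arg"), ("CGC", "arg"), ("CGA", "arg"), ("CGG", "arg"),
    ("AGT", "ser"), ("AGC", "ser"), ("AGA", "arg"), ("AGG", "arg"),
    ("GGT", "gly"), ("GGC", "gly"), ("GGA", "gly"), ("GGG", "gly"),
]
for _codon, _aa in _AA_BY_BLOCK:
    CODON_TABLE[_codon] = _aa

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
SENSE_CODONS = frozenset(CODON_TABLE)  # 61 codons

AMINO_ACIDS = sorted(set(CODON_TABLE.values()))
SYNONYMS: dict[str, list[str]] = {
    aa: sorted(c for c, a in CODON_TABLE.items() if a == aa) for aa in AMINO_ACIDS
}
DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in SYNONYMS.items()}

DEGENERATE_AMINO_ACIDS = sorted(aa for aa, n in DEGENERACY.items() if n > 1)  # 18
DEGENERATE_CODONS = sorted(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TABLE[c]] > 1
)  # 59


class CodonError(ValueError):
    """Raised for stop codons, unknown codons, or invalid codon pairs."""


def amino_acid(codon: str) -> str:
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise CodonError(f"stop codon {codon} has no amino acid")
    try:
        return CODON_TABLE[codon]
    except KeyError:
        raise CodonError(f"unknown codon {codon!r}") from None


def degeneracy(codon: str) -> int:
    """Degeneracy (number of synonyms, including itself) of a sense codon."""
    return DEGENERACY[amino_acid(codon)]


@lru_cache(maxsize=None)
def synonymous_site_count(codon: str) -> float:
    """Fractional synonymous site count of a sense codon.

    Each position contributes (number of synonymous single-base changes)/3;
    positions are summed.  A fourfold-degenerate third position gives 1.0,
    a twofold-degenerate one gives 1/3, and ATG/TGG give 0.
    """
    codon = codon.upper()
    aa = amino_acid(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
                syn += 1
        total += syn / 3.0
    return total


@dataclass(frozen=True)
class CodonPairClass:
    """Classification of a synonymous codon pair differing at one position.

    ``pair`` is the unordered base pair at the differing position, in the
    fixed orientations "C/T", "G/A", "C/G", "A/T", "C/A", "G/T";
    ``position`` is 0-based within the codon; ``subclass`` tags the
    amino-acid degeneracy context (fourfold, twofold, fourfold-of-sixfold,
    twofold-of-sixfold, isoleucine).
    """

    pair: str
    position: int
    amino_acid: str
    subclass: str


# Canonical orientation for unordered base pairs (pyrimidine/purine pairs
# named C-first / G-first to match the usual C/T and G/A labels).
_PAIR_LABEL = {
    frozenset("CT"): "C/T",
    frozenset("GA"): "G/A",
    frozenset("CG"): "C/G",
    frozenset("AT"): "A/T",
    frozenset("CA"): "C/A",
    frozenset("GT"): "G/T",
}

# Sixfold amino acids split into a fourfold box and a twofold box.
_SIXFOLD_FOURFOLD_PREFIX = {"leu": "CT", "ser": "TC", "arg": "CG"}
_SIXFOLD_TWOFOLD_PREFIX = {"leu": "TT", "ser": "AG", "arg": "AG"}


def _subclass(aa: str, codon: str, position: int) -> str:
    deg = DEGENERACY[aa]
    if aa == "ile":
        return "isoleucine"
    if deg == 2:
        return "twofold"
    if deg == 4:
        return "fourfold"
    if deg == 6:
        if position != 2:
            return "sixfold-first-position"
        if codon[:2] == _SIXFOLD_FOURFOLD_PREFIX[aa]:
            return "fourfold-of-sixfold"
        return "twofold-of-sixfold"
    raise CodonError(f"unexpected degeneracy {deg} for {aa}")


def classify_pair(ancestral: str, derived: str) -> CodonPairClass:
    """Classify a synonymous codon pair segregating at exactly one position."""
    ancestral, derived = ancestral.upper(), derived.upper()
    aa_a, aa_d = amino_acid(ancestral), amino_acid(derived)
    if aa_a != aa_d:
        raise CodonError(f"{ancestral}/{derived} is not a synonymous pair")
    diffs = [i for i in range(3) if ancestral[i] != derived[i]]
    if len(diffs) != 1:
        raise CodonError(
            f"{ancestral}/{derived} differ at {len(diffs)} positions; "
            "exactly one is required"
        )
    pos = diffs[0]
    label = _PAIR_LABEL[frozenset({ancestral[pos], derived[pos]})]
    return CodonPairClass(
        pair=label,
        position=pos,
        amino_acid=aa_a,
        subclass=_subclass(aa_a, ancestral, pos),
    )


def third_position_pairs(pair: str) -> list[tuple[str, str]]:
    """All synonymous codon pairs segregating the given bases at position 3.

    ``pair`` is e.g. "C/T"; each returned tuple is (codon ending in the first
    base, codon ending in the second base).  There are 16 such C/T pairs and
    13 G/A pairs in the standard code.
    """
    b1, b2 = pair.split("/")
    out = []
    for prefix in (x + y for x in BASES for y in BASES):
        c1, c2 = prefix + b1, prefix + b2
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        if c1 in CODON_TABLE and c2 in CODON_TABLE and CODON_TABLE[c1] == CODON_TABLE[c2]:
            out.append((c1, c2))
    return out
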