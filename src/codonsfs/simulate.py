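"""Synthetic data with the statistical structure the analyses assume.

The generator emits, per gene, an alignment of k ingroup sequences plus one
outgroup together with gene models, per-base masks, an optional recombination
map, and a ground-truth table, in exactly the formats the calling pipeline
reads — so every downstream stage can be exercised end to end and its output
checked against the planted truth.

Selection on codon usage is planted through the unfolded SFS: a biallelic
synonymous site whose derived codon changes the preference score by
delta-pref is assigned a scaled selection coefficient gamma_site =
gamma * delta-pref and its derived count d is drawn from the stationary
sampling distribution

    P(d) ∝ C(k, d) ∫0..1 x^d (1-x)^(k-d) * h(x; gamma) / (x (1-x)) dx,
    h(x; gamma) = (1 - exp(-2 gamma (1-x))) / (1 - exp(-2 gamma)),

the classic diffusion result for the frequency of a semidominant selected
derived allele.  This is the minimal model whose gamma = 0 limit is the
neutral 1/d spectrum that the downstream null expectations are built on.
Intron sites are always neutral.

Ancestral-state misassignment is planted by substituting the outgroup to the
derived allele with probability b/(1+b), b = D - ((k-1)/k) theta, per site
class; sequencing errors convert ancestral copies (or invariant sites) to a
single error state with independent per-sequence probability eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .genetic_code import (
    BASES,
    CODON_TABLE,
    DEGENERACY,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMS,
    amino_acid,
    synonymous_site_count,
)
from .neutral import harmonic
from .preference import PreferenceTable, load_reference_scores
from .recomb import RecombinationMap
from .sites import GeneModel, StrainAlignment


# --------------------------------------------------------------------------
# Selected-SFS sampler


@lru_cache(maxsize=512)
def selected_sfs_pmf(k: int, gamma: float) -> tuple[float, ...]:
    """Sampling distribution of derived counts 1..k-1 under selection gamma.

    gamma is the scaled selection coefficient of the derived allele; gamma=0
    reduces exactly to the neutral spectrum proportional to 1/d.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    d = np.arange(1, k)
    if abs(gamma) < 1e-9:
        w = 1.0 / d
    else:
        from math import comb, exp, expm1

        denom = -expm1(-2.0 * gamma)
        w = np.empty(k - 1)
        for i, di in enumerate(d):
            def integrand(x, di=di):
                return (
                    x ** (di - 1)
                    * (1.0 - x) ** (k - di - 1)
                    * (-expm1(-2.0 * gamma * (1.0 - x)))
                    / denom
                )

            val, _ = quad(integrand, 0.0, 1.0, limit=200)
            if not np.isfinite(val) or val < 0:
                raise RuntimeError(f"quadrature failed for k={k}, gamma={gamma}, d={di}")
            w[i] = comb(k, di) * val
    w = w / w.sum()
    return tuple(float(x) for x in w)


def sample_selected_sfs_counts(
    n_sites: int, k: int, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. derived counts from the selected sampling distribution."""
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    pmf = np.array(selected_sfs_pmf(k, round(float(gamma), 3)))
    return rng.choice(np.arange(1, k), size=n_sites, p=pmf)


# --------------------------------------------------------------------------
# Parameters


@dataclass
class RecombMapSpec:
    """Spec for a synthetic two-testcross recombination map."""

    n_segments: int = 30
    rate_mean: float = 2.5        # cM/Mb, lognormal mean of the true rate
    rate_sigma: float = 0.6       # lognormal sigma of the true rate
    cross_noise_sd: float = 0.15  # per-testcross multiplicative noise (sd of log)
    coupling: bool = True         # theta rises with rate, saturating
    saturation: float = 2.0       # cM/Mb at which the theta-rate coupling levels off
    floor: float = 0.35           # theta multiplier as rate -> 0


@dataclass
class SimulationParams:
    """Generator settings; defaults mirror the study conditions.

    k = 11 sampled sequences; theta and divergence per synonymous site are
    the chromosome-2 estimates (0.0222 and 0.0763) and the intron values
    0.0085 / 0.0297; sequencing error and singleton inflation are off by
    default.  gamma scales selection per unit delta-pref (gamma = 1 is the
    planted-selection condition, gamma = 0 the neutral control).
    """

    seed: int
    k: int = 11
    n_genes: int = 60
    gene_length_codons: int = 300
    intron_length: int = 70
    gamma: float = 1.0
    theta_syn: float = 0.0222
    theta_intron: float = 0.0085
    div_syn: float = 0.0763
    div_intron: float = 0.0297
    eps: float = 0.0
    asm: bool = True
    preference: PreferenceTable | None = None
    recomb: RecombMapSpec | None = None
    singleton_inflation: float = 1.0
    mask_fail_rate: float = 0.0
    chrom: str = "chr2"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("theta_syn", "theta_intron", "div_syn", "div_intron", "eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not np.isfinite(self.gamma):
            raise ValueError("gamma must be finite")
        if self.singleton_inflation < 1.0:
            raise ValueError("singleton_inflation must be >= 1")

    def table(self) -> PreferenceTable:
        return self.preference if self.preference is not None else load_reference_scores()

    def flip_probability(self, theta: float, div: float) -> float:
        if not self.asm:
            return 0.0
        b = div - (self.k - 1) / self.k * theta
        return max(b, 0.0) / (1.0 + max(b, 0.0))


@dataclass
class SimulatedDataset:
    params: SimulationParams
    alignments: list[StrainAlignment]
    models: list[GeneModel]
    truth: pd.DataFrame
    rmap: RecombinationMap | None = None
    theta_multipliers: pd.DataFrame | None = None


# --------------------------------------------------------------------------
# Helpers

_SINGLE_POSITION_PARTNERS: dict[str, list[str]] = {}
for _c in sorted(SENSE_CODONS):
    if DEGENERACY[CODON_TABLE[_c]] == 1:
        continue
    _partners = []
    for _pos in range(3):
        for _b in BASES:
            if _b == _c[_pos]:
                continue
            _alt = _c[:_pos] + _b + _c[_pos + 1:]
            if _alt not in STOP_CODONS and CODON_TABLE.get(_alt) == CODON_TABLE[_c]:
                _partners.append(_alt)
    _SINGLE_POSITION_PARTNERS[_c] = _partners


def _draw_d(gamma_site: float, inflation: float, k: int, rng: np.random.Generator) -> int:
    pmf = np.array(selected_sfs_pmf(k, round(float(gamma_site), 2)))
    if inflation > 1.0:
        pmf = pmf.copy()
        pmf[0] *= inflation
        pmf /= pmf.sum()
    return int(rng.choice(np.arange(1, k), p=pmf))


def simulate_recomb_map(
    spec: RecombMapSpec,
    chrom_length: int,
    seed_or_rng,
    chrom: str = "chr2",
) -> tuple[RecombinationMap, pd.DataFrame]:
    """Synthetic two-testcross map plus per-segment theta multipliers.

    Segments tile the chromosome; each has a true lognormal rate observed
    twice with independent multiplicative noise (the two "testcrosses"),
    and a theta multiplier that rises linearly with the true rate until the
    saturation rate, from ``floor`` up to 1.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if spec.n_segments < 1:
        raise ValueError("need >= 1 segment")
    bounds = np.linspace(0, chrom_length, spec.n_segments + 1).astype(int)
    mu = np.log(spec.rate_mean) - spec.rate_sigma**2 / 2
    true_rate = rng.lognormal(mu, spec.rate_sigma, spec.n_segments)
    rate_a = true_rate * rng.lognormal(0.0, spec.cross_noise_sd, spec.n_segments)
    rate_b = true_rate * rng.lognormal(0.0, spec.cross_noise_sd, spec.n_segments)
    if spec.coupling:
        mult = spec.floor + (1 - spec.floor) * np.minimum(true_rate, spec.saturation) / spec.saturation
    else:
        mult = np.ones(spec.n_segments)
    seg = pd.DataFrame(
        {
            "chrom": chrom,
            "start": bounds[:-1],
            "end": bounds[1:],
            "rate_a": rate_a,
            "rate_b": rate_b,
            "segment_id": [f"seg{i:04d}" for i in range(spec.n_segments)],
        }
    )
    mult_df = pd.DataFrame(
        {"segment_id": seg["segment_id"], "true_rate": true_rate, "theta_multiplier": mult}
    )
    return RecombinationMap(seg), mult_df


_AA_POOL = sorted(set(CODON_TABLE.values()))  # all 20, degenerate and not


def _random_coding_codons(
    n_codons: int, bias: float, table: PreferenceTable, rng: np.random.Generator
) -> list[str]:
    """Ancestral codons for one gene: usage skewed toward preferred codons.

    Within each amino acid, codon probabilities are proportional to
    exp(bias * preference score); ``bias`` varies among genes so that genes
    span a range of codon-usage bias, which is what the factor analysis
    extracts.
    """
    aas = rng.choice(_AA_POOL, size=n_codons)
    out = []
    for aa in aas:
        syns = SYNONYMS[aa]
        if len(syns) == 1:
            out.append(syns[0])
            continue
        scores = np.array([table.score(c) for c in syns])
        p = np.exp(bias * scores)
        p /= p.sum()
        out.append(syns[rng.choice(len(syns), p=p)])
    return out


def _random_intron(length: int, rng: np.random.Generator) -> str:
    if length < 4:
        raise ValueError("intron must be >= 4 bp for GT..AG boundaries")
    middle = "".join(rng.choice(list(BASES), size=length - 4))
    return "GT" + middle + "AG"


# --------------------------------------------------------------------------
# Main generator


def simulate_sites(params: SimulationParams) -> SimulatedDataset:
    """Generate alignments, gene models, masks, and the ground-truth table.

    Each gene is laid out as [exon 1][intron][exon 2]; polymorphic
    synonymous sites are planted at degenerate codons with per-codon
    probability theta_syn * a_k * (fractional synonymous sites of the
    codon), scaled by the gene's segment theta multiplier when a
    recombination map is generated; intron sites analogously at
    theta_intron * a_k per base.  Divergence substitutions are placed on the
    outgroup at monomorphic positions; ASM flips place the derived allele on
    the outgroup at polymorphic ones.
    """
    rng = np.random.default_rng(params.seed)
    table = params.table()
    k = params.k
    a_k = harmonic(k)

    n_coding = params.gene_length_codons
    if n_coding < 20:
        raise ValueError("gene_length_codons too small")
    gene_span = 3 * (n_coding + 2) + params.intron_length + 100
    chrom_length = params.n_genes * gene_span
    rmap = None
    multipliers = None
    seg_mult_lookup = None
    if params.recomb is not None:
        rmap, multipliers = simulate_recomb_map(
            params.recomb, chrom_length, rng, chrom=params.chrom
        )
        seg = rmap.segments
        seg_mult_lookup = (
            seg["start"].to_numpy(),
            seg["end"].to_numpy(),
            multipliers["theta_multiplier"].to_numpy(),
        )

    p_poly_codon_base = params.theta_syn * a_k
    if p_poly_codon_base >= 1:
        raise ValueError("theta_syn too large for per-codon polymorphism probability")
    flip_syn = params.flip_probability(params.theta_syn, params.div_syn)
    flip_intron = params.flip_probability(params.theta_intron, params.div_intron)

    strain_names = ["ref"] + [f"strain{i:02d}" for i in range(1, k)]
    alignments: list[StrainAlignment] = []
    models: list[GeneModel] = []
    truth_rows: list[dict] = []

    for g in range(params.n_genes):
        gene = f"g{g:04d}"
        chrom_start = g * gene_span
        mult = 1.0
        if seg_mult_lookup is not None:
            starts, ends, mults = seg_mult_lookup
            mid = chrom_start + gene_span // 2
            i = int(np.searchsorted(starts, mid, side="right") - 1)
            if 0 <= i < len(mults) and mid <= ends[i]:
                mult = float(mults[i])

        bias = rng.uniform(0.0, 2.0)
        body = _random_coding_codons(n_coding, bias, table, rng)
        codons = ["ATG"] + body + ["TAA"]
        n_total = len(codons)
        # Split coding sequence into two exons around the intron.
        split_codon = n_total // 2
        exon1 = "".join(codons[:split_codon])
        exon2 = "".join(codons[split_codon:])
        intron = _random_intron(params.intron_length, rng)
        anc_seq = exon1 + intron + exon2
        L = len(anc_seq)
        i_start = len(exon1)
        i_end = i_start + params.intron_length
        model = GeneModel(
            gene=gene,
            strand="+",
            cds_blocks=[(0, i_start), (i_end, L)],
            intron_blocks=[(i_start, i_end)],
            chrom=params.chrom,
            chrom_start=chrom_start,
        )

        ingroup = [list(anc_seq) for _ in range(k)]
        outgroup = list(anc_seq)

        # --- synonymous sites -------------------------------------------
        coding_pos = model.coding_positions()
        for ci in range(1, n_total - 1):  # skip start and stop codons
            codon = codons[ci]
            partners = _SINGLE_POSITION_PARTNERS.get(codon, [])
            if not partners:
                continue
            ssc = synonymous_site_count(codon)
            p_poly = min(p_poly_codon_base * ssc * mult, 0.9)
            lo = 3 * ci
            if rng.random() < p_poly:
                der = partners[rng.integers(len(partners))]
                pos = next(i for i in range(3) if codon[i] != der[i])
                dpref = table.score(der) - table.score(codon)
                gamma_site = params.gamma * dpref
                d = _draw_d(gamma_site, params.singleton_inflation, k, rng)
                carriers = rng.choice(k, size=d, replace=False)
                seq_pos = int(coding_pos[lo + pos])
                for s in carriers:
                    ingroup[s][seq_pos] = der[pos]
                flipped = rng.random() < flip_syn
                if flipped:
                    outgroup[seq_pos] = der[pos]
                truth_rows.append(
                    {
                        "gene": gene,
                        "position": seq_pos + 1,
                        "chrom_position": chrom_start + seq_pos + 1,
                        "site_type": "synonymous",
                        "amino_acid": amino_acid(codon),
                        "true_ancestral": codon,
                        "true_derived": der,
                        "true_d": d,
                        "delta_pref": dpref,
                        "gamma_site": gamma_site,
                        "asm_flipped": flipped,
                    }
                )
            else:
                # Outgroup divergence at monomorphic codons only.
                p_div = min(params.div_syn * ssc, 0.9)
                if rng.random() < p_div:
                    sub = partners[rng.integers(len(partners))]
                    pos = next(i for i in range(3) if codon[i] != sub[i])
                    outgroup[int(coding_pos[lo + pos])] = sub[pos]

        # --- intron sites ------------------------------------------------
        p_poly_i = params.theta_intron * a_k
        for j in range(i_start + 2, i_end - 2):  # keep GT..AG intact
            anc_base = anc_seq[j]
            if rng.random() < p_poly_i * mult:
                der_base = rng.choice([b for b in BASES if b != anc_base])
                d = _draw_d(0.0, params.singleton_inflation, k, rng)
                carriers = rng.choice(k, size=d, replace=False)
                for s in carriers:
                    ingroup[s][j] = der_base
                flipped = rng.random() < flip_intron
                if flipped:
                    outgroup[j] = der_base
                truth_rows.append(
                    {
                        "gene": gene,
                        "position": j + 1,
                        "chrom_position": chrom_start + j + 1,
                        "site_type": "intron",
                        "amino_acid": "",
                        "true_ancestral": anc_base,
                        "true_derived": der_base,
                        "true_d": d,
                        "delta_pref": 0.0,
                        "gamma_site": 0.0,
                        "asm_flipped": flipped,
                    }
                )
            elif rng.random() < params.div_intron:
                outgroup[j] = rng.choice([b for b in BASES if b != anc_base])

        # --- sequencing errors ------------------------------------------
        if params.eps > 0:
            _apply_errors(ingroup, anc_seq, model, params.eps, rng)

        # --- masks -------------------------------------------------------
        quality = np.full((k - 1, L), 40, dtype=int)
        coverage = np.full((k - 1, L), 30, dtype=int)
        if params.mask_fail_rate > 0:
            fail = rng.random((k - 1, L)) < params.mask_fail_rate
            quality[fail] = 20

        alignments.append(
            StrainAlignment(
                gene=gene,
                names=strain_names,
                ingroup=["".join(s) for s in ingroup],
                outgroup="".join(outgroup),
                quality=quality,
                coverage=coverage,
            )
        )
        models.append(model)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene", "position", "chrom_position", "site_type", "amino_acid",
            "true_ancestral", "true_derived", "true_d", "delta_pref",
            "gamma_site", "asm_flipped",
        ],
    )
    return SimulatedDataset(
        params=params,
        alignments=alignments,
        models=models,
        truth=truth,
        rmap=rmap,
        theta_multipliers=multipliers,
    )


def _apply_errors(
    ingroup: list[list[str]],
    anc_seq: str,
    model: GeneModel,
    eps: float,
    rng: np.random.Generator,
) -> None:
    """Independent per-sequence miscalls, all toward one state per site.

    At sites already segregating, errors convert ancestral copies to the
    segregating derived state; at invariant sites the error state is a
    synonymous partner (coding) or a random other base (intron).
    """
    k = len(ingroup)
    coding_pos = model.coding_positions()
    targets: list[tuple[int, str]] = []
    coding_ref = model.coding_sequence(anc_seq)
    for ci in range(1, len(coding_ref) // 3 - 1):
        codon = coding_ref[3 * ci:3 * ci + 3]
        partners = _SINGLE_POSITION_PARTNERS.get(codon, [])
        if not partners:
            continue
        err = partners[rng.integers(len(partners))]
        pos = next(i for i in range(3) if codon[i] != err[i])
        targets.append((int(coding_pos[3 * ci + pos]), err[pos]))
    for s, e in model.intron_blocks:
        for j in range(s + 2, e - 2):
            alt = rng.choice([b for b in BASES if b != anc_seq[j]])
            targets.append((j, alt))
    n_errors = rng.binomial(k, eps, size=len(targets))
    for (pos, fallback_state), n_err in zip(targets, n_errors):
        if n_err == 0:
            continue
        column = [ingroup[s][pos] for s in range(k)]
        derived_states = sorted(set(column) - {anc_seq[pos]})
        state = derived_states[0] if derived_states else fallback_state
        ancestral_copies = [s for s in range(k) if column[s] == anc_seq[pos]]
        for s in rng.choice(ancestral_copies, size=min(n_err, len(ancestral_copies)), replace=False):
            ingroup[s][pos] = state


# --------------------------------------------------------------------------
# On-disk round trip (the formats the calling pipeline reads)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write FASTA alignments, annotation, masks, map, and truth table."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    (outdir / "genes").mkdir(parents=True, exist_ok=True)
    ann_rows = []
    mask_rows = []
    for aln, model in zip(ds.alignments, ds.models):
        records = [
            SeqRecord(Seq(s), id=name, description="")
            for name, s in zip(aln.names, aln.ingroup)
        ]
        records.append(SeqRecord(Seq(aln.outgroup), id="outgroup", description=""))
        SeqIO.write(records, outdir / "genes" / f"{aln.gene}.fasta", "fasta")
        ann_rows.append(
            {
                "gene": model.gene,
                "strand": model.strand,
                "chrom": model.chrom,
                "chrom_start": model.chrom_start,
                "cds_blocks": ";".join(f"{s}-{e}" for s, e in model.cds_blocks),
                "intron_blocks": ";".join(f"{s}-{e}" for s, e in model.intron_blocks),
            }
        )
        if aln.quality is not None:
            fail = np.argwhere((aln.quality < 40) | (aln.coverage < 30))
            for i, pos in fail:
                mask_rows.append(
                    {
                        "gene": aln.gene,
                        "strain": aln.names[i + 1],
                        "position": int(pos) + 1,
                        "quality": int(aln.quality[i, pos]),
                        "coverage": int(aln.coverage[i, pos]),
                    }
                )
    pd.DataFrame(ann_rows).to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    pd.DataFrame(
        mask_rows, columns=["gene", "strain", "position", "quality", "coverage"]
    ).to_csv(outdir / "masks.tsv", sep="\t", index=False)
    ds.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if ds.rmap is not None:
        ds.rmap.to_tsv(outdir / "recomb_map.tsv")


def read_dataset(indir) -> tuple[list[StrainAlignment], list[GeneModel], RecombinationMap | None]:
    """Read back a dataset written by :func:`write_dataset`.

    Mask entries absent from masks.tsv default to passing values
    (quality 40, coverage 30).
    """
    from Bio import SeqIO

    indir = Path(indir)
    ann = pd.read_csv(indir / "annotation.tsv", sep="\t")
    masks_path = indir / "masks.tsv"
    masks = pd.read_csv(masks_path, sep="\t") if masks_path.exists() else pd.DataFrame(
        columns=["gene", "strain", "position", "quality", "coverage"]
    )
    masks_by_gene = dict(tuple(masks.groupby("gene"))) if len(masks) else {}
    alignments = []
    models = []
    for _, row in ann.iterrows():
        gene = row["gene"]
        records = list(SeqIO.parse(indir / "genes" / f"{gene}.fasta", "fasta"))
        names = [r.id for r in records[:-1]]
        ingroup = [str(r.seq) for r in records[:-1]]
        outgroup = str(records[-1].seq)
        L = len(ingroup[0])
        quality = np.full((len(ingroup) - 1, L), 40, dtype=int)
        coverage = np.full((len(ingroup) - 1, L), 30, dtype=int)
        gm = masks_by_gene.get(gene)
        if gm is not None:
            name_idx = {n: i - 1 for i, n in enumerate(names) if i > 0}
            for _, m in gm.iterrows():
                i = name_idx[m["strain"]]
                quality[i, int(m["position"]) - 1] = int(m["quality"])
                coverage[i, int(m["position"]) - 1] = int(m["coverage"])
        alignments.append(
            StrainAlignment(
                gene=gene, names=names, ingroup=ingroup, outgroup=outgroup,
                quality=quality, coverage=coverage,
            )
        )

        def _blocks(txt) -> list[tuple[int, int]]:
            if not isinstance(txt, str) or not txt:
                return []
            return [tuple(map(int, part.split("-"))) for part in txt.split(";")]

        models.append(
            GeneModel(
                gene=gene,
                strand=row["strand"],
                cds_blocks=_blocks(row["cds_blocks"]),
                intron_blocks=_blocks(row["intron_blocks"]),
                chrom=row["chrom"],
                chrom_start=int(row["chrom_start"]),
            )
        )
    map_path = indir / "recomb_map.tsv"
    rmap = RecombinationMap.from_tsv(map_path) if map_path.exists() else None
    return alignments, models, rmap
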