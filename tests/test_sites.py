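"""Gene filters, masking thresholds, site calling, and polarization."""

import numpy as np
import pandas as pd
import pytest

from codonsfs.preference import load_reference_scores
from codonsfs.sites import (
    GeneModel,
    StrainAlignment,
    apply_masks,
    call_sites,
    polarize,
    read_site_table,
    short_intron_filter,
    validate_gene,
    write_site_table,
)

K = 11
TABLE = load_reference_scores()
INTRON = "GT" + "ACCA" * 4 + "AG"  # 20 bp, canonical boundaries


def build_gene(codons_exon1, codons_exon2, intron=INTRON):
    """Gene layout: [exon1][intron][exon2]; returns (sequence, model)."""
    exon1 = "".join(codons_exon1)
    exon2 = "".join(codons_exon2)
    seq = exon1 + intron + exon2
    i0, i1 = len(exon1), len(exon1) + len(intron)
    model = GeneModel(
        gene="t0001",
        strand="+",
        cds_blocks=[(0, i0), (i1, len(seq))],
        intron_blocks=[(i0, i1)],
    )
    return seq, model


def make_alignment(ref_seq, variants=None, outgroup=None, gene="t0001"):
    """k=11 copies of ref_seq with per-strain substitutions.

    ``variants`` maps strain index (1..10) to a list of (position, base).
    """
    ingroup = [list(ref_seq) for _ in range(K)]
    for strain, subs in (variants or {}).items():
        for pos, base in subs:
            ingroup[strain][pos] = base
    quality = np.full((K - 1, len(ref_seq)), 40, dtype=int)
    coverage = np.full((K - 1, len(ref_seq)), 30, dtype=int)
    return StrainAlignment(
        gene=gene,
        names=["ref"] + [f"s{i}" for i in range(1, K)],
        ingroup=["".join(s) for s in ingroup],
        outgroup=outgroup if outgroup is not None else ref_seq,
        quality=quality,
        coverage=coverage,
    )


BASE_EXON1 = ["ATG", "GAA", "GCT"]
BASE_EXON2 = ["CTG", "AAA", "TAA"]


class TestValidateGene:
    def test_canonical_gene_included(self):
        seq, model = build_gene(BASE_EXON1, BASE_EXON2)
        assert validate_gene(model, seq) == (True, "ok")

    def test_non_aug_start_excluded(self):
        seq, model = build_gene(["GTG", "GAA", "GCT"], BASE_EXON2)
        assert validate_gene(model, seq) == (False, "start")

    def test_bad_stop_excluded(self):
        seq, model = build_gene(BASE_EXON1, ["CTG", "AAA", "TGC"])
        assert validate_gene(model, seq) == (False, "stop")

    def test_premature_stop_excluded(self):
        seq, model = build_gene(["ATG", "TAA", "GCT"], BASE_EXON2)
        assert validate_gene(model, seq) == (False, "premature stop")

    def test_unresolved_codon_excluded(self):
        seq, model = build_gene(["ATG", "GNA", "GCT"], BASE_EXON2)
        assert validate_gene(model, seq) == (False, "unresolved codon")

    def test_noncanonical_intron_excluded(self):
        seq, model = build_gene(BASE_EXON1, BASE_EXON2, intron="GA" + "A" * 16 + "AG")
        assert validate_gene(model, seq) == (False, "noncanonical intron")

    def test_out_of_range_block_raises(self):
        seq, model = build_gene(BASE_EXON1, BASE_EXON2)
        model.cds_blocks[-1] = (model.cds_blocks[-1][0], len(seq) + 5)
        with pytest.raises(ValueError):
            validate_gene(model, seq)


class TestMasks:
    @pytest.mark.parametrize(
        "quality,coverage,kept",
        [(29, 20, False), (35, 14, False), (30, 15, True), (40, 30, True)],
    )
    def test_thresholds_are_strict_below(self, quality, coverage, kept):
        seq, _ = build_gene(BASE_EXON1, BASE_EXON2)
        aln = make_alignment(seq)
        aln.quality[0, 4] = quality
        aln.coverage[0, 4] = coverage
        masked = apply_masks(aln)
        assert (masked.ingroup[1][4] != "N") is kept

    def test_reference_strain_never_masked(self):
        seq, _ = build_gene(BASE_EXON1, BASE_EXON2)
        aln = make_alignment(seq)
        aln.quality[:, :] = 0
        masked = apply_masks(aln)
        assert masked.ingroup[0] == seq
        assert set(masked.ingroup[1]) == {"N"}

    def test_missing_masks_mean_unresolved(self):
        seq, _ = build_gene(BASE_EXON1, BASE_EXON2)
        aln = make_alignment(seq)
        aln.quality = None
        masked = apply_masks(aln)
        assert set(masked.ingroup[1]) == {"N"}
        assert masked.ingroup[0] == seq


class TestPolarize:
    def test_low_frequency_derived(self):
        anc, der, d = polarize(["C"] * 10 + ["T"], "C")
        assert (anc, der, d) == ("C", "T", 1)

    def test_high_frequency_derived(self):
        anc, der, d = polarize(["C"] + ["T"] * 10, "C")
        assert (anc, der, d) == ("C", "T", 10)

    def test_outgroup_matching_neither_state_rejected(self):
        with pytest.raises(ValueError):
            polarize(["C"] * 6 + ["T"] * 5, "A")


class TestCallSites:
    def test_simple_synonymous_site(self):
        # GAA x8, GAG x3 at codon 1 (exon1), outgroup GAA
        seq, model = build_gene(BASE_EXON1, BASE_EXON2)
        variants = {i: [(5, "G")] for i in (2, 5, 9)}  # third base of GAA codon
        aln = make_alignment(seq, variants)
        res = call_sites(aln, model, TABLE)
        assert len(res.sites) == 1
        site = res.sites.iloc[0]
        assert site.site_type == "synonymous"
        assert (site.amino_acid, site.ancestral, site.derived) == ("glu", "GAA", "GAG")
        assert site.d == 3
        assert site.delta_pref == pytest.approx(1.448)
        assert site.direction == "U->P"
        assert (site.pair, site.pair_subclass) == ("G/A", "twofold")

    def test_unresolved_strain_removes_codon_from_totals(self):
        seq, model = build_gene(BASE_EXON1, BASE_EXON2)
        clean = call_sites(make_alignment(seq), model, TABLE)
        aln = make_alignment(seq, {3: [(4, "N")]})  # breaks the GAA codon
        res = call_sites(aln, model, TABLE)
        L = lambda r: float(r.totals.loc[r.totals["class"] == "synonymous", "L"].iloc[0])
        assert L(res) == pytest.approx(L(clean) - 1 / 3)
        assert len(res.sites) == 0

    def test_three_codons_segregating_dropped(self):
        seq, model = build_gene(BASE_EXON1, BASE_EXON2)
        variants = {2: [(5, "G")], 7: [(3, "C"), (5, "G")]}  # GAA/GAG/CAG
        aln = make_alignment(seq, variants)
        res = call_sites(aln, model, TABLE)
        assert "multiallelic" in set(res.dropped["reason"])

    def test_unpolarizable_site_logged(self):
        seq, model = build_gene(BASE_EXON1, BASE_EXON2)
        variants = {2: [(5, "G")], 5: [(5, "G")]}
        out = seq[:5] + "T" + seq[6:]  # outgroup GAT at the polymorphic codon
        aln = make_alignment(seq, variants, outgroup=out)
        res = call_sites(aln, model, TABLE)
        assert len(res.sites) == 0
        assert set(res.dropped["reason"]) == {"unpolarizable"}

    def test_two_position_codon_pair_excluded(self):
        seq, model = build_gene(BASE_EXON1, BASE_EXON2)
        # CTG -> TTA: Leu in both, but two positions differ
        pos = model.cds_blocks[1][0]  # CTG is the first codon of exon2
        variants = {i: [(pos, "T"), (pos + 2, "A")] for i in (1, 4)}
        aln = make_alignment(seq, variants)
        res = call_sites(aln, model, TABLE)
        assert "multi-position" in set(res.dropped["reason"])

    def test_intron_site_called_and_divergence_counted(self):
        seq, model = build_gene(BASE_EXON1, BASE_EXON2)
        ipos = model.intron_blocks[0][0] + 5
        variants = {i: [(ipos, "G")] for i in (1, 2, 6, 8)}
        aln = make_alignment(seq, variants)
        res = call_sites(aln, model, TABLE)
        intron_sites = res.sites[res.sites.site_type == "intron"]
        assert len(intron_sites) == 1
        s = intron_sites.iloc[0]
        assert s.d == 4 and s.intron_len == 20 and s.intron_pos == 6

    def test_synonymous_divergence_counts_reference_vs_outgroup(self):
        seq, model = build_gene(BASE_EXON1, BASE_EXON2)
        out = seq[:5] + "G" + seq[6:]  # outgroup GAG vs reference GAA
        aln = make_alignment(seq, outgroup=out)
        res = call_sites(aln, model, TABLE)
        D = res.totals.loc[res.totals["class"] == "synonymous", "D_count"].iloc[0]
        assert D == 1


class TestShortIntronFilter:
    @staticmethod
    def intron_sites(length, positions):
        return pd.DataFrame(
            {
                "site_type": "intron",
                "intron_len": length,
                "intron_pos": positions,
                "d": 1,
            }
        )

    def test_80bp_intron_has_63_eligible_positions(self):
        sites = self.intron_sites(80, list(range(1, 81)))
        assert len(short_intron_filter(sites)) == 63

    def test_81bp_intron_fully_excluded(self):
        sites = self.intron_sites(81, list(range(1, 82)))
        assert len(short_intron_filter(sites)) == 0

    def test_splice_adjacent_positions_excluded(self):
        sites = self.intron_sites(60, [9, 10, 52, 53])
        kept = short_intron_filter(sites)["intron_pos"].tolist()
        assert kept == [10, 52]


def test_site_table_roundtrip(tmp_path, small_dataset):
    from codonsfs.sites import call_sites as cs, combine_results

    res = combine_results(
        [cs(a, m, TABLE) for a, m in zip(small_dataset.alignments[:5], small_dataset.models[:5])]
    )
    path = tmp_path / "sites.tsv"
    write_site_table(res.sites, path)
    again = read_site_table(path)
    pd.testing.assert_frame_equal(
        again[["gene", "position", "d", "ancestral", "derived"]],
        res.sites[["gene", "position", "d", "ancestral", "derived"]],
    )
    assert np.allclose(
        again["delta_pref"].fillna(0.0), res.sites["delta_pref"].fillna(0.0)
    )
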