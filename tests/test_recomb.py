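"""Recombination-rate assignment, rate classes, and correlations."""

import numpy as np
import pandas as pd
import pytest

from codonsfs.recomb import (
    RecombinationMap,
    assign_rate,
    bin_rate_classes,
    class_summaries,
    correlate,
    rate_class_label,
    segment_summaries,
)
from codonsfs.simulate import RecombMapSpec, simulate_recomb_map


@pytest.fixture()
def toy_map():
    return RecombinationMap(
        pd.DataFrame(
            {
                "chrom": "chr2",
                "start": [0, 100, 200],
                "end": [100, 200, 300],
                "rate_a": [1.0, 3.0, np.nan],
                "rate_b": [2.0, 5.0, 4.0],
            }
        )
    )


class TestAssignRate:
    def test_inside_segment_gets_average(self, toy_map):
        out = assign_rate([50], toy_map)
        assert out["rate"].iloc[0] == pytest.approx(1.5)
        assert out["segment_id"].iloc[0] == "seg0000"

    def test_upstream_position_is_missing(self, toy_map):
        out = assign_rate([0], toy_map)  # (0, 100] excludes 0
        assert np.isnan(out["rate"].iloc[0])

    def test_boundary_belongs_to_lower_segment(self, toy_map):
        out = assign_rate([100, 101], toy_map)
        assert out["segment_id"].tolist() == ["seg0000", "seg0001"]

    def test_single_map_segment_requires_flag(self, toy_map):
        strict = assign_rate([250], toy_map)
        assert np.isnan(strict["rate"].iloc[0])
        loose = assign_rate([250], toy_map, allow_single_map=True)
        assert loose["rate"].iloc[0] == pytest.approx(4.0)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            RecombinationMap(
                pd.DataFrame(
                    {
                        "chrom": "c",
                        "start": [0, 50],
                        "end": [100, 150],
                        "rate_a": [1.0, 1.0],
                        "rate_b": [1.0, 1.0],
                    }
                )
            )


class TestRateClasses:
    @pytest.mark.parametrize(
        "rate,cls", [(0.0, 0), (0.25, 0), (0.26, 1), (5.99, 23), (6.0, 23), (6.2, 24)]
    )
    def test_binning(self, rate, cls):
        assert bin_rate_classes([rate]).iloc[0] == cls

    def test_25_classes_with_defaults(self):
        labels = {rate_class_label(c) for c in range(25)}
        assert len(labels) == 25
        assert rate_class_label(0) == "0.00-0.25"
        assert rate_class_label(24) == ">6.00"

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            bin_rate_classes([-0.1])

    def test_class_counts_conserve_assigned_sites(self, rng):
        rates = rng.uniform(0, 8, 500)
        cls = bin_rate_classes(rates)
        assert cls.value_counts().sum() == 500


class TestCorrelate:
    def test_perfect_line(self):
        r, df, p = correlate([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert df == 2

    def test_five_points_match_direct_formula(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        r, df, _ = correlate(x, y, tail=2)
        direct = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(direct)
        assert df == 3

    def test_null_calibration(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        r, _, _ = correlate(x, y)
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])


class TestSummaries:
    def test_single_class_equals_global(self):
        sites = pd.DataFrame({"rate": [0.1] * 7, "d": 1})
        totals = pd.DataFrame({"rate_class": [0], "L": [350.0]})
        out = class_summaries(sites, totals)
        from codonsfs.diversity import watterson_theta

        assert out["theta_w_per_bp"].iloc[0] == pytest.approx(
            watterson_theta(7, 350.0, 11)
        )

    def test_segment_filter_threshold(self, toy_map):
        sites = pd.DataFrame(
            {"segment_id": ["seg0000"] * 3 + ["seg0001"] * 2, "d": 1}
        )
        totals = pd.DataFrame(
            {"segment_id": ["seg0000", "seg0001"], "L": [6000.0, 100.0]}
        )
        out = segment_summaries(sites, totals, toy_map, min_sites=5000)
        flags = dict(zip(out["segment_id"], out["well_sampled"]))
        assert flags == {"seg0000": True, "seg0001": False}


class TestSimulatedMap:
    def test_testcross_replicates_agree(self):
        rmap, _ = simulate_recomb_map(RecombMapSpec(n_segments=80), 10_000_000, 5)
        r = np.corrcoef(rmap.segments["rate_a"], rmap.segments["rate_b"])[0, 1]
        assert r > 0.8

    def test_coupling_is_monotone_then_flat(self):
        _, mult = simulate_recomb_map(RecombMapSpec(n_segments=200), 10_000_000, 9)
        below = mult[mult["true_rate"] < 2.0].sort_values("true_rate")
        assert below["theta_multiplier"].is_monotonic_increasing
        above = mult[mult["true_rate"] >= 2.0]
        assert np.allclose(above["theta_multiplier"], 1.0)

    def test_coupling_disabled_gives_flat_multipliers(self):
        _, mult = simulate_recomb_map(
            RecombMapSpec(n_segments=50, coupling=False), 1_000_000, 2
        )
        assert np.allclose(mult["theta_multiplier"], 1.0)


def test_planted_theta_rate_coupling_recovered(small_dataset):
    """Class-level diversity rises with recombination rate when coupled."""
    from codonsfs.recomb import bin_rate_classes
    from codonsfs.sites import apply_masks, call_sites, combine_results
    from codonsfs.preference import load_reference_scores

    ds = small_dataset
    table = load_reference_scores()
    res = combine_results(
        [call_sites(apply_masks(a), m, table) for a, m in zip(ds.alignments, ds.models)]
    )
    sites = res.sites
    assigned = assign_rate(sites["chrom_position"].to_numpy(), ds.rmap)
    sites = sites.assign(rate=assigned["rate"].to_numpy())
    syn = sites[(sites["site_type"] == "synonymous") & sites["rate"].notna()].copy()
    truth = ds.theta_multipliers
    # per-segment S correlates with the planted multiplier
    seg_sites = assign_rate(syn["chrom_position"].to_numpy(), ds.rmap)["segment_id"]
    counts = pd.Series(seg_sites).value_counts()
    merged = truth.set_index("segment_id").join(counts.rename("S")).dropna()
    r, _, _ = correlate(merged["theta_multiplier"], merged["S"])
    assert r > 0
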