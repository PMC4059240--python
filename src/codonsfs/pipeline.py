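"""End-to-end orchestration: filters -> preference table -> site table -> tests.

``run_full_analysis`` takes a :class:`RunConfig`, obtains data (either a
synthetic dataset generated in-process or a directory in the on-disk
formats), applies the gene and site filters, builds or loads the preference
table, calls and polarizes sites, and writes the report bundle:

* ``site_table.tsv``        one row per biallelic polymorphic site
* ``preference_table.tsv``  per-codon scores and preferred flags
* ``diversity.tsv``         theta_W / divergence per class (overall + amino acid)
* ``sfs_tests.tsv``         U->P vs P->U shift tests, permutation tests
* ``anova.tsv``             site type x direction ANOVA per base-change pair
* ``codon_pairs.tsv``       per codon pair: S/N by ancestral state, mean d by direction
* ``recomb_classes.tsv`` / ``segments.tsv``   when a recombination map exists
* ``dropped.tsv``           per-column drop log with reasons
* ``manifest.json``         seed, thresholds, and per-stage counts

Reruns with the same config and seed produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import summaries_to_frame, summarize_by_class
from .genetic_code import DEGENERACY, amino_acid
from .preference import (
    GeneUsageProfile,
    PreferenceTable,
    infer_preference_table,
    load_reference_scores,
)
from .recomb import RecombinationMap, assign_rate, bin_rate_classes, class_summaries, segment_summaries
from .sfs import (
    asm_randomized_permutation_test,
    permutation_test,
    shift_tests,
    two_way_anova,
)
from .neutral import NeutralModelParams
from .simulate import SimulatedDataset, SimulationParams, read_dataset, simulate_sites
from .sites import (
    CallResult,
    GeneModel,
    StrainAlignment,
    apply_masks,
    call_sites,
    combine_results,
    validate_gene,
)


@dataclass
class RunConfig:
    seed: int
    input_dir: str | None = None
    simulate: SimulationParams | None = None
    out_dir: str = "results"
    k: int = 11
    quality_min: int = 30
    coverage_min: int = 15
    preference_source: str = "fixture"  # "fixture" | "infer"
    replicates: int = 10_000
    assignment_draws: int = 10
    exclude_singletons: bool = False
    min_segment_sites: float = 5000.0

    def __post_init__(self) -> None:
        if self.input_dir is None and self.simulate is None:
            raise ValueError("either input_dir or simulate params required")
        if self.preference_source not in ("fixture", "infer"):
            raise ValueError("preference_source must be 'fixture' or 'infer'")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _profiles_from_codon_counts(codon_counts_by_gene: dict[str, dict[str, int]]) -> list[GeneUsageProfile]:
    profiles = []
    for gene, counts in codon_counts_by_gene.items():
        degenerate = {
            c: n for c, n in counts.items() if DEGENERACY[amino_acid(c)] > 1
        }
        if degenerate:
            profiles.append(GeneUsageProfile(gene=gene, counts=degenerate))
    return profiles


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole pipeline; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "quality_min": config.quality_min,
            "coverage_min": config.coverage_min,
            "min_segment_sites": config.min_segment_sites,
        },
        "counts": {},
        "warnings": [],
    }

    # ---- data ------------------------------------------------------------
    try:
        if config.simulate is not None:
            ds = simulate_sites(config.simulate)
            alignments, models, rmap = ds.alignments, ds.models, ds.rmap
            manifest["counts"]["truth_sites"] = int(len(ds.truth))
        else:
            alignments, models, rmap = read_dataset(config.input_dir)
            ds = None
    except Exception as e:  # noqa: BLE001
        raise StageError("load", e) from e

    # ---- gene filters ----------------------------------------------------
    try:
        kept: list[tuple[StrainAlignment, GeneModel]] = []
        reasons: dict[str, int] = {}
        for aln, model in zip(alignments, models):
            ok, reason = validate_gene(model, aln.ingroup[0])
            if ok:
                kept.append((aln, model))
            else:
                reasons[reason] = reasons.get(reason, 0) + 1
        manifest["counts"]["genes_total"] = len(models)
        manifest["counts"]["genes_included"] = len(kept)
        manifest["counts"]["genes_excluded_by_reason"] = reasons
        if not kept:
            raise ValueError("no gene passed the inclusion filters")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("gene-filter", e) from e

    # ---- masks + preference table ---------------------------------------
    try:
        masked = [
            (apply_masks(aln, config.quality_min, config.coverage_min), model)
            for aln, model in kept
        ]
    except Exception as e:  # noqa: BLE001
        raise StageError("mask", e) from e

    try:
        if config.preference_source == "fixture":
            table = load_reference_scores()
        else:
            pre = [call_sites(aln, model, table=None) for aln, model in masked]
            counts_by_gene = {
                model.gene: dict(zip(r.codon_counts["codon"], r.codon_counts["count"]))
                for (aln, model), r in zip(masked, pre)
            }
            table = infer_preference_table(_profiles_from_codon_counts(counts_by_gene))
        table.to_tsv(out / "preference_table.tsv")
    except Exception as e:  # noqa: BLE001
        raise StageError("preference", e) from e

    # ---- site calling ----------------------------------------------------
    try:
        per_gene = [call_sites(aln, model, table=table) for aln, model in masked]
        combined = combine_results(per_gene)
        sites = combined.sites
        totals = combined.totals
        sites.to_csv(out / "site_table.tsv", sep="\t", index=False)
        combined.dropped.to_csv(out / "dropped.tsv", sep="\t", index=False)
        manifest["counts"]["sites_called"] = int(len(sites))
        manifest["counts"]["sites_synonymous"] = int((sites["site_type"] == "synonymous").sum())
        manifest["counts"]["sites_intron"] = int((sites["site_type"] == "intron").sum())
        manifest["counts"]["sites_dropped"] = int(len(combined.dropped))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("call-sites", e) from e

    # ---- diversity -------------------------------------------------------
    try:
        totals_cls = totals.rename(columns={"class": "cls"})
        syn_sites = sites[sites["site_type"] == "synonymous"].copy()
        syn_sites["cls"] = syn_sites["amino_acid"]
        overall = sites.copy()
        overall["cls"] = overall["site_type"]
        div_rows = summarize_by_class(overall, totals_cls[totals_cls["cls"].isin(["synonymous", "intron"])], "cls", config.k)
        div_rows += summarize_by_class(syn_sites, totals_cls[~totals_cls["cls"].isin(["synonymous", "intron"])], "cls", config.k)
        div = summaries_to_frame(div_rows)
        div.to_csv(out / "diversity.tsv", sep="\t", index=False)
        theta_syn = float(div.loc[div["class"] == "synonymous", "theta_w_per_bp"].iloc[0])
        div_syn = float(div.loc[div["class"] == "synonymous", "D_per_bp"].iloc[0])
    except Exception as e:  # noqa: BLE001
        raise StageError("diversity", e) from e

    # ---- SFS tests -------------------------------------------------------
    try:
        test_rows = []
        syn = sites[(sites["site_type"] == "synonymous") & sites["delta_pref"].notna()]
        rng = np.random.default_rng(config.seed)
        variants = [("all", syn)]
        if config.exclude_singletons:
            nonsing = syn[(syn["d"] > 1) & (syn["d"] < config.k - 1)]
            variants.append(("no-singletons", nonsing))
        for label, subset in variants:
            up = subset.loc[subset["delta_pref"] > 0, "d"].to_numpy()
            pu = subset.loc[subset["delta_pref"] < 0, "d"].to_numpy()
            if up.size == 0 or pu.size == 0:
                manifest["warnings"].append(f"sfs-tests[{label}]: empty direction group")
                continue
            t_res, u_res = shift_tests(up, pu)
            perm = permutation_test(
                subset["d"].to_numpy(), subset["delta_pref"].to_numpy(),
                replicates=config.replicates, seed=rng,
            )
            for res in (t_res, u_res, perm):
                test_rows.append({
                    "subset": label, "test": res.name, "statistic": res.statistic,
                    "p_value": res.p_value, "mean_d_up": float(up.mean()),
                    "mean_d_pu": float(pu.mean()), "n_up": int(up.size), "n_pu": int(pu.size),
                })
            if div_syn > (config.k - 1) / config.k * theta_syn and label == "all":
                params = NeutralModelParams(k=config.k, theta=theta_syn, div=div_syn)
                asm = asm_randomized_permutation_test(
                    subset["d"].to_numpy(), subset["delta_pref"].to_numpy(),
                    params=params, replicates=config.replicates,
                    assignment_draws=config.assignment_draws, seed=rng,
                )
                test_rows.append({
                    "subset": label, "test": asm.name, "statistic": asm.statistic,
                    "p_value": asm.p_value, "mean_d_up": float(up.mean()),
                    "mean_d_pu": float(pu.mean()), "n_up": int(up.size), "n_pu": int(pu.size),
                })
        pd.DataFrame(test_rows).to_csv(out / "sfs_tests.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("sfs-tests", e) from e

    # ---- site type x direction ANOVA ------------------------------------
    try:
        anova_rows = []
        for pair in ("C/T", "G/A"):
            syn_pair = sites[(sites["site_type"] == "synonymous") & (sites["pair"] == pair)]
            bases = set(pair.split("/"))
            intron_pair = sites[
                (sites["site_type"] == "intron")
                & sites["anc_base"].isin(bases)
                & sites["der_base"].isin(bases)
            ]
            if len(syn_pair) < 4 or len(intron_pair) < 4:
                manifest["warnings"].append(f"anova[{pair}]: too few sites")
                continue
            both = pd.concat([syn_pair, intron_pair])
            direction = both["anc_base"] + ">" + both["der_base"]
            if direction.nunique() < 2 or both["site_type"].nunique() < 2:
                manifest["warnings"].append(f"anova[{pair}]: degenerate design")
                continue
            try:
                tab = two_way_anova(both["d"], both["site_type"], direction)
            except ValueError as err:
                manifest["warnings"].append(f"anova[{pair}]: {err}")
                continue
            tab = tab.reset_index(names="effect")
            tab.insert(0, "base_pair", pair)
            anova_rows.append(tab)
        if anova_rows:
            pd.concat(anova_rows, ignore_index=True).to_csv(out / "anova.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("anova", e) from e

    # ---- codon-pair summary ---------------------------------------------
    try:
        counts = dict(zip(combined.codon_counts["codon"], combined.codon_counts["count"]))
        pair_rows = []
        syn2 = sites[sites["site_type"] == "synonymous"]
        for (pair, aa), grp in syn2[syn2["pair"].isin(["C/T", "G/A"])].groupby(["pair", "amino_acid"]):
            hi, lo = pair.split("/")  # C/T -> C-ending vs T-ending, G/A likewise
            anc_hi = grp[grp["anc_base"] == hi]
            anc_lo = grp[grp["anc_base"] == lo]
            n_hi = sum(n for c, n in counts.items() if amino_acid(c) == aa and c[2] == hi)
            n_lo = sum(n for c, n in counts.items() if amino_acid(c) == aa and c[2] == lo)
            pair_rows.append({
                "pair": pair, "amino_acid": aa,
                "S_cg": int(len(anc_hi)), "N_cg": int(n_hi),
                "S_ta": int(len(anc_lo)), "N_ta": int(n_lo),
                "mean_d_cg_to_ta": float(anc_hi["d"].mean()) if len(anc_hi) else np.nan,
                "mean_d_ta_to_cg": float(anc_lo["d"].mean()) if len(anc_lo) else np.nan,
            })
        pd.DataFrame(pair_rows).to_csv(out / "codon_pairs.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("codon-pairs", e) from e

    # ---- recombination ---------------------------------------------------
    if rmap is None:
        manifest["warnings"].append("no recombination map: recombination reports skipped")
    else:
        try:
            assigned = assign_rate(sites["chrom_position"].to_numpy(), rmap)
            sites = sites.assign(segment_id=assigned["segment_id"].to_numpy(),
                                 rate=assigned["rate"].to_numpy())
            sites.to_csv(out / "site_table.tsv", sep="\t", index=False)
            # Per-gene L assigned to the gene's segment (gene midpoint).
            gene_L = {}
            for (aln, model), r in zip(masked, per_gene):
                L = float(r.totals.loc[r.totals["class"] == "synonymous", "L"].iloc[0])
                mid = model.chrom_start + 1
                gene_L[model.gene] = (mid, L)
            gl = pd.DataFrame(
                [{"gene": g, "position": p, "L": L} for g, (p, L) in gene_L.items()]
            )
            ga = assign_rate(gl["position"].to_numpy(), rmap)
            gl["segment_id"] = ga["segment_id"].to_numpy()
            gl["rate"] = ga["rate"].to_numpy()
            seg_totals = gl.dropna(subset=["segment_id"]).groupby("segment_id", as_index=False)["L"].sum()
            segs = segment_summaries(sites, seg_totals, rmap, k=config.k,
                                     min_sites=config.min_segment_sites)
            segs.to_csv(out / "segments.tsv", sep="\t", index=False)
            gl["rate_class"] = bin_rate_classes(gl["rate"]).to_numpy()
            cls_totals = gl[gl["rate_class"] >= 0].groupby("rate_class", as_index=False)["L"].sum()
            syn_rate = sites[sites["site_type"] == "synonymous"]
            cls = class_summaries(syn_rate, cls_totals, k=config.k)
            cls.to_csv(out / "recomb_classes.tsv", sep="\t", index=False)
            manifest["counts"]["sites_rate_assigned"] = int(sites["rate"].notna().sum())
        except Exception as e:  # noqa: BLE001
            raise StageError("recombination", e) from e

    manifest["counts"]["theta_syn"] = theta_syn
    manifest["counts"]["div_syn"] = div_syn
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
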