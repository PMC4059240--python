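"""Diversity against recombination rate on a synthetic two-testcross map.

Simulates a chromosome whose per-segment diversity rises with recombination
rate until ~2 cM/Mb, assigns averaged rates to called sites, bins them into
0.25-cM/Mb classes, and reports the class-level correlation between rate and
Watterson's theta (and the absence of one for Fop).
"""

import pandas as pd

from codonsfs import (
    RecombMapSpec,
    SimulationParams,
    assign_rate,
    correlate,
    load_reference_scores,
    simulate_sites,
)
from codonsfs.recomb import bin_rate_classes, class_summaries
from codonsfs.sites import call_sites, combine_results

ds = simulate_sites(
    SimulationParams(
        seed=11, n_genes=120, gene_length_codons=250, gamma=1.0,
        recomb=RecombMapSpec(n_segments=40),
    )
)
table = load_reference_scores()
res = combine_results(
    [call_sites(a, m, table) for a, m in zip(ds.alignments, ds.models)]
)
sites = res.sites
assigned = assign_rate(sites["chrom_position"].to_numpy(), ds.rmap)
sites = sites.assign(rate=assigned["rate"].to_numpy())
syn = sites[(sites["site_type"] == "synonymous") & sites["rate"].notna()].copy()

# class totals: resolved synonymous sites apportioned by gene midpoint rate,
# plus a class-level Fop over every resolved codon (not just polymorphic ones)
per_gene = [call_sites(a, m, table) for a, m in zip(ds.alignments, ds.models)]
gene_rate = assign_rate(
    pd.Series([m.chrom_start + 1 for m in ds.models]).to_numpy(), ds.rmap
)["rate"]
rows = []
for r, rate in zip(per_gene, gene_rate):
    counts = {
        c: n for c, n in zip(r.codon_counts["codon"], r.codon_counts["count"])
        if c in table.scores  # degenerate codons only
    }
    pref = sum(n for c, n in counts.items() if table.preferred(c))
    rows.append({
        "rate": rate,
        "L": float(r.totals.loc[r.totals["class"] == "synonymous", "L"].iloc[0]),
        "pref": pref,
        "codons": sum(counts.values()),
    })
gl = pd.DataFrame(rows).dropna()
gl["rate_class"] = bin_rate_classes(gl["rate"]).to_numpy()
totals = gl.groupby("rate_class", as_index=False)[["L", "pref", "codons"]].sum()
totals["fop_class"] = totals["pref"] / totals["codons"]

summary = class_summaries(syn, totals[["rate_class", "L"]])
summary = summary.merge(totals[["rate_class", "fop_class"]], on="rate_class")
print(summary[["label", "S", "L", "theta_w_per_bp", "fop_class"]].to_string(index=False))

ok = summary[summary["S"] > 0]
r_theta, df, p = correlate(ok["upper_rate"], ok["theta_w_per_bp"])
print(f"\nrate vs theta:  r = {r_theta:.3f} ({df} d.f., 1-tailed p = {p:.2g})")
r_fop, df, p = correlate(ok["upper_rate"], ok["fop_class"])
print(f"rate vs Fop:    r = {r_fop:.3f} ({df} d.f., 1-tailed p = {p:.2g})")
print("\nDiversity tracks the planted rate coupling; gene codon-usage bias was")
print("planted independently of rate, so the Fop correlation has no signal.")
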