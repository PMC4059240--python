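"""End-to-end run: simulate selected data, call sites, test the SFS shift.

Generates a synthetic chromosome with planted selection on codon usage
(gamma = 1 per unit delta-pref), ancestral-state misassignment from outgroup
divergence, and a recombination map; runs the full pipeline; and prints the
headline contrasts.
"""

import json
from pathlib import Path
from tempfile import mkdtemp

import pandas as pd

from codonsfs import RecombMapSpec, RunConfig, SimulationParams, run_full_analysis

out = Path(mkdtemp(prefix="codonsfs_example_"))
config = RunConfig(
    seed=7,
    simulate=SimulationParams(
        seed=7, n_genes=80, gene_length_codons=300, gamma=1.0,
        recomb=RecombMapSpec(n_segments=15), mask_fail_rate=0.002,
    ),
    out_dir=str(out),
    replicates=20_000,
    exclude_singletons=True,
)
manifest = run_full_analysis(config)
print("per-stage counts:", json.dumps(manifest["counts"], indent=2, sort_keys=True))

tests = pd.read_csv(out / "sfs_tests.tsv", sep="\t")
print("\nSFS shift tests (one-tailed):")
print(tests[["subset", "test", "statistic", "p_value", "mean_d_up", "mean_d_pu"]]
      .to_string(index=False))
print("\nU->P sites segregate at higher derived counts than P->U sites when")
print("selection favors preferred codons; the permutation test on")
print("sum(d x delta-pref) and its ASM-randomized variant agree.")
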