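"""Shared helpers for building synthetic gene-usage profiles in tests."""

import numpy as np

from codonsfs.genetic_code import DEGENERATE_AMINO_ACIDS, SYNONYMS
from codonsfs.preference import GeneUsageProfile


def biased_profiles(ref_table, rng, n_genes=40, n_per_aa=80):
    """Genes spanning a range of bias toward the reference preferred set."""
    profiles = []
    for g in range(n_genes):
        bias = rng.uniform(0.0, 2.5)
        counts = {}
        for aa in DEGENERATE_AMINO_ACIDS:
            syns = SYNONYMS[aa]
            scores = np.array([ref_table.score(c) for c in syns])
            p = np.exp(bias * scores)
            p /= p.sum()
            for c, n in zip(syns, rng.multinomial(n_per_aa, p)):
                counts[c] = int(n) + 1  # keep all amino acids used
        profiles.append(GeneUsageProfile(gene=f"g{g}", counts=counts))
    return profiles
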