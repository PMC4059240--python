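"""Neutral, ASM, and sequencing-error null expectations for k = 11.

Prints the constant-size neutral SFS constants, then asks three questions of
the ancestral-state-misassignment (ASM) forward model and the binomial
sequencing-error model at the chromosome-2 parameterization
(theta = 0.0222/site, divergence = 0.0763/site).
"""

from codonsfs import (
    NeutralModelParams,
    apparent_singleton_fraction,
    asm_forward_sfs,
    neutral_mean_d,
    neutral_sfs,
    nonsingleton_mean,
    solve_equal_tail_divergence,
    solve_error_rate,
    tail_ratio,
)

K, THETA, DIV = 11, 0.0222, 0.0763

print(f"neutral mean derived count (k={K}):     {neutral_mean_d(K):.3f}")
print(f"neutral singleton share:                {neutral_sfs(K)[0]:.3f}")
print(f"neutral nonsingleton mean:              {nonsingleton_mean(K):.3f}")

# ASM: a substitution on the outgroup branch flips apparent polarity, raising
# the high-frequency tail of the presented SFS.
params = NeutralModelParams(k=K, theta=THETA, div=DIV)
print(f"\npresented 10:9 tail ratio at D={DIV}:  {tail_ratio(params):.3f}")
d_eq = solve_equal_tail_divergence(THETA, K)
pres = asm_forward_sfs(neutral_sfs(K), NeutralModelParams(k=K, theta=THETA, div=d_eq))
print(f"divergence for a 1:1 tail:              {d_eq:.4f}")
print(f"tail mass in each class there:          {100 * pres[-1]:.1f}%")

# Sequencing error inflates apparent singletons above the neutral 34.1%.
print(f"\nsingleton share at error rate 0.1%:     {apparent_singleton_fraction(THETA, K, 0.001):.3f}")
eps = solve_error_rate(THETA, K, 0.551)
print(f"error rate needed for 55.1% singletons: {100 * eps:.2f}%")
print("\nA tail ratio above 1 needs ASM; a singleton share above ~42% at")
print("phred-30 error rates needs more than sequencing error alone.")
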