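"""Neutral-model expectations, ancestral-state misassignment, sequencing error.

All quantities refer to the unfolded site frequency spectrum (SFS) of a sample
of ``k`` sequences polarized against an outgroup.  Under a constant-size
Wright-Fisher neutral model the expected relative frequency of sites with
``d`` derived copies is proportional to 1/d, so the mean derived count is
(k-1)/a_k with a_k the (k-1)-th harmonic number.

Ancestral-state misassignment (ASM) arises when a substitution on the branch
to the outgroup makes the true derived allele look ancestral; a site with true
derived count d then presents as k-d.  The prior odds of a correct parsimony
polarization are 1/b with b = D - ((k-1)/k)*theta, the expected density of
substitutions on the outgroup branch beyond those already counted in the
ingroup coalescent; combined with the neutral likelihood ratio (k-d)/d this
gives the posterior odds of Eq.-style Bayesian polarity correction.

Sequencing errors are modelled as independent per-sequence base miscalls that
all produce the same (derived) state, so a truly invariant site presents j
derived copies with binomial probability C(k,j) eps^j (1-eps)^(k-j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


def harmonic(k: int) -> float:
    """a_k = sum_{i=1}^{k-1} 1/i, the Watterson denominator for sample size k."""
    if k < 2:
        raise ValueError("sample size k must be >= 2")
    return float(np.sum(1.0 / np.arange(1, k)))


@dataclass
class NeutralModelParams:
    """Per-class parameters of the neutral/ASM/error null model.

    theta and div are per-site estimates (Watterson's theta and outgroup
    divergence); ``b`` is the outgroup-branch substitution density
    D - ((k-1)/k)*theta, which must be positive for polarity odds to be
    defined; ``eps`` is the per-base per-sequence error rate.
    """

    k: int = 11
    theta: float = 0.0
    div: float = 0.0
    eps: float = 0.0
    label: str = "all"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not 0 <= self.eps < 1:
            raise ValueError("eps must be in [0, 1)")

    @property
    def b(self) -> float:
        return self.div - (self.k - 1) / self.k * self.theta

    @property
    def flip_probability(self) -> float:
        """Probability that the outgroup carries the derived state: b/(1+b)."""
        b = self.b
        if b < 0:
            raise ValueError(
                f"divergence {self.div} below ingroup expectation; b={b} < 0"
            )
        return b / (1.0 + b)


def neutral_sfs(k: int) -> np.ndarray:
    """Expected neutral proportions over derived counts d = 1..k-1."""
    d = np.arange(1, k)
    p = 1.0 / d
    return p / p.sum()


def neutral_mean_d(k: int) -> float:
    """(k-1)/a_k, the neutral expectation of the mean derived count."""
    return (k - 1) / harmonic(k)


def nonsingleton_mean(k: int) -> float:
    """Neutral mean derived count excluding d in {1, k-1}.

    Both d=1 and d=k-1 are treated as singletons (the latter being a
    singleton under the opposite polarization).
    """
    if k < 4:
        raise ValueError("k must be >= 4 to have nonsingleton classes")
    d = np.arange(2, k - 1)
    w = 1.0 / d
    return float((d * w).sum() / w.sum())


def posterior_odds(d: int, params: NeutralModelParams) -> float:
    """Posterior odds that the parsimony polarization of a site is correct.

    odds = ((k-d)/d) * (1/b): the neutral likelihood ratio of true count d
    versus k-d, times the prior odds of no substitution on the outgroup
    branch.  P(ASM) = 1/(1+odds).
    """
    k = params.k
    if not 1 <= d <= k - 1:
        raise ValueError(f"d={d} outside 1..{k - 1}")
    b = params.b
    if b <= 0:
        raise ValueError(f"prior odds undefined: b={b} <= 0")
    return (k - d) / d / b


def asm_probability(d: int, params: NeutralModelParams) -> float:
    """Probability that a parsimony-polarized site with count d is misassigned."""
    return 1.0 / (1.0 + posterior_odds(d, params))


def asm_forward_sfs(true_proportions: np.ndarray, params: NeutralModelParams) -> np.ndarray:
    """SFS presented under ASM: each class d flips to k-d with prob b/(1+b)."""
    p = np.asarray(true_proportions, dtype=float)
    k = params.k
    if p.shape != (k - 1,):
        raise ValueError(f"expected {k - 1} classes, got {p.shape}")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("true proportions must be nonnegative and sum to 1")
    f = params.flip_probability
    return p * (1.0 - f) + p[::-1] * f


def tail_ratio(params: NeutralModelParams) -> float:
    """presented(k-1)/presented(k-2) of the neutral SFS after ASM flips."""
    pres = asm_forward_sfs(neutral_sfs(params.k), params)
    return float(pres[-1] / pres[-2])


def solve_equal_tail_divergence(theta: float, k: int = 11) -> float:
    """Divergence at which ASM makes presented(k-2) and presented(k-1) equal.

    On the 1/d neutral SFS the condition presented(k-2) = presented(k-1)
    gives a closed form for the flip probability f, hence for
    b = f/(1-f) and D = b + ((k-1)/k)*theta.  The flip exchanges classes
    1 <-> k-1 and 2 <-> k-2, i.e. it factors in low-count sites presenting as
    high-count and factors out the converse.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    # (1/(k-2))(1-f) + (1/2) f = (1/(k-1))(1-f) + f  =>  b = f/(1-f):
    b = (1.0 / (k - 2) - 1.0 / (k - 1)) / (1.0 - 0.5)
    return b + (k - 1) / k * theta


def error_mixing_matrix(k: int, eps: float) -> np.ndarray:
    """P(observed count | true count) under same-state sequencing errors.

    Rows index the true derived count 0..k-1 (0 = invariant), columns the
    observed count 0..k: each of the k-d truly-ancestral copies of a
    class-d site miscalls to the derived state independently with
    probability eps, so observed = d + Binomial(k-d, eps).  An observed
    count of k means all copies present the derived state, i.e. the site
    looks invariant for the other allele.
    """
    if not 0 <= eps < 1:
        raise ValueError("eps must be in [0, 1)")
    from math import comb

    M = np.zeros((k, k + 1))
    for d in range(k):
        n = k - d
        for j in range(n + 1):
            # direct binomial pmf; robust down to subnormal eps
            M[d, d + j] = comb(n, j) * eps**j * (1.0 - eps) ** (n - j)
    return M


def apparent_singleton_fraction(theta: float, k: int = 11, eps: float = 0.0) -> float:
    """Share of observed polymorphic sites presenting exactly one derived copy.

    True per-site class frequencies are theta/d for d = 1..k-1 and
    1 - theta*a_k for invariant sites; these are pushed through the error
    mixing matrix and the observed-singleton share is taken among sites
    observed with 1..k-1 derived copies.
    """
    a = harmonic(k)
    if theta * a >= 1:
        raise ValueError("theta too large: polymorphic fraction would exceed 1")
    freq = np.zeros(k)
    freq[0] = 1.0 - theta * a
    freq[1:] = theta / np.arange(1, k)
    observed = freq @ error_mixing_matrix(k, eps)
    polymorphic = observed[1:k]
    return float(polymorphic[0] / polymorphic.sum())


def solve_error_rate(theta: float, k: int, target_singleton_fraction: float) -> float:
    """Error rate at which the apparent-singleton share reaches the target.

    Monotone root solve (bisection/Brent) of ``apparent_singleton_fraction``
    in eps; the target must exceed the eps=0 baseline 1/a_k.
    """
    base = apparent_singleton_fraction(theta, k, 0.0)
    if not base < target_singleton_fraction < 1:
        raise ValueError(
            f"target {target_singleton_fraction} outside ({base:.4f}, 1)"
        )
    # The fraction rises from 1/a_k, peaks once errors start stacking into
    # higher classes, then falls; return the smallest (left-branch) root.
    grid = np.geomspace(1e-8, 0.5, 400)
    vals = np.array([apparent_singleton_fraction(theta, k, e) for e in grid])
    above = np.nonzero(vals >= target_singleton_fraction)[0]
    if above.size == 0:
        raise ValueError(
            f"target {target_singleton_fraction} unreachable for theta={theta}, k={k}"
        )
    i = above[0]
    lo = grid[i - 1] if i > 0 else 1e-12
    return float(
        brentq(
            lambda e: apparent_singleton_fraction(theta, k, e) - target_singleton_fraction,
            lo,
            grid[i],
            xtol=1e-10,
        )
    )
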