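"""Site-frequency-spectrum contrasts and association tests for weak selection.

The central objects are the unfolded SFS of derived counts d (1..k-1) for a
class of polymorphic sites, and per-site (d, delta-pref) pairs.  Natural
selection on codon usage predicts that U->P changes segregate at higher
frequencies than P->U changes, hence:

* location shift tests between the U->P and P->U derived-count distributions
  (one-tailed t and Mann-Whitney U);
* a Monte Carlo permutation test on T = sum(d * delta-pref), whose observed
  value is compared with the distribution of T under random re-pairings of d
  with delta-pref;
* a variant of the permutation test that integrates over ancestral-state
  misassignment by redrawing each site's polarity from its posterior odds of
  correct parsimony assignment before permuting;
* regression slopes of d on delta-pref and Tukey-Kramer-style contrasts of
  slopes between groups (e.g. recombination-rate classes);
* two-way ANOVA of d on site type x direction of base change, and G-tests of
  independence on polymorphism counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .neutral import NeutralModelParams, asm_probability


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    tails: int = 1
    replicates: int | None = None
    seed: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class SFS:
    """Counts of polymorphic sites by derived count d = 1..k-1."""

    k: int
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.k - 1,):
            raise ValueError(f"need {self.k - 1} classes, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative SFS counts")

    @classmethod
    def from_d(cls, d_values, k: int, label: str = "") -> "SFS":
        d = np.asarray(d_values, dtype=int)
        if d.size and (d.min() < 1 or d.max() > k - 1):
            raise ValueError("derived counts outside 1..k-1")
        counts = np.bincount(d, minlength=k)[1:k]
        return cls(k=k, counts=counts, label=label)

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    @property
    def mean_d(self) -> float:
        n = self.n_sites
        if n == 0:
            return float("nan")
        d = np.arange(1, self.k)
        return float((d * self.counts).sum() / n)

    def proportions(self) -> np.ndarray:
        n = self.n_sites
        return self.counts / n if n else np.zeros_like(self.counts, dtype=float)

    def excluding_singletons(self) -> "SFS":
        """Drop d in {1, k-1}: both tails count as singletons."""
        c = self.counts.copy()
        c[0] = 0
        c[-1] = 0
        return SFS(k=self.k, counts=c, label=self.label + " (no singletons)")


def build_sfs(
    sites: pd.DataFrame,
    k: int,
    label: str = "",
    where: pd.Series | None = None,
    exclude_singletons: bool = False,
) -> SFS:
    """SFS of the site-table rows selected by the boolean mask ``where``."""
    d = sites["d"] if where is None else sites.loc[where, "d"]
    sfs = SFS.from_d(d.to_numpy(), k=k, label=label)
    return sfs.excluding_singletons() if exclude_singletons else sfs


def shift_tests(d_high: np.ndarray, d_low: np.ndarray) -> tuple[TestResult, TestResult]:
    """One-tailed t and Mann-Whitney U tests of H1: d_high located above d_low.

    For the selection contrast, ``d_high`` is the U->P group and ``d_low``
    the P->U group.  The U-test uses the normal approximation with tie and
    continuity corrections.
    """
    d_high = np.asarray(d_high, dtype=float)
    d_low = np.asarray(d_low, dtype=float)
    if d_high.size == 0 or d_low.size == 0:
        raise ValueError("both groups must be nonempty")
    t_stat, t_p = stats.ttest_ind(d_high, d_low, equal_var=True, alternative="greater")
    u_stat, u_p = stats.mannwhitneyu(
        d_high, d_low, alternative="greater", method="asymptotic"
    )
    return (
        TestResult(name="t-test", statistic=float(t_stat), p_value=float(t_p)),
        TestResult(name="mann-whitney-u", statistic=float(u_stat), p_value=float(u_p)),
    )


def sum_product_statistic(d: np.ndarray, dpref: np.ndarray) -> float:
    """T = sum(d * delta-pref), the permutation-test statistic."""
    return float(np.dot(np.asarray(d, float), np.asarray(dpref, float)))


def permutation_test(
    d,
    dpref,
    replicates: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> TestResult:
    """Monte Carlo permutation test of association between d and delta-pref.

    One-tailed: p is the fraction of random re-pairings of d with delta-pref
    whose sum of products strictly exceeds the observed one.  p = 0 therefore
    means no exceedance in ``replicates`` permutations (p < 1/replicates).
    If either variable is constant the statistic is permutation-invariant and
    p = 1 by construction (flagged in the result note).
    """
    d = np.asarray(d, dtype=float)
    dpref = np.asarray(dpref, dtype=float)
    if d.shape != dpref.shape or d.ndim != 1:
        raise ValueError("d and dpref must be equal-length 1-d arrays")
    if d.size < 2:
        raise ValueError("need >= 2 sites")
    t_obs = sum_product_statistic(d, dpref)
    if np.all(d == d[0]) or np.all(dpref == dpref[0]):
        return TestResult(
            name="permutation",
            statistic=t_obs,
            p_value=1.0,
            replicates=replicates,
            note="statistic invariant under permutation (constant input)",
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(replicates):
        exceed += np.dot(rng.permutation(d), dpref) > t_obs
    return TestResult(
        name="permutation",
        statistic=t_obs,
        p_value=exceed / replicates,
        replicates=replicates,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def asm_randomized_permutation_test(
    d,
    dpref,
    params: NeutralModelParams | dict[str, NeutralModelParams],
    classes=None,
    replicates: int = 100_000,
    assignment_draws: int = 20,
    seed: int | np.random.Generator | None = None,
) -> TestResult:
    """Permutation test integrating over ancestral-state misassignment.

    For each of ``assignment_draws`` polarity draws, every site keeps its
    parsimony polarization with probability odds/(1+odds) (posterior odds of
    correct assignment, computed from the site's class-specific theta and
    divergence) and otherwise flips (d -> k-d, delta-pref -> -delta-pref).
    The plain permutation test is run on each draw and the reported p-value
    is the mean over draws; the statistic reported is the mean observed T.
    """
    d = np.asarray(d, dtype=int)
    dpref = np.asarray(dpref, dtype=float)
    if isinstance(params, dict):
        if classes is None:
            raise ValueError("per-class params require a classes vector")
        classes = np.asarray(classes)
        site_params = [params[c] for c in classes]
    else:
        site_params = [params] * d.size
    k = site_params[0].k
    flip_p = np.array(
        [asm_probability(int(di), pi) for di, pi in zip(d, site_params)]
    )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pvals = []
    stats_ = []
    per_draw = max(1, replicates // assignment_draws)
    for _ in range(assignment_draws):
        flip = rng.random(d.size) < flip_p
        d_draw = np.where(flip, k - d, d).astype(float)
        dp_draw = np.where(flip, -dpref, dpref)
        res = permutation_test(d_draw, dp_draw, replicates=per_draw, seed=rng)
        pvals.append(res.p_value)
        stats_.append(res.statistic)
    return TestResult(
        name="asm-permutation",
        statistic=float(np.mean(stats_)),
        p_value=float(np.mean(pvals)),
        replicates=per_draw * assignment_draws,
        seed=None if isinstance(seed, np.random.Generator) else seed,
        note=f"mean over {assignment_draws} polarity draws",
    )


@dataclass
class SlopeFit:
    slope: float
    stderr: float
    intercept: float
    n: int
    sxx: float
    rss: float


def slope_d_on_dpref(d, dpref) -> SlopeFit:
    """Ordinary least-squares slope of d on delta-pref, with standard error."""
    d = np.asarray(d, dtype=float)
    x = np.asarray(dpref, dtype=float)
    if d.size < 3:
        raise ValueError("need >= 3 sites")
    if np.ptp(x) == 0:
        raise ValueError("delta-pref has zero variance")
    res = stats.linregress(x, d)
    sxx = float(((x - x.mean()) ** 2).sum())
    resid = d - (res.intercept + res.slope * x)
    return SlopeFit(
        slope=float(res.slope),
        stderr=float(res.stderr),
        intercept=float(res.intercept),
        n=d.size,
        sxx=sxx,
        rss=float((resid**2).sum()),
    )


def compare_slopes(
    groups: dict[str, tuple[np.ndarray, np.ndarray]],
    one_tailed: bool = True,
) -> pd.DataFrame:
    """Pairwise Tukey-Kramer contrasts of regression slopes across groups.

    Each group supplies (d, dpref); slopes are fit per group, the residual
    variance pooled over groups, and each pairwise difference referred to the
    studentized-range distribution with the number of groups and the pooled
    residual degrees of freedom.  One-tailed p-values halve the two-sided
    studentized-range tail (the direction is reported via the sign of the
    difference).  Groups whose slope cannot be fit are omitted.
    """
    fits: dict[str, SlopeFit] = {}
    for label, (d, x) in groups.items():
        try:
            fits[label] = slope_d_on_dpref(d, x)
        except ValueError:
            continue
    if len(fits) < 2:
        raise ValueError("need >= 2 groups with a valid slope")
    df_pooled = sum(f.n - 2 for f in fits.values())
    s2 = sum(f.rss for f in fits.values()) / df_pooled
    labels = list(fits)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            fa, fb = fits[a], fits[b]
            se = np.sqrt(s2 * (1.0 / fa.sxx + 1.0 / fb.sxx))
            diff = fa.slope - fb.slope
            q = abs(diff) / (se / np.sqrt(2.0))
            p = float(stats.studentized_range.sf(q, len(labels), df_pooled))
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "slope_a": fa.slope,
                    "slope_b": fb.slope,
                    "difference": diff,
                    "q": q,
                    "p_value": p / 2 if one_tailed else p,
                }
            )
    return pd.DataFrame(rows)


def two_way_anova(values, factor_a, factor_b, names=("site_type", "direction")) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction (sequential sums of squares).

    Main effects are entered before the interaction (Type I); unbalanced
    designs are allowed but every cell of the two-way layout must be
    populated.  Returns a table with SS, df, MS, F and p per effect.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(values, float),
                       "A": np.asarray(factor_a), "B": np.asarray(factor_b)})
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("each factor needs >= 2 levels")
    cells = df.groupby(["A", "B"]).size()
    full = df["A"].nunique() * df["B"].nunique()
    if len(cells) < full:
        present = set(cells.index)
        missing = [
            (a, b)
            for a in df["A"].unique()
            for b in df["B"].unique()
            if (a, b) not in present
        ]
        raise ValueError(f"empty cell(s) in two-way layout: {missing}")
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(
        index={
            "C(A)": names[0],
            "C(B)": names[1],
            "C(A):C(B)": "interaction",
            "Residual": "residual",
        },
        columns={"sum_sq": "SS", "PR(>F)": "p_value"},
    )
    table["MS"] = table["SS"] / table["df"]
    return table[["df", "SS", "MS", "F", "p_value"]]


def g_test(table) -> TestResult:
    """G-test of independence: G = 2 sum O ln(O/E), df = (r-1)(c-1).

    Expected counts come from the product of the margins; zero margins are
    rejected.  Cells with O = 0 contribute 0 to G.  The same function covers
    the one-way heterogeneity use (an r x 2 table of successes/failures).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("negative counts")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal total")
    expected = row @ col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    G = 2.0 * terms.sum()
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(G, dof))
    return TestResult(name="g-test", statistic=float(G), p_value=p, tails=2,
                      note=f"df={dof}")


def sequential_bonferroni(p_values) -> np.ndarray:
    """Holm's sequential Bonferroni adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
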