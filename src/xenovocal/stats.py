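"""Nonparametric tests used throughout the analyses.

Thin, validated wrappers around scipy.stats: a one-sample sign test (exact
binomial), the Wilcoxon signed-rank test, the Mann-Whitney U test and
one-way ANOVA. Because the study's sample sizes are small (2–26), the
paired/two-sample tests report an exact p-value where scipy can enumerate
it alongside the tie-corrected normal approximation (Z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .errors import ValidationError


@dataclass
class TestSummary:
    """Outcome of one statistical comparison."""

    test_name: str
    statistic: float  # Z, U, F or the sign count, per test
    p: float
    n: int
    df: tuple | None = None
    paired: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError("p must be in [0, 1]")


def sign_test_one_sample(x, mu0: float = 0.0) -> TestSummary:
    """Exact two-sided one-sample sign test against ``mu0``.

    Exact ties with ``mu0`` are dropped; if every value ties the test is
    undefined and a :class:`ValidationError` is raised.
    """
    d = np.asarray(x, dtype=float) - mu0
    d = d[d != 0]
    if d.size == 0:
        raise ValidationError("sign test undefined: all values tie with mu0")
    k = int((d > 0).sum())
    res = sstats.binomtest(k, d.size, 0.5, alternative="two-sided")
    return TestSummary(test_name="one_sample_sign", statistic=float(k),
                       p=float(res.pvalue), n=int(d.size))


def _signed_rank_z(d: np.ndarray) -> float:
    """Tie-corrected normal-approximation Z for the signed-rank statistic."""
    n = d.size
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        return 0.0
    # continuity correction toward the mean
    num = w_plus - mu
    num = np.sign(num) * max(abs(num) - 0.5, 0.0)
    return num / sigma


def wilcoxon_signed_rank(x, y=None) -> TestSummary:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's rule). If every difference is
    zero the test is undefined: the summary carries p = 1 with a
    ``degenerate`` flag and a warning, matching the convention that
    identical paired samples provide no evidence of a shift. ``extras``
    reports the exact enumeration p (n <= 25, no ties) and the
    normal-approximation p side by side.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.size != y.size:
            raise ValidationError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    if d.size == 0:
        raise ValidationError("empty sample")
    dz = d[d != 0]
    if dz.size == 0:
        warnings.warn("all paired differences are zero; signed-rank test "
                      "is degenerate", UserWarning, stacklevel=2)
        return TestSummary(test_name="wilcoxon_signed_rank", statistic=0.0,
                           p=1.0, n=0, paired=True,
                           extras={"degenerate": True})
    z = _signed_rank_z(dz)
    p_norm = float(2.0 * sstats.norm.sf(abs(z)))
    extras = {"p_normal": p_norm}
    p = p_norm
    has_rank_ties = np.unique(np.abs(dz)).size < dz.size
    if dz.size <= 25 and not has_rank_ties:
        exact = sstats.wilcoxon(dz, method="exact")
        extras["p_exact"] = float(exact.pvalue)
        p = float(exact.pvalue)
    return TestSummary(test_name="wilcoxon_signed_rank", statistic=float(z),
                       p=min(p, 1.0), n=int(dz.size), paired=True,
                       extras=extras)


def mann_whitney_u(x, y) -> TestSummary:
    """Two-sided Mann-Whitney U test for two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    u = float(res.statistic)
    # tie-corrected normal approximation
    all_v = np.concatenate([x, y])
    _, counts = np.unique(all_v, return_counts=True)
    tie = float(np.sum(counts ** 3 - counts))
    n = n1 + n2
    sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1))))
    z = (u - n1 * n2 / 2.0) / sigma if sigma > 0 else 0.0
    extras = {"p_normal": float(2.0 * sstats.norm.sf(abs(z)))}
    has_ties = np.unique(all_v).size < n
    if max(n1, n2) <= 25 and not has_ties:
        exact = sstats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="exact")
        extras["p_exact"] = float(exact.pvalue)
    return TestSummary(test_name="mann_whitney_u", statistic=u,
                       p=float(res.pvalue), n=n, extras={"z": float(z), **extras})


def anova_oneway(groups) -> TestSummary:
    """One-way ANOVA across two or more groups."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValidationError("each group needs at least 2 observations")
    if np.ptp(np.concatenate(arrs)) == 0:
        # all observations identical: no between- or within-group variance
        return TestSummary(test_name="anova_oneway", statistic=0.0, p=1.0,
                           n=sum(a.size for a in arrs),
                           df=(len(arrs) - 1, sum(a.size for a in arrs) - len(arrs)))
    res = sstats.f_oneway(*arrs)
    n = sum(a.size for a in arrs)
    return TestSummary(test_name="anova_oneway", statistic=float(res.statistic),
                       p=float(res.pvalue), n=n,
                       df=(len(arrs) - 1, n - len(arrs)))
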