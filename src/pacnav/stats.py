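"""Nonparametric group tests: Kruskal-Wallis with Dunn's post hoc, Mann-Whitney
U (with normal-approximation Z), and Spearman rank correlation.

Thin, well-specified wrappers over the scipy routines, plus a hand-written
Dunn's pairwise z-test (rank-mean differences with tie correction, Bonferroni
adjusted) since no post-hoc provider is bundled.  All tests are two-sided and
invariant to monotone rescaling of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

__all__ = ["TestResult", "kruskal_wallis_dunn", "mann_whitney", "spearman"]


@dataclass
class TestResult:
    statistic: float
    p: float
    groups: list[str]
    z: float | None = None
    df: int | None = None
    posthoc: list[tuple[tuple[str, str], float]] = field(default_factory=list)

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        return [pair for pair, p in self.posthoc if p < alpha]


def _dunn(samples: dict[str, np.ndarray]) -> list[tuple[tuple[str, str], float]]:
    """Dunn's pairwise z-tests on rank means, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T] (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups.
    """
    labels = list(samples)
    pooled = np.concatenate([samples[g] for g in labels])
    ranks = _st.rankdata(pooled)
    N = pooled.size
    # tie correction over the pooled sample
    _, counts = np.unique(pooled, return_counts=True)
    tie = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    mean_rank = {}
    start = 0
    for g in labels:
        n_g = samples[g].size
        mean_rank[g] = ranks[start : start + n_g].mean()
        start += n_g
    m = len(labels) * (len(labels) - 1) // 2
    out = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            ga, gb = labels[a], labels[b]
            se = np.sqrt(
                (N * (N + 1) / 12.0 - tie) * (1.0 / samples[ga].size + 1.0 / samples[gb].size)
            )
            z = (mean_rank[ga] - mean_rank[gb]) / se
            p = min(1.0, 2.0 * _st.norm.sf(abs(z)) * m)  # Bonferroni
            out.append(((ga, gb), float(p)))
    return out


def kruskal_wallis_dunn(samples: dict[str, "np.ndarray | list"]) -> TestResult:
    """Kruskal-Wallis H test across >= 3 groups with Dunn's pairwise post hoc.

    The omnibus H statistic has k-1 degrees of freedom under the chi-square
    approximation.  Post-hoc p-values are Bonferroni-adjusted across the
    k(k-1)/2 pairs.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in samples.items()}
    if len(groups) < 3:
        raise ValueError("kruskal_wallis_dunn needs >= 3 groups; use mann_whitney for 2")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    H, p = _st.kruskal(*groups.values())
    return TestResult(
        statistic=float(H),
        p=float(p),
        df=len(groups) - 1,
        groups=list(groups),
        posthoc=_dunn(groups),
    )


def mann_whitney(a, b, labels: tuple[str, str] = ("a", "b")) -> TestResult:
    """Two-sided Mann-Whitney U test, reporting min(U1, U2) and the tie-corrected
    normal-approximation Z.

    The p-value follows scipy's policy (exact for small untied samples, normal
    approximation otherwise).  Z is signed by the rank-sum of the first sample:
    swapping the samples flips Z's sign but leaves U and p unchanged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    res = _st.mannwhitneyu(a, b, alternative="two-sided")
    n1, n2 = a.size, b.size
    u1 = float(res.statistic)
    u = min(u1, n1 * n2 - u1)
    # tie-corrected normal approximation for Z
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    return TestResult(
        statistic=float(u), z=float(z), p=float(res.pvalue), groups=list(labels)
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (r_S, two-sided p) with tie handling.

    Constant input has undefined rank correlation; returns (NaN, NaN) rather
    than a spurious 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), float("nan"))
    res = _st.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
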