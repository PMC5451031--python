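"""Two-group statistical comparison machinery.

Numeric features pass through a normality gate (one-sample K-S against a
normal with sample-estimated parameters, Lilliefors-corrected by default);
both samples normal selects Welch's unequal-variance t, otherwise the
two-tailed Mann-Whitney U (exact enumeration for small tie-free samples,
normal approximation with tie correction and no continuity correction
otherwise).  Categorical features use Pearson's chi-squared on the 2x2
table without Yates correction, falling back to Fisher's exact test when
any expected cell drops below 5.  Significance is assessed against the
Bonferroni per-family threshold alpha/m; term enrichment reports
DAVID-style inflated p-values min(1, m*p) instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

__all__ = [
    "ComparisonSpec",
    "TestResult",
    "EnrichmentResult",
    "normality_gate",
    "compare_numeric",
    "compare_categorical",
    "bonferroni_threshold",
    "term_enrichment",
]


@dataclass(frozen=True)
class ComparisonSpec:
    """What is being compared and under which multiple-testing family."""

    feature: str
    kind: str = "numeric"  # numeric | categorical
    m: int = 1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown comparison kind {self.kind!r}")
        if self.m < 1:
            raise ValueError("family size m must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class TestResult:
    feature: str
    summary_a: float
    summary_b: float
    test: str  # welch_t | mann_whitney_u | chi_squared | fisher_exact
    statistic: float
    p: float
    threshold: float
    significant: bool


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    query_hits: int
    query_size: int
    background_hits: int
    background_size: int
    fold_enrichment: float
    p: float
    corrected_p: float


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold alpha/m for a family of m tests."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return alpha / m


def normality_gate(sample, alpha: float = 0.05, lilliefors: bool = True) -> bool:
    """True iff the sample is compatible with a normal distribution.

    K-S against a normal with mean/SD estimated from the sample.  With
    estimated parameters the plain K-S p-value is anti-conservative, so the
    Lilliefors-corrected test is the default; ``lilliefors=False`` exposes
    the uncorrected variant.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError(f"normality gate needs n >= 8, got n={x.size}")
    sd = x.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        return False
    if lilliefors:
        _, p = _lilliefors(x, dist="norm", pvalmethod="table")
    else:
        _, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return bool(p > alpha)


def _mwu(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    tie_free = np.unique(np.concatenate([a, b])).size == a.size + b.size
    if tie_free and max(a.size, b.size) <= 20:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def compare_numeric(a, b, spec: ComparisonSpec) -> TestResult:
    """Gate both samples; Welch t if both normal, else two-tailed MWU."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"{spec.feature}: empty sample")

    def _gate(x: np.ndarray) -> bool:
        if x.size < 8:
            return False
        return normality_gate(x, alpha=spec.alpha)

    if _gate(a) and _gate(b):
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        test = "welch_t"
        stat, p = float(stat), float(p)
    else:
        stat, p = _mwu(a, b)
        test = "mann_whitney_u"
    threshold = bonferroni_threshold(spec.m, spec.alpha)
    return TestResult(
        feature=spec.feature,
        summary_a=float(np.median(a)),
        summary_b=float(np.median(b)),
        test=test,
        statistic=stat,
        p=min(p, 1.0),
        threshold=threshold,
        significant=bool(p <= threshold),
    )


def compare_categorical(k_a: int, n_a: int, k_b: int, n_b: int,
                        spec: ComparisonSpec) -> TestResult:
    """Pearson chi-squared on the 2x2 table (no continuity correction);
    Fisher exact fallback when any expected cell < 5."""
    for k, n in ((k_a, n_a), (k_b, n_b)):
        if n <= 0:
            raise ValueError(f"{spec.feature}: group total must be > 0")
        if not 0 <= k <= n:
            raise ValueError(f"{spec.feature}: successes {k} outside [0, {n}]")
    table = np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.any(table.sum(axis=0) == 0):
        # degenerate: a margin is empty, no association testable
        test, stat, p = "chi_squared", 0.0, 1.0
    elif np.any(expected < 5.0) or np.any(table == 0):
        stat, p = sps.fisher_exact(table.astype(int), alternative="two-sided")
        test = "fisher_exact"
        stat, p = float(stat), float(p)
    else:
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        test = "chi_squared"
        stat, p = float(stat), float(p)
    threshold = bonferroni_threshold(spec.m, spec.alpha)
    return TestResult(
        feature=spec.feature,
        summary_a=100.0 * k_a / n_a,
        summary_b=100.0 * k_b / n_b,
        test=test,
        statistic=stat,
        p=min(p, 1.0),
        threshold=threshold,
        significant=bool(p <= threshold),
    )


def term_enrichment(query: set, background: set,
                    term_annotations: dict[str, set],
                    alpha: float = 0.05) -> list[EnrichmentResult]:
    """One-tailed Fisher over-representation per term, Bonferroni-inflated.

    ``term_annotations`` maps term id -> set of annotated background genes.
    Results are sorted by corrected p-value.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError("query gene set must be a subset of the background")
    terms = {t: set(g) & background for t, g in term_annotations.items()}
    for t, genes in terms.items():
        if not genes:
            raise ValueError(f"term {t!r} annotates no background gene")
    m = len(terms)
    nq, nb = len(query), len(background)
    out = []
    for t, genes in terms.items():
        q_hits = len(genes & query)
        b_hits = len(genes)
        table = [[q_hits, nq - q_hits],
                 [b_hits - q_hits, (nb - nq) - (b_hits - q_hits)]]
        _, p = sps.fisher_exact(table, alternative="greater")
        fold = (q_hits / nq) / (b_hits / nb) if nq else 0.0
        out.append(EnrichmentResult(
            term=t, query_hits=q_hits, query_size=nq,
            background_hits=b_hits, background_size=nb,
            fold_enrichment=fold, p=float(p),
            corrected_p=min(1.0, m * float(p)),
        ))
    out.sort(key=lambda r: (r.corrected_p, r.p, r.term))
    return out
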