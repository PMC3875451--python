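"""Confronting observed offspring counts with model expectations.

Offspring phenotype counts from a cross are compared with survivor-level
expectations of the two-locus model through Pearson chi-square (or exact
multinomial) goodness-of-fit, and competing parental-genotype classes and
allele hypotheses are ranked by multinomial log-likelihood.  A pooled
two-sample t-test compares survival-rate groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from scipy.stats import ttest_ind

from .genetic_model import (
    AlleleModel,
    GenotypePairClass,
    OBSERVABLE_CATEGORIES,
    Phenotype,
    PhenotypeDistribution,
    expected_for_cross_type,
)

__all__ = [
    "ObservedCross",
    "GOFResult",
    "HypothesisEntry",
    "HypothesisRanking",
    "TTestResult",
    "reconstruct_counts",
    "multinomial_loglik",
    "goodness_of_fit",
    "rank_parent_hypotheses",
    "compare_survival",
]


@dataclass
class ObservedCross:
    """One cross: label, parental phenotypes and offspring category counts.

    ``counts`` maps observable categories (scaled, linear, irregular, mirror,
    nude) to non-negative integers summing to ``total_n``.  The lethal class
    is unobservable post-hatching and never appears here.
    """

    label: str
    parent_phenotypes: tuple[Phenotype, Phenotype]
    total_n: int
    counts: dict[Phenotype, int]
    location: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat, k in self.counts.items():
            if cat not in OBSERVABLE_CATEGORIES:
                raise ValueError(f"{cat} is not an observable offspring category")
            if k < 0:
                raise ValueError(f"negative count for {cat}")
        if self.total_n < 0:
            raise ValueError("total_n must be non-negative")
        if sum(self.counts.values()) != self.total_n:
            raise ValueError(
                f"counts sum to {sum(self.counts.values())}, expected total_n={self.total_n}"
            )


def reconstruct_counts(
    total_n: int, percentages: Mapping[Phenotype, float]
) -> dict[Phenotype, int]:
    """Convert printed per-category percentages back into integer counts.

    Each category receives ``round(pct/100 * N)`` (half away from zero); any
    residual from rounding is absorbed by the largest-count category so the
    total equals ``total_n`` exactly.
    """
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    if any(p < 0 for p in percentages.values()):
        raise ValueError("percentages must be non-negative")
    total_pct = sum(percentages.values())
    if abs(total_pct - 100.0) > 0.5:
        raise ValueError(
            f"percentages sum to {total_pct:.2f}, deviating from 100 by more than 0.5"
        )
    counts = {
        cat: int(math.floor(p / 100.0 * total_n + 0.5))
        for cat, p in percentages.items()
    }
    residual = total_n - sum(counts.values())
    if residual != 0:
        largest = max(counts, key=lambda c: counts[c])
        counts[largest] += residual
    return counts


def _merge_counts(counts: Mapping[Phenotype, int]) -> dict[Phenotype, int]:
    """Pool irregular and mirror counts into the aggregate scattered class."""
    merged = {
        c: k
        for c, k in counts.items()
        if c not in (Phenotype.IRREGULAR, Phenotype.MIRROR, Phenotype.SCATTERED)
    }
    sc = (
        counts.get(Phenotype.IRREGULAR, 0)
        + counts.get(Phenotype.MIRROR, 0)
        + counts.get(Phenotype.SCATTERED, 0)
    )
    if sc:
        merged[Phenotype.SCATTERED] = sc
    return merged


def multinomial_loglik(
    counts: Mapping[Phenotype, int],
    dist: PhenotypeDistribution,
    merge_scattered: bool = True,
) -> float:
    """Multinomial log-likelihood of observed counts under a survivor-level
    distribution, including the multinomial coefficient.

    With ``merge_scattered`` the irregular and mirror counts are pooled and
    evaluated against the aggregate scattered probability.  Returns ``-inf``
    when any non-zero count sits on a zero-probability category.
    """
    if any(k < 0 for k in counts.values()):
        raise ValueError("counts must be non-negative")
    if dist.includes_lethal and dist.prob(Phenotype.LETHAL) > 0:
        raise ValueError("log-likelihood requires a survivor-level distribution")
    if merge_scattered:
        counts = _merge_counts(counts)
        dist = dist.merge_scattered()
    n = sum(counts.values())
    loglik = float(gammaln(n + 1))
    for cat in set(counts) | set(dist.categories()):
        k = counts.get(cat, 0)
        p = float(dist.prob(cat))
        if k == 0:
            continue
        if p == 0.0:
            return -math.inf
        loglik += k * math.log(p) - float(gammaln(k + 1))
    return loglik


@dataclass(frozen=True)
class GOFResult:
    """Goodness-of-fit summary: Pearson X^2, df and a tail probability."""

    statistic: float
    df: int
    p_value: float
    method: str
    degenerate: bool = False
    expected_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("chi-square statistic cannot be negative")


def _exact_multinomial_pvalue(counts: np.ndarray, probs: np.ndarray) -> float:
    """Exact multinomial tail: total probability of outcomes no more likely
    than the observed one.  Feasible for small category spaces only."""
    keep = probs > 0
    if counts[~keep].sum() > 0:
        return 0.0
    counts = counts[keep]
    probs = probs[keep]
    n = int(counts.sum())
    k = len(counts)
    if k <= 1:
        return 1.0
    logp = np.log(probs)
    lgam = gammaln(np.arange(n + 2) + 1.0)  # lgam[c] = ln c!
    base = float(gammaln(n + 1))
    obs_ll = base - lgam[counts].sum() + float((counts * logp).sum())
    tol = 1e-9
    j = np.arange(n + 1)

    def tail2(prefix_ll: float, m: int, i0: int) -> float:
        jj = j[: m + 1]
        ll = (
            prefix_ll
            - lgam[jj]
            - lgam[m - jj]
            + jj * logp[i0]
            + (m - jj) * logp[i0 + 1]
        )
        return float(np.exp(ll[ll <= obs_ll + tol]).sum())

    if k == 2:
        return min(1.0, tail2(base, n, 0))
    total = 0.0
    if k == 3:
        for i in range(n + 1):
            total += tail2(base - lgam[i] + i * logp[0], n - i, 1)
    elif k == 4:
        for i in range(n + 1):
            pre_i = base - lgam[i] + i * logp[0]
            for m in range(n - i + 1):
                total += tail2(
                    pre_i - lgam[m] + m * logp[1], n - i - m, 2
                )
    else:  # pragma: no cover - guarded by caller
        raise ValueError("exact multinomial tail supports at most 4 categories")
    return min(1.0, total)


def goodness_of_fit(
    observed: ObservedCross,
    dist: PhenotypeDistribution,
    merge_scattered: bool = True,
    method: str = "chi-square",
) -> GOFResult:
    """Pearson chi-square (default) or exact multinomial goodness-of-fit of
    observed offspring counts against a survivor-level expectation.

    Categories with zero expected probability and zero observed count are
    dropped from the degrees of freedom.  The exact method enumerates the
    full outcome space and is offered for ``total_n <= 500`` with at most 4
    retained categories.
    """
    counts = dict(observed.counts)
    if merge_scattered:
        counts = _merge_counts(counts)
        dist = dist.merge_scattered()
    cats = sorted(
        set(counts) | set(dist.categories()), key=lambda c: list(Phenotype).index(c)
    )
    retained = [
        c for c in cats if not (float(dist.prob(c)) == 0.0 and counts.get(c, 0) == 0)
    ]
    n = observed.total_n
    expected = {c: float(dist.prob(c)) * n for c in retained}
    if any(
        float(dist.prob(c)) == 0.0 and counts.get(c, 0) > 0 for c in retained
    ):
        return GOFResult(
            statistic=math.inf,
            df=max(len(retained) - 1, 0),
            p_value=0.0,
            method="chi-square",
            expected_counts=expected,
        )
    df = len(retained) - 1
    if df <= 0:
        return GOFResult(
            statistic=0.0,
            df=0,
            p_value=1.0,
            method=method,
            degenerate=True,
            expected_counts=expected,
        )
    if any(e < 1.0 for e in expected.values()):
        warnings.warn(
            f"cross {observed.label!r}: some expected counts fall below 1; "
            "the chi-square approximation may be poor",
            UserWarning,
            stacklevel=2,
        )
    statistic = sum(
        (counts.get(c, 0) - expected[c]) ** 2 / expected[c] for c in retained
    )
    if method == "chi-square":
        p_value = float(chi2_dist.sf(statistic, df))
    elif method == "exact-multinomial":
        if n > 500 or len(retained) > 4:
            raise ValueError(
                "exact multinomial tail offered only for total_n <= 500 and "
                "at most 4 categories"
            )
        cvec = np.array([counts.get(c, 0) for c in retained])
        pvec = np.array([float(dist.prob(c)) for c in retained])
        p_value = _exact_multinomial_pvalue(cvec, pvec / pvec.sum())
    else:
        raise ValueError(f"unknown goodness-of-fit method {method!r}")
    return GOFResult(
        statistic=float(statistic),
        df=df,
        p_value=p_value,
        method=method,
        expected_counts=expected,
    )


@dataclass(frozen=True)
class HypothesisEntry:
    """One ranked hypothesis: an allele model plus a genotype-pair class."""

    model: AlleleModel
    pair_class: GenotypePairClass
    loglik: float
    rank: int

    def label(self) -> str:
        return f"[{self.model.name}] {self.pair_class.label()}"


@dataclass(frozen=True)
class HypothesisRanking:
    """Hypotheses ordered by decreasing log-likelihood.

    Ties keep hypothesis registration order (models first, then the
    enumeration order of genotype-pair classes within a model).
    """

    entries: tuple[HypothesisEntry, ...]

    @property
    def empty(self) -> bool:
        return not self.entries

    def top(self) -> HypothesisEntry:
        if self.empty:
            raise ValueError("ranking is empty")
        return self.entries[0]


def rank_parent_hypotheses(
    observed: ObservedCross,
    models: Sequence[AlleleModel],
    merge_scattered: bool = True,
) -> HypothesisRanking:
    """Rank all (model, genotype-pair class) hypotheses compatible with the
    parental phenotypes by the multinomial log-likelihood of the observed
    offspring counts.

    Expectations are survivor-conditioned before evaluation.  When
    ``merge_scattered`` is false, each model's ``scattered_split`` is applied
    so irregular and mirror counts are matched separately.
    """
    if not models:
        raise ValueError("at least one allele model must be supplied")
    ph1, ph2 = observed.parent_phenotypes
    raw: list[tuple[AlleleModel, GenotypePairClass, float]] = []
    for model in models:
        for cls in expected_for_cross_type(ph1, ph2, model):
            if cls.distribution.prob(Phenotype.LETHAL) >= 1:
                continue
            dist = cls.distribution.condition_on_survival()
            if not merge_scattered:
                dist = dist.split_scattered(model.scattered_split)
            ll = multinomial_loglik(observed.counts, dist, merge_scattered)
            raw.append((model, cls, ll))
    ordered = sorted(raw, key=lambda t: -t[2])  # stable: ties keep registration order
    entries = tuple(
        HypothesisEntry(model=m, pair_class=c, loglik=ll, rank=i + 1)
        for i, (m, c, ll) in enumerate(ordered)
    )
    return HypothesisRanking(entries)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int


def compare_survival(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sample t-test on survival percentages (pooled variance by default,
    Welch behind a flag), reporting group means and standard deviations."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    if sd_a == 0.0 and sd_b == 0.0:
        # degenerate: constant groups
        if mean_a == mean_b:
            t, p = 0.0, 1.0
        else:
            t = math.inf if mean_a > mean_b else -math.inf
            p = 0.0
    else:
        res = ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
    return TTestResult(t, p, mean_a, sd_a, mean_b, sd_b, len(a), len(b))
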