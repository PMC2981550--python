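"""Over-/under-representation of annotation terms among a kinase's substrates.

For each term the study set (substrate proteins of one family) is compared
to the background proteome by a two-sided hypergeometric test: the p-value
is the total probability of all counts in the support whose point
probability does not exceed that of the observed count (the
minimum-likelihood convention, as in the two-sided Fisher exact test).
P-values are Bonferroni-corrected per namespace over the testable terms
(terms absent from the background are untestable and excluded), and terms
with corrected p below alpha (default 1e-2) are reported as significant,
labeled over- or under-represented.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, List, Tuple

import numpy as np
from scipy.stats import hypergeom

#: Relative tolerance when comparing point probabilities, so that counts tied
#: with the observed one up to float rounding fall inside the two-sided sum.
PMF_TIE_RTOL = 1e-7

DEFAULT_ALPHA = 1e-2


def _check_support(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid population: K={K}, n={n}, N={N}")
    if not (max(0, n - (N - K)) <= k <= min(n, K)):
        raise ValueError(f"k={k} outside support for K={K}, n={n}, N={N}")


@lru_cache(maxsize=200_000)
def _support_pmf(K: int, n: int, N: int) -> Tuple[int, np.ndarray]:
    """(k_min, pmf over the whole support), computed in log space."""
    kmin = max(0, n - (N - K))
    kmax = min(n, K)
    ks = np.arange(kmin, kmax + 1)
    pmf = np.exp(hypergeom.logpmf(ks, N, K, n))
    return kmin, pmf


def hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """P(X = k) when drawing n from N with K marked: C(K,k)C(N-K,n-k)/C(N,n)."""
    _check_support(k, K, n, N)
    kmin, pmf = _support_pmf(K, n, N)
    return float(pmf[k - kmin])


def two_sided_p(k: int, K: int, n: int, N: int) -> float:
    """Minimum-likelihood two-sided hypergeometric p-value."""
    _check_support(k, K, n, N)
    kmin, pmf = _support_pmf(K, n, N)
    pk = pmf[k - kmin]
    p = float(pmf[pmf <= pk * (1.0 + PMF_TIE_RTOL)].sum())
    return min(1.0, p)


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-corrected p: min(1, m * p_raw)."""
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError(f"p_raw outside [0,1]: {p_raw}")
    return min(1.0, m * p_raw)


@dataclass(frozen=True)
class EnrichmentResult:
    """One significant term with its counts, p-values and direction."""

    namespace: str
    term_id: str
    k: int  # study-set proteins with the term
    n: int  # study-set size
    K: int  # background proteins with the term
    N: int  # background size
    p_raw: float
    p_corrected: float
    direction: str  # "over" | "under"


def select_features(
    study_ids: Iterable[str],
    matrix,
    alpha: float = DEFAULT_ALPHA,
) -> List[EnrichmentResult]:
    """Significant terms for a study set against a background-aligned matrix.

    ``matrix`` is a :class:`~hetphos.datatypes.FeatureMatrix` covering the
    background proteome (study proteins included). Bonferroni m counts the
    testable terms of this namespace (K > 0). Results with corrected p below
    ``alpha`` are returned sorted by (p_corrected, term_id); direction is
    "over" iff k/n > K/N.
    """
    study = sorted(set(study_ids))
    if not study:
        raise ValueError("empty study set")
    unknown = [p for p in study if p not in matrix._prow]
    if unknown:
        raise ValueError(f"study proteins absent from matrix: {unknown[:5]}")
    rows = [matrix.protein_row(p) for p in study]
    n = len(study)
    N = matrix.n_proteins
    ks = matrix.incidence[rows].sum(axis=0)
    Ks = matrix.incidence.sum(axis=0)
    testable = np.nonzero(Ks > 0)[0]
    m = len(testable)
    results: List[EnrichmentResult] = []
    for j in testable:
        k, K = int(ks[j]), int(Ks[j])
        p = two_sided_p(k, K, n, N)
        p_corr = bonferroni(p, m)
        if p_corr < alpha:
            direction = "over" if k / n > K / N else "under"
            results.append(
                EnrichmentResult(
                    matrix.namespace, matrix.term_ids[j], k, n, K, N, p, p_corr, direction
                )
            )
    results.sort(key=lambda r: (r.p_corrected, r.term_id))
    return results
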