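"""Robust rank aggregation via beta order-statistic tail probabilities.

For one item observed at sorted normalized ranks ``r(1) <= ... <= r(n)``
across ``n`` lists, the k-th order-statistic score is the exact binomial
upper tail ``beta_k = P[Binomial(n, r(k)) >= k]`` — the probability that
at least ``k`` of ``n`` independent Uniform(0,1) ranks fall at or below
``r(k)``.  The item's score is ``rho = min_k beta_k`` and its p-value is
the Bonferroni bound ``min(1, n * rho)`` over the ``n`` order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import RankMatrix

__all__ = [
    "RhoResult",
    "MetaSignatureRow",
    "beta_score",
    "beta_scores",
    "rho_score",
    "bonferroni_correct",
    "aggregate_signature",
]


@dataclass(frozen=True)
class RhoResult:
    """Per-item rank-aggregation score.

    Attributes
    ----------
    sorted_ranks : tuple of float
        Ascending normalized ranks, unreported lists contributing 1.0.
    beta_scores : tuple of float
        ``beta_k`` for k = 1..n.
    rho : float
        ``min_k beta_k``.
    p_item : float
        ``min(1, n * rho)``.
    n_lists : int
    n_reporting : int
        Number of lists that actually reported the item.
    """

    sorted_ranks: tuple[float, ...]
    beta_scores: tuple[float, ...]
    rho: float
    p_item: float
    n_lists: int
    n_reporting: int


@dataclass(frozen=True)
class MetaSignatureRow:
    mirna: str
    direction: str
    p_value: float
    corrected_p: float
    n_reporting_studies: int

    def __post_init__(self) -> None:
        if not self.corrected_p >= self.p_value:
            raise ValueError("corrected_p must be >= p_value")


def _validate_ranks(r_sorted: np.ndarray) -> np.ndarray:
    r = np.asarray(r_sorted, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("rank vector must be non-empty and one-dimensional")
    if np.any(np.diff(r) < 0):
        raise ValueError("ranks must be sorted ascending")
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("normalized ranks must lie in (0, 1]")
    return r


def beta_score(r_sorted, k: int) -> float:
    """Exact binomial upper-tail probability ``P[Binomial(n, r(k)) >= k]``.

    Parameters
    ----------
    r_sorted : array-like
        Ascending normalized ranks in (0, 1].
    k : int
        1-based order index, ``1 <= k <= n``.
    """
    r = _validate_ranks(r_sorted)
    n = r.size
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    # survival function at k-1 == P[X >= k]; scipy evaluates via the
    # regularized incomplete beta, stable down to ~1e-300
    return float(stats.binom.sf(k - 1, n, r[k - 1]))


def beta_scores(r_sorted) -> np.ndarray:
    """Vector of ``beta_k`` for k = 1..n."""
    r = _validate_ranks(r_sorted)
    n = r.size
    return stats.binom.sf(np.arange(n), n, r)


def rho_score(r_sorted, n_reporting: int | None = None) -> RhoResult:
    """Aggregate one item's ranks into a rho score and p-value."""
    r = _validate_ranks(r_sorted)
    betas = beta_scores(r)
    rho = float(betas.min())
    n = r.size
    if n_reporting is None:
        n_reporting = int(np.sum(r < 1.0))
    return RhoResult(
        sorted_ranks=tuple(r.tolist()),
        beta_scores=tuple(betas.tolist()),
        rho=rho,
        p_item=min(1.0, n * rho),
        n_lists=n,
        n_reporting=n_reporting,
    )


def bonferroni_correct(p: float, m: int) -> float:
    """Bonferroni correction ``min(1, p * m)``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return min(1.0, p * m)


def aggregate_signature(
    matrix: RankMatrix,
    m: int | None = None,
    alpha: float = 0.05,
    direction: str = "",
    raw_rho: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every miRNA of a rank matrix and Bonferroni-correct.

    Parameters
    ----------
    matrix : RankMatrix
        Direction-stratified normalized rank matrix; unreported cells are
        1.0 and enter the score (they cannot fake signal).
    m : int, optional
        Multiplicity for the across-miRNA Bonferroni step; must be at
        least the number of rows.  Defaults to ``max(n_rows, 2064)``.
    alpha : float
        Threshold on the corrected p-value for the significant subset.
    raw_rho : bool
        If true, ``p_value`` is the raw rho score instead of the
        per-item Bonferroni bound ``n * rho``.

    Returns
    -------
    table, significant : pandas.DataFrame
        Full table sorted by p ascending (ties by name), and the subset
        with ``corrected_p < alpha``.
    """
    n_rows = len(matrix.item_names)
    if m is None:
        m = max(n_rows, 2064)
    if m < n_rows:
        raise ValueError(f"multiplicity m={m} smaller than number of items {n_rows}")
    records = []
    for i, name in enumerate(matrix.item_names):
        r = np.sort(matrix.values[i])
        res = rho_score(r, n_reporting=int(matrix.reported_mask[i].sum()))
        p = res.rho if raw_rho else res.p_item
        records.append(
            {
                "mirna": name,
                "direction": direction,
                "n_reporting": res.n_reporting,
                "rho": res.rho,
                "p_value": p,
                "corrected_p": bonferroni_correct(p, m),
            }
        )
    table = pd.DataFrame(
        records,
        columns=["mirna", "direction", "n_reporting", "rho", "p_value", "corrected_p"],
    )
    if len(table):
        table = table.sort_values(["p_value", "mirna"]).reset_index(drop=True)
        table["significant"] = (table["corrected_p"] < alpha).astype(int)
    else:
        table["significant"] = pd.Series(dtype=int)
    significant = table[table["significant"] == 1].reset_index(drop=True)
    return table, significant
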