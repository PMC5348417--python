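"""Validated-target enrichment and miRNA–gene co-expression screening.

Covers the local functional stages: hypergeometric over-representation
of validated target sets in pathway gene sets, Benjamini–Hochberg FDR,
Fisher combination across miRNAs, correlation-distance average-linkage
ordering for heatmaps, and Pearson correlation screening of gene
expression against a miRNA profile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "TargetSet",
    "GeneSetCollection",
    "hypergeom_enrich",
    "bh_fdr",
    "enrich_targets",
    "combine_multi_mirna",
    "heatmap_order",
    "pearson_screen",
    "read_gmt",
    "read_target_sets",
    "read_expression_matrix",
]

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class TargetSet:
    """Validated target genes per miRNA, restricted to strong evidence."""

    targets: Mapping[str, frozenset[str]]
    evidence: str = "strong"

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.targets.values():
            out |= g
        return frozenset(out)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named pathway gene sets with an enrichment universe.

    On construction every pathway is restricted to the universe and
    empty pathways are removed.
    """

    sets: Mapping[str, frozenset[str]]
    names: Mapping[str, str] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        universe = self.universe
        if not universe:
            universe = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        restricted = {pid: frozenset(g) & universe for pid, g in self.sets.items()}
        restricted = {pid: g for pid, g in restricted.items() if g}
        object.__setattr__(self, "sets", restricted)
        object.__setattr__(self, "universe", universe)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set id, description, member genes, tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = frozenset(g for g in parts[2:] if g)
        names[parts[0]] = parts[1]
    return GeneSetCollection(sets=sets, names=names)


def read_target_sets(path: str | Path) -> TargetSet:
    """Read miRNA target sets from a two-column TSV (mirna, gene) or GMT."""
    path = Path(path)
    first = path.read_text().splitlines()[0]
    if first.count("\t") >= 2 and "mirna" not in first.lower():
        coll = read_gmt(path)
        return TargetSet(targets={k: v for k, v in coll.sets.items()})
    df = pd.read_csv(path, sep="\t", dtype=str)
    grouped = df.groupby(df.columns[0])[df.columns[1]].apply(frozenset)
    return TargetSet(targets=dict(grouped))


def hypergeom_enrich(
    targets: Iterable[str], pathway: Iterable[str], universe: Iterable[str]
) -> tuple[frozenset[str], float]:
    """Upper-tail hypergeometric over-representation test.

    Returns the overlap gene set and the probability of observing at
    least that overlap when ``|targets|`` genes are drawn without
    replacement from the universe with ``|pathway|`` genes marked.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    targets = frozenset(targets)
    pathway = frozenset(pathway)
    if not targets <= universe:
        warnings.warn("targets not contained in universe; restricting", stacklevel=2)
        targets = targets & universe
    pathway = pathway & universe
    overlap = targets & pathway
    x = len(overlap)
    p = float(stats.hypergeom.sf(x - 1, len(universe), len(pathway), len(targets)))
    return overlap, min(1.0, max(p, 0.0))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def enrich_targets(
    targets: Iterable[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Per-pathway hypergeometric enrichment of one target set, BH-adjusted.

    Rows: pathway_id, pathway_name, overlap_count, overlap_genes
    (comma-joined, sorted), p_value, fdr; sorted by p then pathway id.
    """
    rows = []
    for pid in sorted(collection.sets):
        overlap, p = hypergeom_enrich(targets, collection.sets[pid], collection.universe)
        rows.append(
            {
                "pathway_id": pid,
                "pathway_name": collection.names.get(pid, pid),
                "overlap_count": len(overlap),
                "overlap_genes": ",".join(sorted(overlap)),
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "pathway_id"]).reset_index(drop=True)
    return df


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: chi-square upper tail of -2 sum(ln p) with 2k df."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p == 0):
        warnings.warn("zero p-value clamped to 1e-300", stacklevel=2)
        p = np.maximum(p, _P_FLOOR)
    X = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(X, 2 * p.size))


def combine_multi_mirna(
    per_mirna_pvalues: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Combine per-miRNA enrichment p-values per pathway (Fisher's method).

    Input maps pathway id to the per-miRNA p-values for that pathway.
    Output columns: pathway_id, n_mirnas, combined_p, fdr.
    """
    rows = []
    for pid in sorted(per_mirna_pvalues):
        ps = per_mirna_pvalues[pid]
        rows.append(
            {"pathway_id": pid, "n_mirnas": len(ps), "combined_p": fisher_combine(ps)}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_fdr(df["combined_p"].to_numpy())
        df = df.sort_values(["combined_p", "pathway_id"]).reset_index(drop=True)
    return df


def correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r distances between rows.

    Zero-variance rows take distance 1 to every other row (convention).
    """
    X = np.asarray(matrix, dtype=float)
    sd = X.std(axis=1)
    ok = sd > 0
    n = X.shape[0]
    D = np.ones((n, n))
    np.fill_diagonal(D, 0.0)
    if ok.sum() >= 2:
        sub = X[ok]
        corr = np.corrcoef(sub)
        D_ok = 1.0 - corr
        idx = np.where(ok)[0]
        D[np.ix_(idx, idx)] = D_ok
        np.fill_diagonal(D, 0.0)
    return D


def heatmap_order(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average-linkage leaf orders for rows and columns of a score matrix.

    Distance is 1 - Pearson correlation; scipy's deterministic
    agglomeration (ties broken by cluster index) fixes the leaf order.

    Returns
    -------
    row_order, col_order : ndarray of int
    row_linkage : ndarray
        The row linkage matrix (for dendrogram rendering or testing).
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows")

    def _order(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        D = correlation_distance(M)
        Z = hierarchy.linkage(squareform(D, checks=False), method="average")
        return hierarchy.leaves_list(Z), Z

    row_order, row_Z = _order(X)
    if X.shape[1] >= 2:
        col_order, _ = _order(X.T)
    else:
        col_order = np.arange(X.shape[1])
    return row_order, col_order, row_Z


def pearson_screen(
    mirna_profile: pd.Series,
    expression: pd.DataFrame,
    r2_min: float = 0.1,
    p_max: float = 0.01,
    adjust_fdr: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Per-gene Pearson correlation screen against one miRNA profile.

    Samples are aligned by the intersection of sample IDs (never by
    position).  Two-sided p-values come from the t transform with
    n - 2 degrees of freedom.  Genes with zero variance are excluded and
    counted.  Rows with ``r^2 > r2_min`` and ``p < p_max`` are kept
    (filtering on the BH-adjusted p instead when ``adjust_fdr``).

    Returns
    -------
    passing : pandas.DataFrame
        Columns gene, r, r2, p_value, n_samples; sorted by r2 descending.
    n_dropped : int
        Count of constant-expression genes excluded.
    """
    shared = expression.columns.intersection(mirna_profile.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    x = mirna_profile[shared].to_numpy(dtype=float)
    E = expression[shared].to_numpy(dtype=float)
    n = len(shared)
    if x.std() == 0:
        raise ValueError("miRNA profile has zero variance")
    sd = E.std(axis=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    E = E[keep]
    genes = expression.index[keep]
    xc = x - x.mean()
    Ec = E - E.mean(axis=1, keepdims=True)
    r = (Ec @ xc) / (np.sqrt((Ec * Ec).sum(axis=1)) * np.sqrt((xc * xc).sum()))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    df = pd.DataFrame(
        {"gene": genes, "r": r, "r2": r * r, "p_value": p, "n_samples": n}
    )
    if adjust_fdr:
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
        crit = df["fdr"]
    else:
        crit = df["p_value"]
    passing = df[(df["r2"] > r2_min) & (crit < p_max)]
    passing = passing.sort_values(["r2", "gene"], ascending=[False, True]).reset_index(drop=True)
    return passing, n_dropped


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV (first column = feature ID)."""
    return pd.read_csv(path, sep="\t", index_col=0)
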