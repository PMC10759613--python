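"""Spearman correlation networks with Storey FDR filtering.

For each condition x timepoint slice, every pair of measures is tested with a
tie-aware Spearman correlation over pairwise-complete observations; the
two-sided p-value uses the t approximation t = rho*sqrt((n-2)/(1-rho^2)) with
n-2 df (p = 0 at rho = +/-1). q-values are computed over the full family of
tested pairs within the slice, and an edge is retained iff q < the threshold.
Pairs with fewer complete observations than the minimum are recorded as
untested rather than entering the q-value family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .qvalue import QvalueResult, storey_qvalues

__all__ = [
    "InsufficientPairsError",
    "SpearmanResult",
    "CorrelationGraph",
    "spearman_with_p",
    "build_graph",
]


class InsufficientPairsError(ValueError):
    """Fewer complete pairs than the configured minimum."""


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    n_pairs: int


def _spearman_p_from_rho(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def spearman_with_p(
    x, y, min_pairs: int = 10, method: str = "t"
) -> SpearmanResult:
    """Tie-aware Spearman rho with a two-sided p-value.

    ``method="t"`` uses the t approximation (standard at the study's group
    sizes); ``method="exact"`` runs a permutation test, intended for n < 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < min_pairs:
        raise InsufficientPairsError(
            f"{n} complete pairs < minimum {min_pairs}"
        )
    xs, ys = x[ok], y[ok]
    rho = float(stats.spearmanr(xs, ys).statistic)
    if method == "t":
        p = _spearman_p_from_rho(rho, n)
    elif method == "exact":
        res = stats.permutation_test(
            (xs,),
            lambda perm: stats.spearmanr(perm, ys).statistic,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=20000,
            rng=0,
        )
        p = float(res.pvalue)
    else:
        raise ValueError("method must be 't' or 'exact'")
    return SpearmanResult(rho=rho, p=p, n_pairs=n)


@dataclass
class CorrelationGraph:
    """One condition x timepoint correlation graph.

    ``edges`` columns: node_i, node_j, rho, p, q, n_pairs — only pairs with
    q below the threshold. ``tested`` carries every evaluated pair (for FDR
    diagnostics); ``untested`` lists pairs skipped for insufficient data.
    """

    condition: str
    timepoint: str
    nodes: list[str]
    edges: pd.DataFrame
    q_threshold: float = 0.05
    tested: pd.DataFrame | None = None
    untested: list[tuple[str, str]] = field(default_factory=list)
    qvalue_diagnostics: QvalueResult | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_weights(self) -> dict[tuple[str, str], float]:
        """Canonical (sorted-pair) -> rho mapping."""
        return {
            tuple(sorted((r.node_i, r.node_j))): float(r.rho)
            for r in self.edges.itertuples(index=False)
        }

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(condition=self.condition, timepoint=self.timepoint)
        g.add_nodes_from(self.nodes)
        for r in self.edges.itertuples(index=False):
            g.add_edge(
                r.node_i, r.node_j,
                rho=float(r.rho), p=float(r.p), q=float(r.q),
                n_pairs=int(r.n_pairs),
            )
        return g

    def write_edgelist(self, path: str | Path) -> None:
        self.edges.to_csv(path, index=False)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def build_graph(
    data: pd.DataFrame,
    condition: str = "",
    timepoint: str = "",
    q_threshold: float = 0.05,
    min_pairs: int = 10,
    pi0_method: str = "smoother",
) -> CorrelationGraph:
    """Build the FDR-filtered Spearman graph for one subject x measure slice.

    ``data`` is a wide subject x measure DataFrame (NaN = missing). All
    measure pairs with at least ``min_pairs`` complete observations are
    tested; Storey correction runs over that family; edges keep q < threshold.
    The node set records every column, including isolated nodes.
    """
    nodes = list(data.columns)
    if len(nodes) < 2:
        return CorrelationGraph(
            condition=condition, timepoint=timepoint, nodes=nodes,
            edges=_empty_edges(), q_threshold=q_threshold,
            tested=_empty_edges(),
        )
    # pairwise-complete, tie-aware Spearman rho for all pairs at once
    rho = data.corr(method="spearman", min_periods=max(min_pairs, 2))
    notna = data.notna().to_numpy().astype(float)
    counts = notna.T @ notna

    rows = []
    untested = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            n = int(counts[i, j])
            r = rho.iat[i, j]
            if n < min_pairs or np.isnan(r):
                untested.append((nodes[i], nodes[j]))
                continue
            rows.append(
                {
                    "node_i": nodes[i],
                    "node_j": nodes[j],
                    "rho": float(r),
                    "p": _spearman_p_from_rho(float(r), n),
                    "n_pairs": n,
                }
            )
    tested = pd.DataFrame(rows) if rows else _empty_edges()
    if len(tested):
        qres = storey_qvalues(tested["p"].to_numpy(), pi0_method=pi0_method)
        tested = tested.assign(q=qres.qvalues)
        edges = tested[tested["q"] < q_threshold].reset_index(drop=True)
    else:
        qres = None
        tested = tested.assign(q=pd.Series(dtype=float))
        edges = tested
    return CorrelationGraph(
        condition=condition,
        timepoint=timepoint,
        nodes=nodes,
        edges=edges[["node_i", "node_j", "rho", "p", "q", "n_pairs"]],
        q_threshold=q_threshold,
        tested=tested,
        untested=untested,
        qvalue_diagnostics=qres,
    )


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["node_i", "node_j", "rho", "p", "q", "n_pairs"]
    )
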