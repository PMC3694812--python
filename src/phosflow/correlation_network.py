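"""Mutant-level similarity and the stringent peptide correlation network.

Two views of the ratio matrix:

* an 8 x 8 Spearman similarity of the kinase-dead mutants, restricted per
  pair to peptides with at least 2-fold changes in both mutants (so the
  unresponsive majority does not dominate), with an average-linkage
  dendrogram on 1 - rho;
* an all-pairs Pearson network over the complete-measurement peptides,
  keeping edges with correlation-test p < 0.05 and |r| >= 0.9, lifted to a
  protein graph.  Proteins connected to more than one distinct partner
  (self-connections from two peptides of one protein ignored) are hubs —
  predicted core components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .core_model import KINASES, RatioMatrix
from .errors import ValidationError


@dataclass
class MutantSimilarity:
    rho: pd.DataFrame            # 8 x 8 Spearman matrix, NaN where undefined
    n_qualifying: pd.DataFrame   # peptides entering each pairwise estimate
    linkage_matrix: np.ndarray   # average linkage on 1 - rho


def mutant_similarity(
    matrix: RatioMatrix, fold_threshold: float = 2.0, min_peptides: int = 3
) -> MutantSimilarity:
    """Pairwise Spearman similarity of the mutants' log2 response profiles.

    Each pair is restricted to peptides observed in both mutants with at
    least ``fold_threshold``-fold change in both; pairs with fewer than
    ``min_peptides`` qualifying peptides yield an undefined (NaN) cell.
    Ties receive average ranks.  For the dendrogram, undefined distances
    are filled with the largest observed distance (pairwise-complete).
    """
    if fold_threshold <= 1:
        raise ValidationError("fold_threshold must exceed 1")
    log2 = matrix.log2.to_numpy(dtype=float)
    cut = np.log2(fold_threshold)
    qualifies = np.isfinite(log2) & (np.abs(log2) >= cut)

    k = len(KINASES)
    rho = np.eye(k)
    nq = np.zeros((k, k), dtype=int)
    for i, j in combinations(range(k), 2):
        mask = qualifies[:, i] & qualifies[:, j]
        nq[i, j] = nq[j, i] = int(mask.sum())
        if mask.sum() < min_peptides:
            rho[i, j] = rho[j, i] = np.nan
            continue
        r = stats.spearmanr(log2[mask, i], log2[mask, j]).statistic
        rho[i, j] = rho[j, i] = r

    dist = 1.0 - rho
    finite = dist[np.isfinite(dist)]
    fill = finite.max() if finite.size else 1.0
    dist = np.where(np.isfinite(dist), dist, fill)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    idx = list(KINASES)
    return MutantSimilarity(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        n_qualifying=pd.DataFrame(nq, index=idx, columns=idx),
        linkage_matrix=Z,
    )


def build_peptide_network(
    log2_complete: pd.DataFrame,
    r_threshold: float = 0.9,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Pearson network over complete-measurement peptides.

    Returns retained edges (peptide_a, peptide_b, r, p_value, n, sign)
    with two-sided p from the t statistic on n - 2 degrees of freedom,
    keeping pairs with p < p_threshold and |r| >= r_threshold.  Peptides
    with zero variance are skipped with a warning (r undefined).
    """
    if log2_complete.isna().any().any():
        raise ValidationError("peptide network requires complete measurements")
    X = log2_complete.to_numpy(dtype=float)
    keys = list(log2_complete.index)
    n_obs = X.shape[1]
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        bad = [keys[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"skipping zero-variance peptide(s): {', '.join(map(str, bad))}",
            RuntimeWarning,
            stacklevel=2,
        )
    ok = np.flatnonzero(~degenerate)
    rows = []
    if ok.size >= 2:
        R = np.corrcoef(X[ok])
        for a_pos, b_pos in combinations(range(ok.size), 2):
            r = float(np.clip(R[a_pos, b_pos], -1.0, 1.0))
            if abs(r) < r_threshold:
                continue
            if r ** 2 >= 1.0:
                p = 0.0
            else:
                t = abs(r) * np.sqrt((n_obs - 2) / (1.0 - r ** 2))
                p = float(2.0 * stats.t.sf(t, n_obs - 2))
            if p >= p_threshold:
                continue
            rows.append(
                {
                    "peptide_a": keys[ok[a_pos]],
                    "peptide_b": keys[ok[b_pos]],
                    "r": r,
                    "p_value": p,
                    "n": n_obs,
                    "sign": "+" if r > 0 else "-",
                }
            )
    return pd.DataFrame(
        rows, columns=["peptide_a", "peptide_b", "r", "p_value", "n", "sign"]
    )


@dataclass
class ProteinNetwork:
    graph: nx.Graph                      # protein-level edges with support lists
    self_connected: set[str]             # proteins linked by two of their own peptides
    degree: dict[str, int]               # distinct partners, self excluded
    hubs: set[str]                       # degree > 1

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def lift_to_proteins(
    edges: pd.DataFrame, mapping: dict[str, frozenset[str]]
) -> ProteinNetwork:
    """Trace peptide-level edges back to their parent proteins.

    A protein edge exists iff at least one peptide edge supports it; an
    edge between two peptides of the same protein is recorded as a
    self-connection and never contributes to degree.  Degree counts
    distinct partner proteins; hubs have degree > 1.
    """
    graph = nx.Graph()
    self_connected: set[str] = set()
    for row in edges.itertuples():
        try:
            prots_a = mapping[row.peptide_a]
            prots_b = mapping[row.peptide_b]
        except KeyError as exc:
            raise ValidationError(f"peptide {exc.args[0]!r} has no protein mapping")
        for pa in prots_a:
            for pb in prots_b:
                graph.add_node(pa)
                graph.add_node(pb)
                if pa == pb:
                    self_connected.add(pa)
                    continue
                if graph.has_edge(pa, pb):
                    graph[pa][pb]["support"].append((row.peptide_a, row.peptide_b))
                    graph[pa][pb]["signs"].append(row.sign)
                else:
                    graph.add_edge(
                        pa, pb,
                        support=[(row.peptide_a, row.peptide_b)],
                        signs=[row.sign],
                    )
    degree = {node: graph.degree(node) for node in graph.nodes}
    hubs = {node for node, d in degree.items() if d > 1}
    return ProteinNetwork(
        graph=graph, self_connected=self_connected, degree=degree, hubs=hubs
    )


# ---------------------------------------------------------------------------
# Cytoscape-compatible exports

def write_sif(network: ProteinNetwork, path: str | Path, relation: str = "cor") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(network.graph.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for node in sorted(network.graph.nodes):
            if network.graph.degree(node) == 0:
                fh.write(f"{node}\n")


def write_graphml(network: ProteinNetwork, path: str | Path) -> None:
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes)
    for node in g.nodes:
        g.nodes[node]["degree"] = network.degree[node]
        g.nodes[node]["hub"] = node in network.hubs
        g.nodes[node]["self_connected"] = node in network.self_connected
    for a, b, data in network.graph.edges(data=True):
        g.add_edge(
            a, b,
            n_supporting_peptide_pairs=len(data["support"]),
            signs="".join(data["signs"]),
        )
    nx.write_graphml(g, path)
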