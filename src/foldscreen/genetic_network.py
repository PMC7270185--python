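"""Genetic-interaction integration and profile-similarity communities.

Quantitative genetic-interaction fitness scores (epsilon) from double-mutant
screens are integrated with the interactome in two ways: direct annotation of
RBP-mRNA pairs whose |epsilon| exceeds a threshold, and a profile-similarity
network where genes are connected when the Pearson correlation of their
epsilon profiles exceeds a cutoff; communities of genes with similar genetic
landscapes are then found by seeded asynchronous label propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

EPSILON_THRESHOLD = 0.08
PCC_THRESHOLD = 0.2


@dataclass
class GiMatrix:
    """Gene x gene epsilon score matrix (rows: query genes, NaN = missing)."""

    genes: list[str]
    epsilon: np.ndarray  # square, may contain NaN

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        n = len(self.genes)
        if self.epsilon.shape != (n, n):
            raise ValueError(
                f"epsilon matrix shape {self.epsilon.shape} != ({n}, {n})"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epsilon, index=self.genes, columns=self.genes)

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "GiMatrix":
        """Build from a Costanzo-style long table (query, array, epsilon)."""
        wide = table.pivot_table(
            index="query", columns="array", values="epsilon", aggfunc="mean"
        )
        genes = sorted(set(wide.index) | set(wide.columns))
        wide = wide.reindex(index=genes, columns=genes)
        return cls(genes=genes, epsilon=wide.to_numpy(float))


@dataclass(frozen=True)
class PairAnnotation:
    rbp_gene: str
    mrna_gene: str
    epsilon: float
    sign: str  # "positive" | "negative"


@dataclass
class CommunityAssignment:
    labels: dict[str, int]
    seed: int
    converged: bool = True
    n_iterations: int = 0

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for gene, cid in self.labels.items():
            out.setdefault(cid, set()).add(gene)
        return out


def pair_annotation_matrix(
    rbp_mrna_pairs: list[tuple[str, str]],
    gi: GiMatrix,
    threshold: float = EPSILON_THRESHOLD,
) -> list[PairAnnotation]:
    """Annotate interactome pairs with their genetic-interaction scores.

    Only pairs with |epsilon| strictly above ``threshold`` are retained,
    signed by the direction of the interaction. Pairs with genes absent from
    the matrix, or with missing epsilon, are skipped.
    """
    index = {g: i for i, g in enumerate(gi.genes)}
    out = []
    for rbp, mrna in rbp_mrna_pairs:
        if rbp not in index or mrna not in index:
            continue
        eps = gi.epsilon[index[rbp], index[mrna]]
        if not np.isfinite(eps) or abs(eps) <= threshold:
            continue
        out.append(
            PairAnnotation(
                rbp_gene=rbp,
                mrna_gene=mrna,
                epsilon=float(eps),
                sign="positive" if eps > 0 else "negative",
            )
        )
    return out


def profile_correlations(gi: GiMatrix, min_overlap: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of epsilon profiles.

    Each gene's profile is its row of the epsilon matrix. Correlations use
    only positions where both profiles are observed; pairs with fewer than
    ``min_overlap`` shared positions, or a constant profile on the shared
    positions, are NaN. The result is symmetric with a unit diagonal.
    """
    n = len(gi.genes)
    if n < 2:
        raise ValueError("need at least 2 genes")
    pcc = np.full((n, n), np.nan)
    X = gi.epsilon
    finite = np.isfinite(X)
    for i in range(n):
        pcc[i, i] = 1.0
        for j in range(i + 1, n):
            mask = finite[i] & finite[j]
            if mask.sum() < min_overlap:
                continue
            xi, xj = X[i, mask], X[j, mask]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            pcc[i, j] = pcc[j, i] = r
    return pd.DataFrame(pcc, index=gi.genes, columns=gi.genes)


def build_network(pcc: pd.DataFrame, threshold: float = PCC_THRESHOLD) -> nx.Graph:
    """Profile-similarity graph: edge iff PCC strictly above ``threshold``.

    Undirected and simple; all genes appear as vertices, including isolates.
    """
    graph = nx.Graph()
    graph.add_nodes_from(pcc.index)
    genes = list(pcc.index)
    vals = pcc.to_numpy(float)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            v = vals[i, j]
            if np.isfinite(v) and v > threshold:
                graph.add_edge(genes[i], genes[j], pcc=float(v))
    return graph


def label_propagation(
    graph: nx.Graph, seed: int, max_iter: int = 1000
) -> CommunityAssignment:
    """Asynchronous label-propagation community detection.

    Every vertex starts in its own community; in each sweep the vertices are
    visited in a seeded random order and each adopts the most frequent label
    among its neighbors, ties broken uniformly at random from the same seeded
    generator. Iteration stops when every vertex already holds one of its
    neighborhood-majority labels (isolates keep their own), or after
    ``max_iter`` sweeps (flagged as non-converged). Final labels are
    renumbered to consecutive integers in order of first appearance over the
    sorted vertex list.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes)
    labels = {v: i for i, v in enumerate(nodes)}
    converged = False
    sweeps = 0
    while sweeps < max_iter:
        sweeps += 1
        order = list(nodes)
        rng.shuffle(order)
        changed = False
        for v in order:
            best = _majority_labels(graph, labels, v)
            if best is None:
                continue
            if labels[v] not in best:
                labels[v] = best[rng.integers(len(best))]
                changed = True
        if not changed and _all_majority(graph, labels):
            converged = True
            break
    final: dict[str, int] = {}
    renumber: dict[int, int] = {}
    for v in nodes:
        final[v] = renumber.setdefault(labels[v], len(renumber))
    return CommunityAssignment(
        labels=final, seed=seed, converged=converged, n_iterations=sweeps
    )


def _majority_labels(graph: nx.Graph, labels: dict, v) -> list | None:
    neighbors = list(graph.neighbors(v))
    if not neighbors:
        return None
    counts: dict[int, int] = {}
    for u in neighbors:
        counts[labels[u]] = counts.get(labels[u], 0) + 1
    top = max(counts.values())
    return [lab for lab, c in counts.items() if c == top]


def _all_majority(graph: nx.Graph, labels: dict) -> bool:
    for v in graph.nodes:
        best = _majority_labels(graph, labels, v)
        if best is not None and labels[v] not in best:
            return False
    return True


def read_gi_table(path) -> GiMatrix:
    """Read a GI input: long (query, array, epsilon) or square matrix TSV."""
    df = pd.read_csv(path, sep="\t")
    if {"query", "array", "epsilon"} <= set(df.columns):
        return GiMatrix.from_long(df)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GiMatrix(genes=list(df.index), epsilon=df.to_numpy(float))
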