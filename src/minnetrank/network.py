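"""Directed gene-interaction networks and the random-walk-with-restart diffusion matrix.

The network is a directed graph over gene symbols. Influence is propagated by a
random walk with restart (RWR): the adjacency is degree-normalized using both
the incoming and the outgoing degree of each gene, and the stationary influence
matrix

    D = beta * [I - (1 - beta) * A_norm]^(-1)

is computed in closed form. ``beta`` is the restart probability: ``beta = 1``
means no diffusion (D is the identity), small ``beta`` spreads signal far into
the network. D needs to be computed only once per network and can be cached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse as sp

logger = logging.getLogger(__name__)

DEFAULT_BETA = 0.48


class NetworkParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


@dataclass(frozen=True)
class InteractionNetwork:
    """Directed gene graph with per-gene in/out degrees.

    ``genes`` is lexicographically sorted and defines the row/column order of
    every matrix derived from the network, so omics matrices built against the
    same network align without re-indexing.
    """

    genes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    in_degree: dict[str, int] = field(repr=False)
    out_degree: dict[str, int] = field(repr=False)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        edge_set = set()
        n_self = 0
        for u, v in edges:
            if u == v:
                n_self += 1
                continue
            edge_set.add((u, v))
        if n_self:
            logger.warning("dropped %d self-loop(s)", n_self)
        if not edge_set:
            raise NetworkParseError("network has no edges after self-loop removal")
        genes = tuple(sorted({g for e in edge_set for g in e}))
        in_deg = {g: 0 for g in genes}
        out_deg = {g: 0 for g in genes}
        for u, v in edge_set:
            out_deg[u] += 1
            in_deg[v] += 1
        return cls(genes=genes, edges=frozenset(edge_set), in_degree=in_deg, out_degree=out_deg)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def content_hash(self) -> str:
        """SHA-256 over the sorted edge list; identifies the network for caching."""
        payload = "\n".join(f"{u}\t{v}" for u, v in sorted(self.edges))
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_directed_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.edges)
        return g


def load_network(edge_list_path: str | Path) -> InteractionNetwork:
    """Load a directed network from a two-column TSV edge list.

    Lines starting with ``#`` are skipped. A header row is detected when the
    first non-comment row reads like column names (``source``/``target`` etc.).
    Duplicate edges are collapsed; self-loops are dropped with a warning.
    """
    path = Path(edge_list_path)
    header_words = {"source", "target", "from", "to", "gene1", "gene2", "genea", "geneb"}
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        first_data_row = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise NetworkParseError(
                    f"{path}:{lineno}: expected two tab-separated gene symbols, got {line!r}"
                )
            u, v = fields[0].strip(), fields[1].strip()
            if first_data_row:
                first_data_row = False
                if u.lower() in header_words and v.lower() in header_words:
                    continue
            edges.append((u, v))
    if not edges:
        raise NetworkParseError(f"{path}: no edges found")
    return InteractionNetwork.from_edges(edges)


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Column-stochastic symmetrized adjacency.

    Entry (i, j) is (a_ij + a_ji) / (out_degree_j + in_degree_j), where
    a_ij = 1 iff there is a directed edge j -> i. Every column of a gene with
    at least one edge sums to 1; isolated genes (possible when a network is
    subset) have all-zero columns.
    """

    matrix: sp.csc_matrix = field(repr=False)
    gene_order: tuple[str, ...]


def normalize_adjacency(net: InteractionNetwork) -> NormalizedAdjacency:
    """Degree-normalize the adjacency using both in- and out-degree."""
    idx = net.gene_index()
    n = net.n_genes
    rows, cols = [], []
    for u, v in net.edges:
        # a_ij = 1 for edge j->i: edge (u, v) sets A[v, u]
        rows.append(idx[v])
        cols.append(idx[u])
    a = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsc()
    m = (a + a.T).tocsc()
    col_tot = np.asarray(m.sum(axis=0)).ravel()  # = out_degree + in_degree
    scale = np.divide(1.0, col_tot, out=np.zeros(n), where=col_tot > 0)
    m = m @ sp.diags(scale)
    return NormalizedAdjacency(matrix=m.tocsc(), gene_order=net.genes)


@dataclass(frozen=True)
class DiffusionMatrix:
    """Dense RWR influence matrix D with its restart probability."""

    matrix: np.ndarray = field(repr=False)
    beta: float
    gene_order: tuple[str, ...]

    @property
    def n_genes(self) -> int:
        return len(self.gene_order)


def compute_diffusion(
    adj: NormalizedAdjacency,
    beta: float = DEFAULT_BETA,
    method: str = "direct",
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> DiffusionMatrix:
    """Compute D = beta * [I - (1-beta) * A_norm]^(-1).

    ``method="direct"`` uses a dense LU solve (fine up to ~15k genes);
    ``method="iterative"`` runs the fixed-point iteration
    D <- beta*I + (1-beta) * A_norm @ D to ``tol``, useful for larger networks.
    beta = 0 is rejected: the resolvent is singular for a column-stochastic
    normalized adjacency.
    """
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"restart probability beta must lie in (0, 1], got {beta}")
    n = len(adj.gene_order)
    a = adj.matrix
    if beta == 1.0:
        return DiffusionMatrix(matrix=np.eye(n), beta=beta, gene_order=adj.gene_order)
    if method == "direct":
        lhs = np.eye(n) - (1.0 - beta) * a.toarray()
        try:
            d = scipy.linalg.solve(lhs, beta * np.eye(n))
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ArithmeticError(
                f"diffusion solve failed for beta={beta}, n={n}: {exc}"
            ) from exc
    elif method == "iterative":
        d = beta * np.eye(n)
        base = beta * np.eye(n)
        damp = (1.0 - beta) * a
        for _ in range(max_iter):
            d_next = base + damp @ d
            delta = np.max(np.abs(d_next - d))
            d = d_next
            if delta < tol:
                break
        else:  # pragma: no cover - defensive
            raise ArithmeticError(
                f"diffusion iteration did not reach tol={tol} in {max_iter} steps"
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    return DiffusionMatrix(matrix=d, beta=beta, gene_order=adj.gene_order)


def save_diffusion(d: DiffusionMatrix, path: str | Path, network_hash: str) -> None:
    """Cache D as an .npz next to a JSON sidecar recording (network hash, beta, genes)."""
    path = Path(path)
    np.savez_compressed(path, matrix=d.matrix)
    meta = {"network_hash": network_hash, "beta": d.beta, "gene_order": list(d.gene_order)}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def load_diffusion(path: str | Path, expected_hash: str | None = None) -> DiffusionMatrix:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    if expected_hash is not None and meta["network_hash"] != expected_hash:
        raise ValueError("diffusion cache does not match the supplied network")
    with np.load(path) as data:
        matrix = data["matrix"]
    return DiffusionMatrix(matrix=matrix, beta=meta["beta"], gene_order=tuple(meta["gene_order"]))


def centrality_baselines(net: InteractionNetwork):
    """Rank genes by degree centrality, betweenness centrality, and their mean.

    Betweenness is shortest-path betweenness on the directed graph with unit
    weights. The combined baseline min-max rescales each centrality to [0, 1]
    before averaging, since the two live on incomparable scales. Returns a dict
    keyed by ``{"degree", "betweenness", "mean_of_both"}``.
    """
    from .ranking import GeneRanking

    g = net.to_directed_graph()
    deg = nx.degree_centrality(g)
    btw = nx.betweenness_centrality(g, normalized=True)

    def _rescaled(values: dict[str, float]) -> dict[str, float]:
        arr = np.array([values[x] for x in net.genes])
        lo, hi = arr.min(), arr.max()
        if hi == lo:
            return {x: 0.0 for x in net.genes}
        return {x: (values[x] - lo) / (hi - lo) for x in net.genes}

    deg01, btw01 = _rescaled(deg), _rescaled(btw)
    mean_of_both = {x: 0.5 * (deg01[x] + btw01[x]) for x in net.genes}
    return {
        "degree": GeneRanking.from_metric(deg, higher_is_better=True),
        "betweenness": GeneRanking.from_metric(btw, higher_is_better=True),
        "mean_of_both": GeneRanking.from_metric(mean_of_both, higher_is_better=True),
    }
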