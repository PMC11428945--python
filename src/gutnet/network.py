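"""SparCC co-occurrence networks, cross-timepoint integration and topology.

SparCC estimates "basis" correlations — correlations of latent absolute
abundances — from compositional counts. For each of ``n_inner_iterations``
resampled fraction matrices (Dirichlet posterior with a pseudocount prior) it

1. computes the log-ratio variation matrix t_ij = var(log(x_i / x_j)),
2. solves the sparsity approximation for the basis variances omega_i
   (row sums of t relate linearly to omega when most pairs are uncorrelated),
3. forms basis correlations rho_ij = (omega_i + omega_j - t_ij) /
   (2 sqrt(omega_i omega_j)),
4. iteratively excludes the most strongly correlated pair (|rho| above the
   exclusion threshold) and re-solves, up to ``n_exclusion_rounds`` rounds,
   so that a few strong correlations do not distort the variance estimates.

The reported adjacency is the entrywise median over inner iterations, clipped
to [-1, 1], with unit diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .data_io import CountTable, ResultTable, ValidationError


@dataclass
class CorrelationNetwork:
    """Symmetric taxon x taxon correlation matrix for one condition."""

    taxon_ids: list[str]
    adjacency: np.ndarray
    condition: str | None = None
    provenance: list[str] = field(default_factory=list)
    n_samples: int | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.shape != (len(self.taxon_ids), len(self.taxon_ids)):
            raise ValidationError("adjacency shape does not match taxon_ids")
        if not np.allclose(a, a.T, atol=1e-8):
            raise ValidationError("adjacency must be symmetric")
        if np.abs(a).max() > 1 + 1e-8:
            raise ValidationError("correlations must lie in [-1, 1]")
        a = np.clip((a + a.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(a, 1.0)
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.adjacency, index=self.taxon_ids,
                            columns=self.taxon_ids)

    def edge_list(self, threshold: float = 0.0) -> pd.DataFrame:
        """Long-format edges (source, target, weight) with |weight| >=
        threshold, importable by graph viewers."""
        rows = []
        a = self.adjacency
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                w = a[i, j]
                if w != 0 and abs(w) >= threshold:
                    rows.append((self.taxon_ids[i], self.taxon_ids[j], w))
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

def _variation_matrix(log_fracs: np.ndarray) -> np.ndarray:
    """t_ij = var(log x_i - log x_j) via the covariance matrix."""
    cov = np.cov(log_fracs, rowvar=False)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _solve_basis(t: np.ndarray, excluded: np.ndarray) -> np.ndarray:
    """Basis variances from the sparsity approximation.

    With no correlations, sum_j t_ij = (p-2) omega_i + sum_j omega_j where the
    sums skip excluded pairs. ``excluded`` is a boolean (p, p) matrix of pairs
    removed from the system.
    """
    p = t.shape[0]
    active = ~excluded
    np.fill_diagonal(active, False)
    m = active.astype(float)
    # system: row_sum_i = sum_{j active} (omega_i + omega_j) - 2*cov_terms~0
    #       = deg_i * omega_i + sum_{j active} omega_j
    a_mat = m.copy()
    np.fill_diagonal(a_mat, m.sum(axis=1))
    t_masked = np.where(active, t, 0.0)
    rhs = t_masked.sum(axis=1)
    try:
        omega = np.linalg.solve(a_mat, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "SparCC basis-variance system is singular after exclusions; "
            "reduce n_exclusion_rounds"
        ) from exc
    return np.maximum(omega, 1e-10)


def _basis_correlations(t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - t) / denom
    np.fill_diagonal(rho, 1.0)
    return rho


def _sparcc_one(fracs: np.ndarray, exclusion_threshold: float,
                n_exclusion_rounds: int) -> np.ndarray:
    log_f = np.log(fracs)
    t = _variation_matrix(log_f)
    p = t.shape[0]
    excluded = np.zeros((p, p), dtype=bool)
    omega = _solve_basis(t, excluded)
    rho = _basis_correlations(t, omega)
    for _ in range(n_exclusion_rounds):
        work = np.abs(rho.copy())
        np.fill_diagonal(work, 0.0)
        work[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(work), work.shape)
        if work[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        # a component excluded from nearly every pair leaves the system
        # under-determined for that variance; keep it but stop excluding
        if excluded[i].sum() >= p - 3 or excluded[j].sum() >= p - 3:
            break
        omega = _solve_basis(t, excluded)
        rho = _basis_correlations(t, omega)
    return rho


def sparcc(table: CountTable, n_inner_iterations: int = 20,
           exclusion_threshold: float = 0.1, n_exclusion_rounds: int = 10,
           pseudocount: float = 0.5, seed: int = 0,
           condition: str | None = None) -> CorrelationNetwork:
    """Infer a basis-correlation network from a count table.

    Parameters follow the algorithm's published defaults: 20 inner resampling
    iterations, 10 pair-exclusion rounds with threshold 0.1, and a Dirichlet
    pseudocount of 0.5. ``n_inner_iterations=0`` skips the Dirichlet
    resampling and uses the posterior-mean fractions directly — deterministic
    and exactly equivariant to taxon order.
    """
    if table.n_taxa < 4:
        raise ValidationError(
            "SparCC needs >= 4 taxa; the basis-variance system is "
            "under-determined below that")
    if table.n_samples < 10:
        warnings.warn("SparCC on fewer than 10 samples is unreliable",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    counts = table.counts.astype(float) + pseudocount
    rhos = []
    if n_inner_iterations == 0:
        # deterministic path: posterior-mean fractions, no resampling
        fracs = counts / counts.sum(axis=1, keepdims=True)
        rhos.append(_sparcc_one(fracs, exclusion_threshold,
                                n_exclusion_rounds))
    for _ in range(n_inner_iterations):
        # Dirichlet(counts + pseudocount) posterior draw, vectorized via gamma
        g = rng.gamma(shape=counts, scale=1.0)
        fracs = g / g.sum(axis=1, keepdims=True)
        fracs = np.maximum(fracs, 1e-12)
        rhos.append(_sparcc_one(fracs, exclusion_threshold,
                                n_exclusion_rounds))
    a = np.median(np.stack(rhos), axis=0)
    a = np.clip((a + a.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(a, 1.0)
    return CorrelationNetwork(list(table.taxon_ids), a, condition=condition,
                              n_samples=table.n_samples)


# ---------------------------------------------------------------------------
# Integration across timepoints
# ---------------------------------------------------------------------------

def integrate_networks(networks: list[CorrelationNetwork],
                       weights: list[float] | None = None,
                       ) -> CorrelationNetwork:
    """Combine per-timepoint networks of one condition into a single network.

    The integrated edge is a weighted mean a_ij = sum_t w_t a_ij(t) / sum w_t.
    Default weights are inverse-variance weights from the Fisher-z variance of
    a correlation coefficient, 1 / (n_t - 3), i.e. w_t = n_t - 3; equal
    weights are used when sample sizes are unknown. Taxa absent from a
    network contribute weight 0 to their edges.
    """
    if not networks:
        raise ValidationError("no networks to integrate")
    conditions = {n.condition for n in networks}
    if len(conditions) > 1:
        raise ValidationError(f"condition mismatch: {sorted(map(str, conditions))}")
    if weights is None:
        if all(n.n_samples and n.n_samples > 3 for n in networks):
            weights = [float(n.n_samples - 3) for n in networks]
        else:
            weights = [1.0] * len(networks)
    if len(weights) != len(networks):
        raise ValidationError("one weight per network required")

    universe: list[str] = []
    for net in networks:
        for t in net.taxon_ids:
            if t not in universe:
                universe.append(t)
    p = len(universe)
    num = np.zeros((p, p))
    den = np.zeros((p, p))
    for net, w in zip(networks, weights):
        idx = np.array([universe.index(t) for t in net.taxon_ids])
        num[np.ix_(idx, idx)] += w * net.adjacency
        den[np.ix_(idx, idx)] += w
    with np.errstate(invalid="ignore"):
        a = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    a = np.clip((a + a.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(a, 1.0)
    prov = [p for net in networks for p in (net.provenance or ["?"])]
    n_total = sum(n.n_samples or 0 for n in networks) or None
    return CorrelationNetwork(universe, a, condition=networks[0].condition,
                              provenance=prov, n_samples=n_total)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

DEFAULT_EDGE_THRESHOLD = 0.3


@dataclass
class TopologyReport:
    node_metrics: pd.DataFrame   # index taxon; degree, strength, betweenness, closeness
    mean_degree: float
    n_edges: int
    density: float


def binarize(network: CorrelationNetwork,
             edge_threshold: float = DEFAULT_EDGE_THRESHOLD) -> nx.Graph:
    """Undirected graph with an edge wherever |a_ij| >= threshold (i != j)."""
    if not 0.0 <= edge_threshold < 1.0:
        raise ValueError("edge_threshold must lie in [0, 1)")
    a = network.adjacency
    g = nx.Graph()
    g.add_nodes_from(network.taxon_ids)
    for i in range(network.n_nodes):
        for j in range(i + 1, network.n_nodes):
            if abs(a[i, j]) >= edge_threshold:
                g.add_edge(network.taxon_ids[i], network.taxon_ids[j],
                           weight=abs(a[i, j]))
    return g


def topology(network: CorrelationNetwork,
             edge_threshold: float = DEFAULT_EDGE_THRESHOLD) -> TopologyReport:
    """Degree / strength / betweenness / closeness on the thresholded graph."""
    g = binarize(network, edge_threshold)
    degree = dict(g.degree())
    strength = dict(g.degree(weight="weight"))
    betweenness = nx.betweenness_centrality(g)
    closeness = nx.closeness_centrality(g)
    df = pd.DataFrame({
        "degree": pd.Series(degree, dtype=float),
        "strength": pd.Series(strength, dtype=float),
        "betweenness": pd.Series(betweenness),
        "closeness": pd.Series(closeness),
    }).loc[network.taxon_ids]
    n = network.n_nodes
    n_edges = g.number_of_edges()
    density = 0.0 if n < 2 else 2.0 * n_edges / (n * (n - 1))
    return TopologyReport(node_metrics=df,
                          mean_degree=float(df["degree"].mean()),
                          n_edges=n_edges, density=density)


def compare_topology(report_a: TopologyReport,
                     report_b: TopologyReport) -> ResultTable:
    """Per-metric Mann-Whitney comparison of node-level distributions."""
    cols_a = set(report_a.node_metrics.columns)
    cols_b = set(report_b.node_metrics.columns)
    if not (set(report_a.node_metrics.index) | set(report_b.node_metrics.index)):
        raise ValidationError("empty topology reports")
    shared_nodes = set(report_a.node_metrics.index) & set(
        report_b.node_metrics.index)
    if not shared_nodes:
        raise ValidationError("disjoint node sets; reports are not comparable")
    rows = []
    for metric in sorted(cols_a | cols_b):
        if metric not in cols_a or metric not in cols_b:
            warnings.warn(f"metric {metric!r} present in only one report; "
                          "skipped", stacklevel=2)
            continue
        x = report_a.node_metrics[metric].to_numpy(dtype=float)
        y = report_b.node_metrics[metric].to_numpy(dtype=float)
        if np.array_equal(np.sort(x), np.sort(y)):
            p = 1.0
        else:
            _, p = mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"metric": metric,
                     "mean_a": float(x.mean()), "mean_b": float(y.mean()),
                     "mean_difference": float(x.mean() - y.mean()),
                     "p_value": float(min(p, 1.0))})
    return ResultTable(pd.DataFrame(rows))
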