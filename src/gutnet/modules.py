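"""Network module detection and node-level module statistics.

Modules (groups of taxa with dense mutual co-occurrence) are detected in the
WGCNA style: the signed soft adjacency s_ij = ((1 + a_ij) / 2)^beta is
converted to a topological overlap similarity, and average-linkage
hierarchical clustering of the TOM dissimilarity is cut at a fixed height;
clusters below ``min_module_size`` are pooled into the unassigned "grey"
label.

Two node statistics accompany a partition:

* connection strength  k_i = sum_{j != i} a_ij — the node's summed
  correlation with every other node;
* module importance    sum_{j in M, j != i} a_ij - sum_{j not in M} a_ij —
  within-module minus out-of-module connectivity of node i's own module M.
  When all of a node's connectivity is inside its module this equals k_i;
  for a singleton module it equals -k_i.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .data_io import ValidationError
from .network import CorrelationNetwork

GREY = "grey"

DEFAULT_SOFT_POWER = 6
DEFAULT_MIN_MODULE_SIZE = 5
# Static cut height on the TOM-dissimilarity dendrogram. Average-linkage merge
# heights on TOM dissimilarity sit around 0.4-0.7 inside genuine modules and
# near 1 between them, so the cut must sit high; 0.9 is the classic static-cut
# default for this dissimilarity.
DEFAULT_CUT_HEIGHT = 0.9


@dataclass
class ModulePartition:
    """node -> module label map with member counts."""

    assignment: dict[str, str]

    @property
    def n(self) -> int:
        return len(self.assignment)

    @property
    def module_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label in self.assignment.values():
            out[label] = out.get(label, 0) + 1
        return out

    def members(self, label: str) -> set[str]:
        return {n for n, m in self.assignment.items() if m == label}

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": list(self.assignment), "module": list(self.assignment.values())}
        )


def signed_adjacency(network: CorrelationNetwork,
                     soft_power: int = DEFAULT_SOFT_POWER) -> np.ndarray:
    """Signed WGCNA soft adjacency ((1 + a) / 2)^beta with zero diagonal."""
    s = ((1.0 + network.adjacency) / 2.0) ** soft_power
    np.fill_diagonal(s, 0.0)
    return s


def topological_overlap(s: np.ndarray) -> np.ndarray:
    """TOM_ij = (l_ij + s_ij) / (min(k_i, k_j) + 1 - s_ij), unit diagonal."""
    k = s.sum(axis=1)
    l_mat = s @ s
    denom = np.minimum.outer(k, k) + 1.0 - s
    tom = (l_mat + s) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(network: CorrelationNetwork,
                   soft_power: int = DEFAULT_SOFT_POWER,
                   min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
                   cut_height: float = DEFAULT_CUT_HEIGHT) -> ModulePartition:
    """WGCNA-style static-cut module detection.

    Deterministic: there is no random initialisation anywhere in the
    clustering path. Clusters smaller than ``min_module_size`` become "grey".
    Module labels are "M1", "M2", ... ordered by decreasing size.
    """
    n = network.n_nodes
    if n < min_module_size:
        warnings.warn("fewer nodes than min_module_size; single module",
                      stacklevel=2)
        return ModulePartition({t: "M1" for t in network.taxon_ids})
    s = signed_adjacency(network, soft_power)
    diss = 1.0 - topological_overlap(s)
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(np.maximum(diss, 0.0), checks=False)
    link = average(condensed)
    raw = fcluster(link, t=cut_height, criterion="distance")
    # order clusters by size (desc), then by smallest member index, for stable
    # labels; sub-threshold clusters -> grey
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(i)
    ordered = sorted(clusters.values(), key=lambda m: (-len(m), m[0]))
    assignment: dict[str, str] = {}
    next_label = 1
    for members in ordered:
        if len(members) >= min_module_size:
            label = f"M{next_label}"
            next_label += 1
        else:
            label = GREY
        for i in members:
            assignment[network.taxon_ids[i]] = label
    return ModulePartition(assignment)


def connection_strength(network: CorrelationNetwork) -> pd.Series:
    """k_i = sum over all other nodes of a_ij (self term excluded)."""
    a = network.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    return pd.Series(a.sum(axis=1), index=network.taxon_ids, name="k")


def module_importance(network: CorrelationNetwork,
                      partition: ModulePartition) -> pd.Series:
    """Within-module minus out-of-module connectivity per node."""
    missing = [t for t in network.taxon_ids if t not in partition.assignment]
    if missing:
        raise ValidationError(f"nodes missing from partition: {missing[:5]}")
    a = network.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    labels = np.array([partition.assignment[t] for t in network.taxon_ids])
    out = np.empty(network.n_nodes)
    for i in range(network.n_nodes):
        same = labels == labels[i]
        same_i = same.copy()
        same_i[i] = False
        out[i] = a[i, same_i].sum() - a[i, ~same].sum()
    return pd.Series(out, index=network.taxon_ids, name="module_importance")


def node_module_statistics(network: CorrelationNetwork,
                           partition: ModulePartition) -> pd.DataFrame:
    """Both node statistics in one frame (columns k, module_importance,
    module)."""
    k = connection_strength(network)
    imp = module_importance(network, partition)
    return pd.DataFrame({
        "k": k,
        "module_importance": imp,
        "module": [partition.assignment[t] for t in network.taxon_ids],
    })
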