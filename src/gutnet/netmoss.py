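"""Network-shift (NetMoss-type) driving-force biomarker scoring.

Given one co-occurrence network per condition (A = control, B = stress) with
module partitions, each taxon receives a driving-force score measuring how
much it contributes to the change in module structure between the two
networks:

    raw(i) = sum_{j in NeighborsA(i)} dD_ij  -  sum_{l in NeighborsB(i)} dD_il

where NeighborsA(i) / NeighborsB(i) are the nodes joined to i by a
supra-threshold edge in network A / B, and the differential module distance
of a node pair compares how the pair is housed by the two partitions:

    dD_ij = d_B(i, j) - d_A(i, j),   d_X(i, j) = 0 if i and j share a module
                                     in network X and 1 otherwise.

A taxon that keeps its module gets dD ~ 0 against its whole neighborhood; a
taxon that migrates to a different module accumulates +1 terms over its old
(A) neighborhood and -1 terms over its new (B) neighborhood, so the two sums
reinforce. When the two networks are identical dD vanishes for every pair
and the score is exactly 0 for every node. Alongside the node scores, the
module-pair distance matrix D — the Jaccard distance between module member
sets across the two partitions — identifies the stable (intersection)
modules of the transition: pairs with D below the stability threshold.

Reported scores are |raw| min-max normalized to [0, 1]. Significance comes
from a condition-label permutation null recomputed through the whole
network -> partition -> score chain, with Benjamini-Hochberg FDR control;
p-values use the raw absolute score (the normalized score is a rank
statistic whose maximum is 1 by construction in every permutation, which
would destroy per-taxon calibration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_io import CountTable, SampleMetadata, ValidationError
from .modules import ModulePartition, detect_modules
from .network import (CorrelationNetwork, DEFAULT_EDGE_THRESHOLD,
                      integrate_networks, sparcc)
from .preprocess import relative_abundance

DEFAULT_STABILITY_THRESHOLD = 0.3


@dataclass
class ChainConfig:
    """Parameters of the network -> modules -> score chain.

    ``economy()`` returns a reduced-iteration profile for permutation nulls,
    where the chain is recomputed hundreds of times.
    """

    sparcc_inner_iterations: int = 20
    sparcc_exclusion_rounds: int = 10
    sparcc_exclusion_threshold: float = 0.1
    sparcc_pseudocount: float = 0.5
    soft_power: int = 6
    min_module_size: int = 5
    cut_height: float = 0.9
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD

    @classmethod
    def economy(cls) -> "ChainConfig":
        return cls(sparcc_inner_iterations=5, sparcc_exclusion_rounds=3)


@dataclass
class DifferentialModuleDistance:
    """Module-pair distances and per-node neighbor context for the
    driving-force score."""

    distance: pd.DataFrame                # modules_A x modules_B, Jaccard
    module_a: dict[str, str]              # node -> module in A
    module_b: dict[str, str]              # node -> module in B
    neighbors_a: dict[str, set[str]]      # node -> modules its A-edges touch
    neighbors_b: dict[str, set[str]]      # node -> modules its B-edges touch
    stable_pairs: list[tuple[str, str]]   # (module_A, module_B) with low D
    node_neighbors_a: dict[str, set[str]] = None  # node -> adjacent nodes, A
    node_neighbors_b: dict[str, set[str]] = None  # node -> adjacent nodes, B


def _node_neighbors(network: CorrelationNetwork,
                    edge_threshold: float) -> dict[str, set[str]]:
    """Co-occurrence neighborhoods: positive supra-threshold edges only.

    Compositional closure makes unrelated taxon groups anti-correlate, so
    negative edges connect a node to everything outside its own guild; using
    them here would cancel the within-guild signal the score measures.
    """
    a = network.adjacency
    out: dict[str, set[str]] = {}
    for i, t in enumerate(network.taxon_ids):
        hit = np.where(a[i] >= edge_threshold)[0]
        out[t] = {network.taxon_ids[j] for j in hit if j != i}
    return out


def differential_module_distance(
        net_a: CorrelationNetwork, part_a: ModulePartition,
        net_b: CorrelationNetwork, part_b: ModulePartition,
        edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
        stability_threshold: float = DEFAULT_STABILITY_THRESHOLD,
        ) -> DifferentialModuleDistance:
    """Module-pair Jaccard distances plus per-node neighborhood context.

    D(M_A, M_B) = 1 - |M_A ∩ M_B| / |M_A ∪ M_B| on member sets. Pairs with
    D below ``stability_threshold`` are flagged as the stable (intersection)
    modules of the transition. Per node, the supra-threshold neighbors in
    each network (and the modules those neighbors belong to) are recorded for
    the driving-force sums.
    """
    if part_a.n == 0 or part_b.n == 0:
        raise ValidationError("empty partition")
    mods_a, mods_b = part_a.labels, part_b.labels
    d = np.ones((len(mods_a), len(mods_b)))
    for i, ma in enumerate(mods_a):
        sa = part_a.members(ma)
        for j, mb in enumerate(mods_b):
            sb = part_b.members(mb)
            union = sa | sb
            if union:
                d[i, j] = 1.0 - len(sa & sb) / len(union)
    dist = pd.DataFrame(d, index=mods_a, columns=mods_b)
    stable = [(ma, mb) for ma in mods_a for mb in mods_b
              if dist.loc[ma, mb] < stability_threshold]
    node_nbr_a = _node_neighbors(net_a, edge_threshold)
    node_nbr_b = _node_neighbors(net_b, edge_threshold)
    neighbors_a = {t: {part_a.assignment[j] for j in nbrs
                       if j in part_a.assignment}
                   for t, nbrs in node_nbr_a.items()}
    neighbors_b = {t: {part_b.assignment[j] for j in nbrs
                       if j in part_b.assignment}
                   for t, nbrs in node_nbr_b.items()}
    return DifferentialModuleDistance(
        distance=dist,
        module_a=dict(part_a.assignment), module_b=dict(part_b.assignment),
        neighbors_a=neighbors_a, neighbors_b=neighbors_b,
        stable_pairs=stable,
        node_neighbors_a=node_nbr_a, node_neighbors_b=node_nbr_b,
    )


def _pair_delta(dist: DifferentialModuleDistance, i: str, j: str) -> float:
    """dD_ij = [i, j in different modules in B] - [different in A]."""
    d_a = 0.0 if dist.module_a[i] == dist.module_a[j] else 1.0
    d_b = 0.0 if dist.module_b[i] == dist.module_b[j] else 1.0
    return d_b - d_a


def nmss(dist: DifferentialModuleDistance, node: str) -> float:
    """Raw (signed) driving-force score of one taxon; see module docstring."""
    if node not in dist.module_a or node not in dist.module_b:
        raise ValidationError(f"node {node!r} absent from a network")
    shared = set(dist.module_a) & set(dist.module_b)
    s_a = sum(_pair_delta(dist, node, j)
              for j in dist.node_neighbors_a.get(node, set()) if j in shared)
    s_b = sum(_pair_delta(dist, node, l)
              for l in dist.node_neighbors_b.get(node, set()) if l in shared)
    return s_a - s_b


def nmss_scores(dist: DifferentialModuleDistance) -> pd.DataFrame:
    """Raw and min-max-normalized |raw| scores for every shared node."""
    nodes = [t for t in dist.module_a if t in dist.module_b]
    raw = np.array([nmss(dist, t) for t in nodes])
    mag = np.abs(raw)
    rng = mag.max() - mag.min()
    norm = (mag - mag.min()) / rng if rng > 0 else np.zeros_like(mag)
    return pd.DataFrame({"raw": raw, "nmss": norm}, index=pd.Index(nodes, name="taxon"))


# ---------------------------------------------------------------------------
# Full chain and significance
# ---------------------------------------------------------------------------

def _chain(table_a: CountTable, table_b: CountTable, config: ChainConfig,
           seed: int) -> pd.DataFrame:
    """counts (two arms) -> SparCC -> modules -> scores."""
    kwargs = dict(n_inner_iterations=config.sparcc_inner_iterations,
                  n_exclusion_rounds=config.sparcc_exclusion_rounds,
                  exclusion_threshold=config.sparcc_exclusion_threshold,
                  pseudocount=config.sparcc_pseudocount)
    net_a = sparcc(table_a, seed=seed, condition="A", **kwargs)
    net_b = sparcc(table_b, seed=seed + 1, condition="B", **kwargs)
    part_a = detect_modules(net_a, config.soft_power, config.min_module_size,
                            config.cut_height)
    part_b = detect_modules(net_b, config.soft_power, config.min_module_size,
                            config.cut_height)
    dist = differential_module_distance(net_a, part_a, net_b, part_b,
                                        config.edge_threshold)
    return nmss_scores(dist)


def _direction(table_a: CountTable, table_b: CountTable,
               taxa: list[str]) -> list[str]:
    rel_a = relative_abundance(table_a).mean(axis=0)
    rel_b = relative_abundance(table_b).mean(axis=0)
    ser_a = pd.Series(rel_a, index=table_a.taxon_ids)
    ser_b = pd.Series(rel_b, index=table_b.taxon_ids)
    out = []
    for t in taxa:
        diff = float(ser_a.get(t, 0.0) - ser_b.get(t, 0.0))
        if diff > 0:
            out.append("enriched_in_A")
        elif diff < 0:
            out.append("enriched_in_B")
        else:
            out.append("none")
    return out


def nmss_significance(table_a: CountTable, table_b: CountTable,
                      n_permutations: int = 1000, seed: int = 0,
                      config: ChainConfig | None = None,
                      observed: pd.DataFrame | None = None) -> pd.DataFrame:
    """Permutation p-values and BH q-values for the driving-force score.

    The null permutes condition labels over the pooled samples and re-runs
    the full network -> partition -> score chain. p-values follow the plus-one
    convention (never exactly 0). ``observed`` lets a caller reuse scores
    already computed with the same config.
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives coarse p-values",
                      stacklevel=2)
    config = config or ChainConfig.economy()
    if set(table_a.taxon_ids) != set(table_b.taxon_ids):
        raise ValidationError("the two arms must share a taxon universe")
    n_a, n_b = table_a.n_samples, table_b.n_samples
    if n_a < 4 or n_b < 4:
        raise ValidationError("too few samples per arm to permute into arms")
    if observed is None:
        observed = _chain(table_a, table_b, config, seed)
    obs_mag = observed["raw"].abs()

    pooled = np.vstack([table_a.counts, table_b.counts])
    ids = list(table_a.sample_ids) + list(table_b.sample_ids)
    taxa = list(table_a.taxon_ids)
    # align B's columns to A's order
    order_b = [table_b.taxon_ids.index(t) for t in taxa]
    pooled[n_a:] = pooled[n_a:][:, order_b]

    rng = np.random.default_rng(seed)
    exceed = pd.Series(0, index=obs_mag.index, dtype=int)
    for perm in range(n_permutations):
        idx = rng.permutation(n_a + n_b)
        pa = CountTable([ids[i] for i in idx[:n_a]], taxa, pooled[idx[:n_a]])
        pb = CountTable([ids[i] for i in idx[n_a:]], taxa, pooled[idx[n_a:]])
        null = _chain(pa, pb, config, seed=int(rng.integers(2 ** 31)))
        null_mag = null["raw"].abs().reindex(obs_mag.index).fillna(0.0)
        exceed += (null_mag >= obs_mag).astype(int)

    p = (1.0 + exceed) / (1.0 + n_permutations)
    q = multipletests(p.to_numpy(), method="fdr_bh")[1]
    out = observed.copy()
    out["p_value"] = p
    out["q_value"] = q
    out["direction"] = _direction(table_a, table_b, list(out.index))
    return out


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Standard monotone step-up BH q-values (convenience re-export)."""
    return multipletests(np.asarray(p_values, dtype=float),
                         method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Per-timepoint and longitudinal modes
# ---------------------------------------------------------------------------

def _split_arms(table: CountTable, metadata: SampleMetadata,
                sample_ids: list[str]) -> tuple[CountTable, CountTable]:
    meta = metadata.for_samples(sample_ids).frame.set_index("sample_id")
    ctrl = [s for s in sample_ids if meta.loc[s, "group"] == "control"]
    strs = [s for s in sample_ids if meta.loc[s, "group"] == "stress"]
    sub = table.select_samples(sample_ids)
    return sub.select_samples(ctrl), sub.select_samples(strs)


def run_per_timepoint(table: CountTable, metadata: SampleMetadata,
                      n_permutations: int = 1000, seed: int = 0,
                      config: ChainConfig | None = None,
                      ) -> dict[str, pd.DataFrame]:
    """Run the full chain independently within each sampling timepoint."""
    meta = metadata.for_samples(table.sample_ids).frame
    results: dict[str, pd.DataFrame] = {}
    for t_idx, t in enumerate(metadata.timepoints):
        sids = list(meta.loc[meta["timepoint"] == t, "sample_id"])
        if not sids:
            continue
        groups = set(meta.loc[meta["timepoint"] == t, "group"])
        if groups != {"control", "stress"}:
            warnings.warn(f"timepoint {t!r} lacks one condition; skipped",
                          stacklevel=2)
            continue
        ta, tb = _split_arms(table, metadata, sids)
        res = nmss_significance(ta, tb, n_permutations,
                                seed=seed + 1000 * t_idx, config=config)
        res["mode"] = "per_timepoint"
        res["timepoint"] = t
        results[t] = res
    if not results:
        raise ValidationError("no timepoint had both conditions")
    return results


def run_longitudinal(table: CountTable, metadata: SampleMetadata,
                     n_permutations: int = 1000, seed: int = 0,
                     config: ChainConfig | None = None) -> pd.DataFrame:
    """Integrate per-timepoint networks per condition, then score.

    For each condition a network is inferred at every timepoint; the networks
    are combined by inverse-variance weighting into one network per condition,
    on which modules and driving-force scores are computed. The permutation
    null shuffles condition labels within each timepoint and replays the whole
    integration chain.
    """
    config = config or ChainConfig.economy()
    meta = metadata.for_samples(table.sample_ids).frame
    tps = [t for t in metadata.timepoints if (meta["timepoint"] == t).any()]
    if len(tps) < 2:
        raise ValidationError("longitudinal mode needs >= 2 timepoints")
    kwargs = dict(n_inner_iterations=config.sparcc_inner_iterations,
                  n_exclusion_rounds=config.sparcc_exclusion_rounds,
                  exclusion_threshold=config.sparcc_exclusion_threshold,
                  pseudocount=config.sparcc_pseudocount)

    def integrated_scores(arms_per_tp, seed0: int) -> pd.DataFrame:
        nets_a, nets_b = [], []
        for k, (ta, tb) in enumerate(arms_per_tp):
            nets_a.append(sparcc(ta, seed=seed0 + 2 * k, condition="A", **kwargs))
            nets_b.append(sparcc(tb, seed=seed0 + 2 * k + 1, condition="B",
                                 **kwargs))
        net_a = integrate_networks(nets_a)
        net_b = integrate_networks(nets_b)
        part_a = detect_modules(net_a, config.soft_power,
                                config.min_module_size, config.cut_height)
        part_b = detect_modules(net_b, config.soft_power,
                                config.min_module_size, config.cut_height)
        dist = differential_module_distance(net_a, part_a, net_b, part_b,
                                            config.edge_threshold)
        return nmss_scores(dist)

    arms = []
    per_tp_samples = []
    for t in tps:
        sids = list(meta.loc[meta["timepoint"] == t, "sample_id"])
        groups = set(meta.loc[meta["timepoint"] == t, "group"])
        if groups != {"control", "stress"}:
            warnings.warn(f"timepoint {t!r} lacks one condition; skipped",
                          stacklevel=2)
            continue
        arms.append(_split_arms(table, metadata, sids))
        per_tp_samples.append(sids)
    if len(arms) < 2:
        raise ValidationError("fewer than 2 usable timepoints")

    observed = integrated_scores(arms, seed)
    obs_mag = observed["raw"].abs()

    rng = np.random.default_rng(seed)
    exceed = pd.Series(0, index=obs_mag.index, dtype=int)
    taxa = list(arms[0][0].taxon_ids)
    for _ in range(n_permutations):
        perm_arms = []
        for (ta, tb), sids in zip(arms, per_tp_samples):
            pooled = np.vstack([ta.counts, tb.counts])
            pids = list(ta.sample_ids) + list(tb.sample_ids)
            idx = rng.permutation(len(pids))
            na = ta.n_samples
            pa = CountTable([pids[i] for i in idx[:na]], taxa, pooled[idx[:na]])
            pb = CountTable([pids[i] for i in idx[na:]], taxa, pooled[idx[na:]])
            perm_arms.append((pa, pb))
        null = integrated_scores(perm_arms, int(rng.integers(2 ** 31)))
        null_mag = null["raw"].abs().reindex(obs_mag.index).fillna(0.0)
        exceed += (null_mag >= obs_mag).astype(int)

    p = (1.0 + exceed) / (1.0 + n_permutations)
    out = observed.copy()
    out["p_value"] = p
    out["q_value"] = benjamini_hochberg(p.to_numpy())
    all_a = CountTable(
        [s for (ta, _), _s in zip(arms, per_tp_samples) for s in ta.sample_ids],
        taxa,
        np.vstack([ta.counts for ta, _ in arms]))
    all_b = CountTable(
        [s for (_, tb), _s in zip(arms, per_tp_samples) for s in tb.sample_ids],
        taxa,
        np.vstack([tb.counts for _, tb in arms]))
    out["direction"] = _direction(all_a, all_b, list(out.index))
    out["mode"] = "longitudinal"
    out["timepoint"] = "all"
    return out


def significant_biomarkers(result: pd.DataFrame,
                           fdr: float = 0.05) -> pd.DataFrame:
    """Taxa passing the FDR cut, ranked by normalized score."""
    hit = result[result["q_value"] < fdr]
    return hit.sort_values("nmss", ascending=False)
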