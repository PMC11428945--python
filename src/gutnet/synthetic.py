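"""Synthetic longitudinal two-arm microbiome communities with known truth.

The generator emulates the product of a 16S amplicon workflow after denoising
and genus aggregation: a sparse compositional count table for two experimental
arms (control vs stress) sampled at several timepoints, with

* planted co-occurrence modules — the latent (basis) log-abundances are drawn
  from a multivariate normal whose correlation matrix is block structured:
  within-block correlation ``basis_correlation_within_module``, between-block
  correlation 0;
* planted differential "driver" taxa whose mean abundance is shifted in the
  stress arm by ``driver_log2_effect`` log2 units and which can additionally be
  rewired into a different correlation block (``driver_rewire``), i.e. change
  module membership between conditions;
* per-sample sequencing depths drawn from a rounded log-normal with
  configurable coefficient of variation, then multinomial count draws from the
  normalized latent composition.

A log-normal basis plus multinomial sampling is used (rather than
Dirichlet-multinomial) because the network-inference stage estimates
correlations of log basis abundances; with this generator the planted
correlation matrix is exactly the quantity that stage targets, making
parameter-recovery tests well-posed.

Sex is generated as a label with zero effect, providing a built-in null for
the multivariate sex test downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import CountTable, SampleMetadata, ValidationError


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    Defaults mirror a genus-level longitudinal two-arm 16S study: 150 genera,
    30 samples per arm at each of three timepoints (60 samples per timepoint),
    mean sequencing depth 55,000 reads (comfortably above a rarefaction depth
    of 31,731) with CV 0.3.
    """

    n_taxa: int = 150
    n_samples_per_group_per_timepoint: int = 30
    n_timepoints: int = 3
    module_sizes: list[int] = field(default_factory=lambda: [25, 20, 15, 10])
    basis_correlation_within_module: float = 0.7
    driver_taxa: list[int] = field(default_factory=list)
    driver_log2_effect: float = 0.0
    driver_rewire: bool = False
    sequencing_depth_mean: int = 55_000
    sequencing_depth_dispersion: float = 0.3  # CV of the log-normal depth law
    log_abundance_sd: float = 1.0
    timepoint_labels: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_taxa:
            raise ConfigError("sum of module_sizes exceeds n_taxa")
        if not -1.0 < self.basis_correlation_within_module < 1.0:
            raise ConfigError("within-module correlation must lie in (-1, 1)")
        if any(i < 0 or i >= self.n_taxa for i in self.driver_taxa):
            raise ConfigError("driver taxon index out of range")
        if self.timepoint_labels is None:
            self.timepoint_labels = [f"t{k + 1}" for k in range(self.n_timepoints)]
        if len(self.timepoint_labels) != self.n_timepoints:
            raise ConfigError("timepoint_labels length != n_timepoints")


@dataclass
class GroundTruth:
    """What the generator planted, for benchmarking downstream inference."""

    basis_correlation: dict[str, np.ndarray]        # condition -> (p, p)
    module_assignment: dict[str, dict[str, int]]    # condition -> taxon -> block
    drivers: list[str]
    taxon_ids: list[str]

    def to_jsonable(self) -> dict:
        return {
            "module_assignment": self.module_assignment,
            "drivers": self.drivers,
            "taxon_ids": self.taxon_ids,
        }


def _block_correlation(n_taxa: int, module_sizes: list[int], rho: float,
                       assignment: np.ndarray) -> np.ndarray:
    """Unit-diagonal correlation matrix: rho within blocks, 0 between.

    ``assignment[i]`` is the block of taxon i, -1 for unassigned taxa.
    """
    sigma = np.eye(n_taxa)
    for b in range(len(module_sizes)):
        idx = np.where(assignment == b)[0]
        for i in idx:
            sigma[i, idx] = rho
            sigma[i, i] = 1.0
    return sigma


def _check_psd(sigma: np.ndarray) -> None:
    w = np.linalg.eigvalsh(sigma)
    if w.min() < -1e-8:
        # nearest-PSD hint: clip eigenvalues at 0 and renormalize
        raise ConfigError(
            "requested basis correlation matrix is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g}); consider projecting to the "
            "nearest PSD matrix by clipping negative eigenvalues to zero"
        )


def _module_assignment(config: SimulationConfig) -> np.ndarray:
    assignment = np.full(config.n_taxa, -1)
    start = 0
    for b, size in enumerate(config.module_sizes):
        assignment[start:start + size] = b
        start += size
    return assignment


def _rewire(assignment: np.ndarray, drivers: list[int],
            n_blocks: int) -> np.ndarray:
    """Move each driver to the next block (cyclically); unassigned drivers
    join block 0."""
    out = assignment.copy()
    for i in drivers:
        b = assignment[i]
        out[i] = (b + 1) % n_blocks if b >= 0 else 0
    return out


def _draw_condition(rng: np.random.Generator, config: SimulationConfig,
                    sigma_chol: np.ndarray, mu: np.ndarray,
                    n_samples: int) -> np.ndarray:
    """Latent log-abundances -> composition -> multinomial counts."""
    p = config.n_taxa
    z = rng.standard_normal((n_samples, p)) @ sigma_chol.T
    log_abund = mu + config.log_abundance_sd * z
    abund = np.exp(log_abund)
    comp = abund / abund.sum(axis=1, keepdims=True)
    cv = config.sequencing_depth_dispersion
    # log-normal with mean sequencing_depth_mean and CV cv, rounded
    sigma_d = np.sqrt(np.log1p(cv ** 2))
    mu_d = np.log(config.sequencing_depth_mean) - sigma_d ** 2 / 2
    depths = np.maximum(1, np.round(rng.lognormal(mu_d, sigma_d, n_samples))
                        ).astype(np.int64)
    counts = np.empty((n_samples, p), dtype=np.int64)
    for s in range(n_samples):
        counts[s] = rng.multinomial(depths[s], comp[s])
    return counts


def simulate_counts(config: SimulationConfig,
                    _effect_scale_per_timepoint: list[float] | None = None,
                    ) -> tuple[CountTable, SampleMetadata, GroundTruth]:
    """Simulate the full two-arm longitudinal study.

    Returns the count table (samples x taxa), metadata (group, sex, pen,
    timepoint), and the planted ground truth. Fixed ``config.seed`` gives
    bit-identical output.

    ``_effect_scale_per_timepoint`` scales the driver effect (mean shift and,
    if enabled, rewiring strength) per timepoint; used by
    :func:`simulate_resilience_trajectory`.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_taxa
    taxon_ids = [f"g{i:03d}" for i in range(p)]
    n_blocks = len(config.module_sizes)

    assign_control = _module_assignment(config)
    rho = config.basis_correlation_within_module
    sigma_control = _block_correlation(p, config.module_sizes, rho, assign_control)
    _check_psd(sigma_control)

    if config.driver_rewire and config.driver_taxa:
        assign_stress = _rewire(assign_control, config.driver_taxa, n_blocks)
        sigma_stress_full = _block_correlation(
            p, config.module_sizes, rho, assign_stress)
        _check_psd(sigma_stress_full)
    else:
        assign_stress = assign_control
        sigma_stress_full = sigma_control

    # heterogeneous baseline mean log-abundances (taxon-specific carrying
    # capacities); shared between arms
    mu0 = rng.normal(0.0, 1.0, p)
    shift = np.zeros(p)
    shift[list(config.driver_taxa)] = config.driver_log2_effect * np.log(2.0)

    scales = _effect_scale_per_timepoint or [1.0] * config.n_timepoints
    if len(scales) != config.n_timepoints:
        raise ConfigError("effect scale list length != n_timepoints")

    chol_control = np.linalg.cholesky(sigma_control + 1e-10 * np.eye(p))

    blocks: list[np.ndarray] = []
    meta_rows = []
    n_per = config.n_samples_per_group_per_timepoint
    sample_counter = 0
    for t_idx, t_label in enumerate(config.timepoint_labels):
        s = scales[t_idx]
        if config.driver_rewire and config.driver_taxa and s > 0:
            sigma_t = (1 - s) * sigma_control + s * sigma_stress_full
            chol_stress = np.linalg.cholesky(sigma_t + 1e-10 * np.eye(p))
        else:
            chol_stress = chol_control
        for group, chol, mu in (
            ("control", chol_control, mu0),
            ("stress", chol_stress, mu0 + s * shift),
        ):
            counts = _draw_condition(rng, config, chol, mu, n_per)
            blocks.append(counts)
            for k in range(n_per):
                sex = "female" if k % 2 == 0 else "castrated_male"
                pen = f"pen{(k % 4) + 1}_{group[0]}"
                meta_rows.append({
                    "sample_id": f"s{sample_counter:04d}",
                    "group": group,
                    "sex": sex,
                    "pen": pen,
                    "timepoint": t_label,
                })
                sample_counter += 1

    counts = np.vstack(blocks)
    sample_ids = [r["sample_id"] for r in meta_rows]
    table = CountTable(sample_ids, taxon_ids, counts)
    meta = SampleMetadata(pd.DataFrame(meta_rows),
                          list(config.timepoint_labels))
    truth = GroundTruth(
        basis_correlation={"control": sigma_control,
                           "stress": sigma_stress_full},
        module_assignment={
            "control": {taxon_ids[i]: int(assign_control[i]) for i in range(p)},
            "stress": {taxon_ids[i]: int(assign_stress[i]) for i in range(p)},
        },
        drivers=[taxon_ids[i] for i in config.driver_taxa],
        taxon_ids=taxon_ids,
    )
    return table, meta, truth


def simulate_latent(config: SimulationConfig, n_samples: int,
                    condition: str = "control") -> np.ndarray:
    """Draw latent log-abundances only (no sampling noise).

    Exposes the multivariate-normal layer of the generator so planted basis
    correlations can be checked directly against their sample estimates.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_taxa
    assign = _module_assignment(config)
    rho = config.basis_correlation_within_module
    sigma = _block_correlation(p, config.module_sizes, rho, assign)
    if condition == "stress" and config.driver_rewire and config.driver_taxa:
        assign = _rewire(assign, config.driver_taxa, len(config.module_sizes))
        sigma = _block_correlation(p, config.module_sizes, rho, assign)
    _check_psd(sigma)
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(p))
    mu = rng.normal(0.0, 1.0, p)
    z = rng.standard_normal((n_samples, p)) @ chol.T
    return mu + config.log_abundance_sd * z


def simulate_resilience_trajectory(config: SimulationConfig,
                                   perturbed_timepoint: str,
                                   recovery_fraction: float,
                                   ) -> tuple[CountTable, SampleMetadata, GroundTruth]:
    """Acute perturbation with partial recovery.

    The driver effect is applied in full at ``perturbed_timepoint``, scaled by
    ``1 - recovery_fraction`` at every later timepoint, and absent earlier —
    emulating a microbiota that drifts back toward its baseline after an acute
    stress event.
    """
    if not 0.0 <= recovery_fraction <= 1.0:
        raise ConfigError("recovery_fraction must lie in [0, 1]")
    labels = config.timepoint_labels or []
    if perturbed_timepoint not in labels:
        raise ConfigError(
            f"unknown timepoint {perturbed_timepoint!r}; have {labels}")
    t_star = labels.index(perturbed_timepoint)
    scales = []
    for t in range(config.n_timepoints):
        if t < t_star:
            scales.append(0.0)
        elif t == t_star:
            scales.append(1.0)
        else:
            scales.append(1.0 - recovery_fraction)
    return simulate_counts(config, _effect_scale_per_timepoint=scales)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
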