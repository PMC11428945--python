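"""Alpha diversity, beta diversity, ordination and PERMANOVA.

Alpha indices (Shannon, Simpson, Chao1, ACE) are computed per sample via
scikit-bio; Shannon defaults to natural log (nats). Beta diversity is exposed
both as the Bray-Curtis distance matrix (for PCoA / PERMANOVA) and as the
Whittaker turnover index gamma / mean(alpha) - 1 on presence/absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as skbio_alpha
from skbio.stats.distance import DistanceMatrix, permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from .data_io import CountTable, ValidationError


def shannon(counts_row: np.ndarray, base: float = np.e) -> float:
    """Shannon entropy H = -sum p_i log p_i over nonzero p_i (nats by
    default; set ``base`` for other logarithms)."""
    row = np.asarray(counts_row, dtype=float)
    if row.sum() <= 0:
        raise ValidationError("Shannon undefined for an all-zero sample")
    return float(skbio_alpha.shannon(row, base=base))


def alpha_suite(table: CountTable, base: float = np.e) -> pd.DataFrame:
    """Per-sample Shannon, Simpson (1 - sum p^2), bias-corrected Chao1 and
    ACE. Chao1/ACE require integer counts (they read singleton/doubleton
    frequencies)."""
    if not np.issubdtype(table.counts.dtype, np.integer):
        raise ValidationError("Chao1/ACE require integer counts")
    rows = []
    for i, sid in enumerate(table.sample_ids):
        c = table.counts[i]
        try:
            ace_val = float(skbio_alpha.ace(c))
        except (ZeroDivisionError, ValueError):
            # no rare taxa to extrapolate from: estimate equals observed richness
            ace_val = float((c > 0).sum())
        rows.append({
            "sample_id": sid,
            "shannon": float(skbio_alpha.shannon(c, base=base)),
            "simpson": float(skbio_alpha.simpson(c)),
            "chao1": float(skbio_alpha.chao1(c, bias_corrected=True)),
            "ace": ace_val,
        })
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis distance d(u, v) = 1 - 2 sum min(u_i, v_i) / (sum u + sum v)."""
    if table.n_samples < 2:
        raise ValidationError("need at least two samples")
    if (table.counts.sum(axis=1) == 0).any():
        raise ValidationError("Bray-Curtis undefined for all-zero samples")
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


def whittaker_beta(table: CountTable, sample_ids: list[str] | None = None,
                   turnover: bool = True) -> float:
    """Whittaker beta diversity on presence/absence.

    ``turnover=True`` gives gamma / mean(alpha) - 1, which is 0 when all
    samples share an identical composition; ``False`` gives the raw ratio
    gamma / mean(alpha).
    """
    sub = table if sample_ids is None else table.select_samples(sample_ids)
    if sub.n_samples == 0:
        raise ValidationError("empty sample subset")
    presence = sub.counts > 0
    gamma = int(presence.any(axis=0).sum())
    mean_alpha = float(presence.sum(axis=1).mean())
    if mean_alpha == 0:
        raise ValidationError("subset has no observed taxa")
    ratio = gamma / mean_alpha
    return ratio - 1.0 if turnover else ratio


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame   # samples x axes
    eigenvalues: np.ndarray     # all eigenvalues incl. negatives
    proportion_explained: np.ndarray


def pcoa(dist: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Classical scaling (Gower-centred -D^2/2). Axes are limited to positive
    eigenvalues; signs are fixed so each axis' first nonzero loading is
    positive (ordination sign is otherwise arbitrary)."""
    res = skbio_pcoa(dist, method="eigh", warn_neg_eigval=False)
    eig = res.eigvals.to_numpy()
    n_pos = int((eig > 1e-10).sum())
    k = min(n_axes, n_pos)
    coords = res.samples.iloc[:, :k].copy()
    for col in coords.columns:
        v = coords[col].to_numpy()
        nz = np.nonzero(np.abs(v) > 1e-12)[0]
        if nz.size and v[nz[0]] < 0:
            coords[col] = -v
    return PcoaResult(coordinates=coords, eigenvalues=eig,
                      proportion_explained=res.proportion_explained.to_numpy())


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int


def permanova(dist: DistanceMatrix, labels, n_permutations: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Distance-based pseudo-F with a label-permutation null.

    p = (1 + #{F_perm >= F_obs}) / (1 + P), so p is never exactly 0.
    """
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2 or (counts < 2).any():
        raise ValidationError(
            "PERMANOVA needs >= 2 groups with >= 2 samples each")
    res = skbio_permanova(dist, labels, permutations=n_permutations, seed=seed)
    f = float(res["test statistic"])
    # R^2 from the same partition: F = (SSB/(a-1)) / (SSW/(n-a))
    a, n = len(groups), len(labels)
    r2 = (f * (a - 1)) / (f * (a - 1) + (n - a))
    return PermanovaResult(pseudo_F=f, R2=float(r2),
                           p_value=float(res["p-value"]),
                           n_permutations=n_permutations)
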