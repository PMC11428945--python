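"""Count-level filtering, rarefaction and taxonomic aggregation.

The canonical order of operations is: remove singletons, drop taxa at or below
the global low-abundance threshold, then rarefy every sample to a common depth
(default 31,731 reads) by subsampling without replacement. Aggregation to a
taxonomic rank (Phylum..Genus) can be applied at any point; it conserves the
grand total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import CountTable, TAXONOMIC_RANKS, ValidationError

DEFAULT_RAREFACTION_DEPTH = 31_731
DEFAULT_MIN_FRACTION = 1e-6  # 0.0001% of the pooled read total


@dataclass
class FilterReport:
    n_taxa_in: int = 0
    n_removed_singletons: int = 0
    n_removed_low_abundance: int = 0
    n_samples_dropped: int = 0
    rarefaction_depth: int | None = None
    steps: list[str] = field(default_factory=list)

    def merge(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            n_taxa_in=self.n_taxa_in or other.n_taxa_in,
            n_removed_singletons=self.n_removed_singletons
            + other.n_removed_singletons,
            n_removed_low_abundance=self.n_removed_low_abundance
            + other.n_removed_low_abundance,
            n_samples_dropped=self.n_samples_dropped + other.n_samples_dropped,
            rarefaction_depth=other.rarefaction_depth or self.rarefaction_depth,
            steps=self.steps + other.steps,
        )


def remove_singletons(table: CountTable) -> tuple[CountTable, FilterReport]:
    """Drop taxa whose total count across all samples equals exactly 1."""
    totals = table.counts.sum(axis=0)
    keep = totals != 1
    out = table.select_taxa([t for t, k in zip(table.taxon_ids, keep) if k])
    report = FilterReport(n_taxa_in=table.n_taxa,
                          n_removed_singletons=int((~keep).sum()),
                          steps=["remove_singletons"])
    return out, report


def filter_low_abundance(table: CountTable,
                         fraction: float = DEFAULT_MIN_FRACTION,
                         ) -> tuple[CountTable, FilterReport]:
    """Retain a taxon iff its pooled count exceeds ``fraction`` of the grand
    total (strict inequality). The grand total is computed before removal."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    totals = table.counts.sum(axis=0)
    grand = table.counts.sum()
    keep = totals > fraction * grand
    out = table.select_taxa([t for t, k in zip(table.taxon_ids, keep) if k])
    report = FilterReport(n_taxa_in=table.n_taxa,
                          n_removed_low_abundance=int((~keep).sum()),
                          steps=["filter_low_abundance"])
    return out, report


def rarefy(table: CountTable, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int = 0) -> tuple[CountTable, FilterReport]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped (and counted in the
    report), never padded. Subsampling uses the multivariate hypergeometric
    distribution, i.e. drawing reads uniformly without replacement, which
    leaves a sample untouched when its total equals ``depth``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    survive = totals >= depth
    if not survive.any():
        raise ValidationError("no samples survive rarefaction")
    rows = []
    for i in np.where(survive)[0]:
        row = table.counts[i]
        if totals[i] == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    out = CountTable(
        [s for s, k in zip(table.sample_ids, survive) if k],
        list(table.taxon_ids),
        np.asarray(rows, dtype=np.int64),
        table.taxonomy,
    )
    report = FilterReport(n_taxa_in=table.n_taxa,
                          n_samples_dropped=int((~survive).sum()),
                          rarefaction_depth=depth,
                          steps=["rarefy"])
    return out, report


def aggregate_to_rank(table: CountTable, rank: str = "Genus") -> CountTable:
    """Sum counts over taxa sharing the lineage down to ``rank``.

    Taxa unclassified at ``rank`` are grouped under their lowest classified
    level with an ``unclassified_`` prefix, e.g. ``unclassified_f__Lachnospiraceae``.
    """
    if rank not in TAXONOMIC_RANKS:
        raise ValueError(f"rank must be one of {TAXONOMIC_RANKS}")
    if table.taxonomy is None or any(
            t not in table.taxonomy for t in table.taxon_ids):
        raise ValidationError("aggregation requires taxonomy for every taxon")
    rank_idx = TAXONOMIC_RANKS.index(rank)
    groups: dict[str, list[int]] = {}
    for j, t in enumerate(table.taxon_ids):
        lineage = table.taxonomy[t]
        levels = [lineage.get(r) for r in TAXONOMIC_RANKS[:rank_idx + 1]]
        if levels and levels[-1]:
            label = ";".join(x for x in levels if x)
        else:
            classified = [x for x in levels if x]
            label = ("unclassified_" + classified[-1]) if classified \
                else "unclassified_unknown"
        groups.setdefault(label, []).append(j)
    labels = list(groups)
    mat = np.zeros((table.n_samples, len(labels)), dtype=np.int64)
    for k, label in enumerate(labels):
        mat[:, k] = table.counts[:, groups[label]].sum(axis=1)
    return CountTable(list(table.sample_ids), labels, mat)


def relative_abundance(table: CountTable) -> np.ndarray:
    """Row-normalized matrix; every row sums to 1. All-zero samples are an
    error."""
    totals = table.counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals.ravel()) if t == 0]
        raise ValidationError(f"all-zero sample(s): {bad}")
    return table.counts / totals


def standard_filter_chain(table: CountTable,
                          fraction: float = DEFAULT_MIN_FRACTION,
                          depth: int = DEFAULT_RAREFACTION_DEPTH,
                          seed: int = 0) -> tuple[CountTable, FilterReport]:
    """Singletons -> low-abundance -> rarefaction, with a merged report."""
    t1, r1 = remove_singletons(table)
    t2, r2 = filter_low_abundance(t1, fraction)
    t3, r3 = rarefy(t2, depth, seed)
    return t3, r1.merge(r2).merge(r3)
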