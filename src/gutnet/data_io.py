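"""Tables, metadata and result I/O.

Every pipeline stage exchanges data through three containers defined here:

``CountTable``
    an integer sample x taxon abundance matrix with optional ranked taxonomy,
``SampleMetadata``
    per-sample annotations (group, sex, pen, timepoint) with a closed group
    vocabulary and totally ordered timepoints,
``ResultTable``
    a thin validated wrapper around a :class:`pandas.DataFrame` for scores,
    p-values and q-values.

On disk everything is TSV (tab-delimited, header row, UTF-8); count tables can
additionally be read from the dense JSON BIOM variant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TAXONOMIC_RANKS = ("Phylum", "Class", "Order", "Family", "Genus")

GROUP_LABELS = ("control", "stress")
SEX_LABELS = ("female", "castrated_male")


class ValidationError(ValueError):
    """An input violates a data-model invariant."""


class SchemaError(ValidationError):
    """A file is missing required columns or uses an unknown vocabulary."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Sample x taxon matrix of non-negative integer counts.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers (rows).
    taxon_ids : list of str
        Unique taxon identifiers (columns); ASVs or genera.
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative integers.
    taxonomy : dict, optional
        ``taxon_id -> {rank: name}`` ranked lineage (Phylum..Genus). Keys must
        be a subset of ``taxon_ids``.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, dict[str, str]] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        n_s, n_t = self.counts.shape
        if n_s != len(self.sample_ids) or n_t != len(self.taxon_ids):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.sample_ids)) != n_s:
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample IDs: {dupes}")
        if len(set(self.taxon_ids)) != n_t:
            dupes = _duplicates(self.taxon_ids)
            raise ValidationError(f"duplicate taxon IDs: {dupes}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.round(self.counts).astype(np.int64)
            if not np.allclose(self.counts, as_int, atol=1e-9):
                raise ValidationError("counts must be integers")
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.taxon_ids)
            if unknown:
                raise ValidationError(
                    f"taxonomy refers to unknown taxa: {sorted(unknown)[:5]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids,
                            columns=self.taxon_ids)

    def select_samples(self, keep: list[str]) -> "CountTable":
        """Subset (and reorder) samples by ID."""
        idx = [self.sample_ids.index(s) for s in keep]
        return CountTable(list(keep), list(self.taxon_ids),
                          self.counts[idx], self.taxonomy)

    def select_taxa(self, keep: list[str]) -> "CountTable":
        idx = [self.taxon_ids.index(t) for t in keep]
        tax = None
        if self.taxonomy is not None:
            tax = {t: self.taxonomy[t] for t in keep if t in self.taxonomy}
        return CountTable(list(self.sample_ids), list(keep),
                          self.counts[:, idx], tax)


def _duplicates(ids: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in ids:
        if x in seen:
            out.append(x)
        seen.add(x)
    return out


def read_count_table(path, format: str = "tsv",
                     taxa_as_rows: bool = True) -> CountTable:
    """Read a count table from TSV or dense-JSON BIOM.

    TSV layout defaults to the common amplicon convention, taxa as rows and
    samples as columns (``taxa_as_rows=True``); pass ``False`` for the
    transposed layout. Internally everything is samples x taxa.
    """
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValidationError(f"cannot parse {path}: {exc}") from exc
        if df.isna().any().any():
            row = df.index[df.isna().any(axis=1)][0]
            raise ValidationError(
                f"missing count value(s), first at row {row!r}; "
                "empty cells are an error, not zero"
            )
        try:
            mat = df.astype(float).to_numpy()
        except ValueError as exc:
            raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
        if taxa_as_rows:
            return CountTable(list(df.columns), list(df.index), mat.T)
        return CountTable(list(df.index), list(df.columns), mat)
    if format == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("matrix_type") != "dense":
            raise ValidationError(
                "only the dense JSON BIOM variant is supported"
            )
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        mat = np.asarray(doc["data"], dtype=float)  # BIOM is observation x sample
        taxonomy = {}
        for r in doc["rows"]:
            lineage = (r.get("metadata") or {}).get("taxonomy")
            if lineage:
                taxonomy[r["id"]] = dict(zip(TAXONOMIC_RANKS, lineage))
        return CountTable(samples, taxa, mat.T, taxonomy or None)
    raise ValueError(f"unknown format {format!r}")


def write_count_table(table: CountTable, path, taxa_as_rows: bool = True) -> None:
    df = table.to_frame()
    if taxa_as_rows:
        df = df.T
        df.index.name = "taxon_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path) -> dict[str, dict[str, str]]:
    """Read a taxonomy TSV: taxon_id column plus rank columns Phylum..Genus."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "taxon_id" not in df.columns:
        raise SchemaError("taxonomy file must have a 'taxon_id' column")
    ranks = [r for r in TAXONOMIC_RANKS if r in df.columns]
    out: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        out[row["taxon_id"]] = {
            r: row[r] for r in ranks if isinstance(row[r], str) and row[r]
        }
    return out


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-sample annotations with validated vocabularies.

    ``timepoints`` holds the total order of timepoint labels (ascending);
    labels like ``07_2022 < 09_2022 < 10_2022`` sort lexicographically, but the
    explicit order is kept so arbitrary labels also work.
    """

    frame: pd.DataFrame
    timepoints: list[str] = field(default_factory=list)

    REQUIRED = ("sample_id", "group", "timepoint")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"metadata missing required column(s): {missing}")
        if self.frame["sample_id"].duplicated().any():
            d = self.frame["sample_id"][self.frame["sample_id"].duplicated()]
            raise ValidationError(f"duplicate sample_id in metadata: {list(d)}")
        bad = set(self.frame["group"]) - set(GROUP_LABELS)
        if bad:
            raise SchemaError(
                f"unknown group label(s) {sorted(bad)}; expected {GROUP_LABELS}"
            )
        if "sex" in self.frame.columns:
            bad = set(self.frame["sex"].dropna()) - set(SEX_LABELS)
            if bad:
                raise SchemaError(
                    f"unknown sex label(s) {sorted(bad)}; expected {SEX_LABELS}"
                )
        if not self.timepoints:
            self.timepoints = sorted(set(self.frame["timepoint"]))
        stray = set(self.frame["timepoint"]) - set(self.timepoints)
        if stray:
            raise ValidationError(f"timepoint(s) outside stated order: {stray}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def for_samples(self, sample_ids: list[str]) -> "SampleMetadata":
        """Align metadata to a CountTable's samples; orphans are an error."""
        sub = self.frame.set_index("sample_id")
        orphans = [s for s in sample_ids if s not in sub.index]
        if orphans:
            raise ValidationError(
                f"samples missing from metadata: {orphans}"
            )
        out = sub.loc[list(sample_ids)].reset_index()
        return SampleMetadata(out, list(self.timepoints))

    def column(self, name: str, sample_ids: list[str]) -> np.ndarray:
        return (self.for_samples(sample_ids).frame[name]).to_numpy()


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ResultTable
# ---------------------------------------------------------------------------

@dataclass
class ResultTable:
    """Keyed records with typed numeric columns (scores, p, q)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in self.frame.columns:
            if col in ("p_value", "q_value", "p", "q"):
                vals = pd.to_numeric(self.frame[col], errors="coerce").dropna()
                if ((vals < 0) | (vals > 1)).any():
                    raise ValidationError(f"column {col!r} outside [0, 1]")


def write_result(table: ResultTable, path, sig_digits: int = 6) -> None:
    """Write a ResultTable as TSV with deterministic column order and fixed
    significant-digit float formatting (byte-identical across reruns)."""
    df = table.frame
    df.to_csv(path, sep="\t", index=False,
              float_format=f"%.{sig_digits}g")


def read_result(path) -> ResultTable:
    return ResultTable(pd.read_csv(path, sep="\t"))
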