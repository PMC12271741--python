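"""Domain types, gene-table I/O, location collapsing, and curation filters.

The unit of analysis is one protein-coding gene carrying a branch-specific
evolutionary rate (omega = dN/dS), a protein abundance in ppm, a free-text
subcellular location label, and an optional binary essentiality call.
Location labels are collapsed into three compartment classes (Membrane,
Cytoplasm, Others) by a case-insensitive substring rule; dubious orthologs
are removed by Tukey-style interquartile fences on per-branch dS.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "CompartmentClass",
    "GeneRecord",
    "CurationConfig",
    "CurationResult",
    "ConfigurationError",
    "GeneTableParseError",
    "read_gene_table",
    "write_gene_table",
    "collapse_location",
    "location_is_ambiguous",
    "iqr_upper_fence",
    "curate",
    "records_to_frame",
    "write_rejection_log",
]


class ConfigurationError(ValueError):
    """Raised when the input table or configuration is structurally invalid."""


class GeneTableParseError(ValueError):
    """Raised when a row holds a malformed (non-missing, non-numeric) value."""


class CompartmentClass(str, Enum):
    MEMBRANE = "Membrane"
    CYTOPLASM = "Cytoplasm"
    OTHERS = "Others"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: tokens interpreted as "missing" in numeric/boolean columns
MISSING_TOKENS = frozenset({"", "na", "nan", "none", "null", "."})

#: columns that must be present (after dialect mapping)
REQUIRED_COLUMNS = ("gene_id", "omega", "ds", "abundance", "location_label")
OPTIONAL_COLUMNS = ("dn", "essential", "species_tag")

_TRUE_TOKENS = frozenset({"1", "true", "t", "yes", "y", "essential"})
_FALSE_TOKENS = frozenset({"0", "false", "f", "no", "n", "nonessential", "non-essential"})


@dataclass
class GeneRecord:
    """One gene's rates, abundance, location, and essentiality.

    ``omega``/``dn``/``ds`` are nonnegative; ``abundance`` (ppm) is positive
    when present. ``compartment`` is always the deterministic collapse of
    ``location_label``. ``extra_ds`` holds additional per-branch dS columns
    (e.g. the sister-lineage branch) used for curation fencing.
    """

    gene_id: str
    omega: Optional[float] = None
    dn: Optional[float] = None
    ds: Optional[float] = None
    abundance: Optional[float] = None
    location_label: Optional[str] = None
    compartment: Optional[CompartmentClass] = None
    essential: Optional[bool] = None
    species_tag: str = ""
    extra_ds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("omega", "dn", "ds"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v!r} for {self.gene_id}")
        if self.abundance is not None and self.abundance <= 0:
            raise ValueError(f"abundance must be positive, got {self.abundance!r} for {self.gene_id}")
        if self.compartment is None and self.location_label:
            self.compartment = collapse_location(self.location_label)


@dataclass
class CurationConfig:
    """Settings for ortholog-table curation.

    iqr_multiplier : Tukey fence multiplier k; the upper fence is
        Q3 + k * (Q3 - Q1) with linear-interpolation quartiles.
    ds_columns : which per-branch dS columns to fence ("ds" is the focal
        branch; other names look up ``GeneRecord.extra_ds``).
    ds_fences : optional explicit fences per column. When absent, fences
        are estimated from the input sample and recorded in the result so
        curation is reproducible and idempotent given the recorded fences.
    """

    iqr_multiplier: float = 1.5
    ds_columns: Sequence[str] = ("ds",)
    require_location: bool = True
    require_essentiality: bool = True
    ds_fences: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.iqr_multiplier <= 0:
            raise ConfigurationError("iqr_multiplier must be positive")


@dataclass
class CurationResult:
    kept: list
    rejected: list  # list of (gene_id, reason)
    fences: dict  # column -> fence actually applied

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def collapse_location(location_label: str) -> CompartmentClass:
    """Collapse a free-text subcellular location into a compartment class.

    Case-insensitive substring test: any label containing "membrane" maps to
    Membrane (taking precedence over "cytoplasm": membrane anchoring is the
    physical commitment); containing "cytoplasm" maps to Cytoplasm; anything
    else to Others.
    """
    if not location_label or not location_label.strip():
        raise ValueError("location label must be a non-empty string")
    lab = location_label.lower()
    if "membrane" in lab:
        return CompartmentClass.MEMBRANE
    if "cytoplasm" in lab:
        return CompartmentClass.CYTOPLASM
    return CompartmentClass.OTHERS


def location_is_ambiguous(location_label: str) -> bool:
    """True when the label names both a membrane and a cytoplasmic context."""
    lab = location_label.lower()
    return "membrane" in lab and "cytoplasm" in lab


def iqr_upper_fence(values: Sequence[float], k: float = 1.5) -> float:
    """Upper Tukey fence Q3 + k*(Q3 - Q1), linear-interpolation quartiles."""
    if k <= 0:
        raise ValueError("k must be positive")
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 4:
        raise ValueError(f"need at least 4 finite values for an IQR fence, got {arr.size}")
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # numpy default: linear (type 7)
    return float(q3 + k * (q3 - q1))


def _parse_float(token: str, column: str, row_index: int) -> Optional[float]:
    tok = token.strip()
    if tok.lower() in MISSING_TOKENS:
        return None
    try:
        return float(tok)
    except ValueError:
        raise GeneTableParseError(
            f"row {row_index}: column {column!r} holds non-numeric value {token!r}"
        ) from None


def _parse_bool(token: str, column: str, row_index: int) -> Optional[bool]:
    tok = token.strip().lower()
    if tok in MISSING_TOKENS:
        return None
    if tok in _TRUE_TOKENS:
        return True
    if tok in _FALSE_TOKENS:
        return False
    raise GeneTableParseError(
        f"row {row_index}: column {column!r} holds non-boolean value {token!r}"
    )


def read_gene_table(
    path,
    dialect: Optional[Mapping[str, str]] = None,
    extra_ds_columns: Sequence[str] = (),
) -> list[GeneRecord]:
    """Read a tab-separated gene table into GeneRecords (row order preserved).

    ``dialect`` maps canonical field names to the file's column names, e.g.
    ``{"omega": "w_branch", "abundance": "ppm"}``. Required fields: gene_id,
    omega, ds, abundance, location_label; optional: dn, essential,
    species_tag. Missing optional values stay missing, never silently zero.
    Each name in ``extra_ds_columns`` is read (via the dialect) into
    ``extra_ds`` for per-branch fencing.
    """
    dialect = dict(dialect or {})

    def col(name: str) -> str:
        return dialect.get(name, name)

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for name in REQUIRED_COLUMNS:
            if col(name) not in header:
                raise ConfigurationError(
                    f"gene table {path} lacks required column {col(name)!r} (field {name})"
                )
        for name in extra_ds_columns:
            if col(name) not in header:
                raise ConfigurationError(
                    f"gene table {path} lacks dS column {col(name)!r}"
                )
        has = {name: col(name) in header for name in OPTIONAL_COLUMNS}
        records: list[GeneRecord] = []
        for i, row in enumerate(reader):
            label = (row[col("location_label")] or "").strip()
            if label.lower() in MISSING_TOKENS:
                label = None
            rec = GeneRecord(
                gene_id=row[col("gene_id")].strip(),
                omega=_parse_float(row[col("omega")] or "", "omega", i),
                dn=_parse_float(row[col("dn")] or "", "dn", i) if has["dn"] else None,
                ds=_parse_float(row[col("ds")] or "", "ds", i),
                abundance=_parse_float(row[col("abundance")] or "", "abundance", i),
                location_label=label,
                essential=_parse_bool(row[col("essential")] or "", "essential", i)
                if has["essential"]
                else None,
                species_tag=(row[col("species_tag")] or "").strip() if has["species_tag"] else "",
                extra_ds={
                    name: _parse_float(row[col(name)] or "", name, i) for name in extra_ds_columns
                },
            )
            records.append(rec)
    return records


def write_gene_table(records: Iterable[GeneRecord], path, extra_ds_columns: Sequence[str] = ()) -> None:
    """Write GeneRecords to the standard TSV layout."""

    def fmt(v):
        if v is None:
            return "NA"
        if isinstance(v, bool):
            return "1" if v else "0"
        if isinstance(v, float):
            return repr(v)
        return str(v)

    cols = ["gene_id", "omega", "dn", "ds", "abundance", "location_label", "essential", "species_tag"]
    cols += list(extra_ds_columns)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [
                r.gene_id,
                fmt(r.omega),
                fmt(r.dn),
                fmt(r.ds),
                fmt(r.abundance),
                r.location_label or "NA",
                fmt(r.essential),
                r.species_tag or "NA",
            ]
            row += [fmt(r.extra_ds.get(name)) for name in extra_ds_columns]
            fh.write("\t".join(row) + "\n")


def _ds_value(record: GeneRecord, column: str) -> Optional[float]:
    if column == "ds":
        return record.ds
    return record.extra_ds.get(column)


def curate(records: Sequence[GeneRecord], config: CurationConfig) -> CurationResult:
    """Filter dubious orthologs and under-annotated genes.

    Removes records whose dS (in any column of ``config.ds_columns``)
    exceeds its per-branch upper IQR fence, then records missing a location
    label or (optionally) an essentiality call. Fences are taken from
    ``config.ds_fences`` when supplied, otherwise estimated from the input
    sample; the fences applied are returned so the operation can be replayed
    exactly (applying curate again with the recorded fences is the identity).
    """
    fences: dict[str, float] = {}
    if config.ds_fences is not None:
        fences = dict(config.ds_fences)
    else:
        for column in config.ds_columns:
            vals = [v for r in records if (v := _ds_value(r, column)) is not None]
            fences[column] = iqr_upper_fence(vals, config.iqr_multiplier)

    kept: list[GeneRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        reason = None
        for column in config.ds_columns:
            v = _ds_value(rec, column)
            if v is not None and v > fences[column]:
                reason = "ds_fence"
                break
        if reason is None and config.require_location and not rec.location_label:
            reason = "no_location"
        if reason is None and config.require_essentiality and rec.essential is None:
            reason = "no_essentiality"
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec.gene_id, reason))
    assert len(kept) + len(rejected) == len(records)
    return CurationResult(kept=kept, rejected=rejected, fences=fences)


def write_rejection_log(result: CurationResult, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("gene_id\treason\n")
        for gene_id, reason in result.rejected:
            fh.write(f"{gene_id}\t{reason}\n")


def records_to_frame(records: Sequence[GeneRecord]):
    """GeneRecords as a pandas DataFrame (compartment as its string value)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "omega": [r.omega for r in records],
            "dn": [r.dn for r in records],
            "ds": [r.ds for r in records],
            "abundance": [r.abundance for r in records],
            "location_label": [r.location_label for r in records],
            "compartment": [r.compartment.value if r.compartment else None for r in records],
            "essential": [r.essential for r in records],
            "species_tag": [r.species_tag for r in records],
        }
    )
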