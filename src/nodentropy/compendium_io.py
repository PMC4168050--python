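"""Reading, validation and serialization of expression compendia.

A compendium is a probe-set (gene) x condition matrix of hybridization
signals on the *linear* scale (RMA-style output, background around 9),
together with a condition-metadata table describing each column: the organ
the sample came from, any treatment applied, an optional timepoint (days
post inoculation for nodules, days after pollination for seeds, or hours),
and a sample class distinguishing whole organs from hand-dissected nodule
zones and laser-capture-microdissected (LCM) cell types.

All files are UTF-8 TSV.  The matrix has a header row whose first field is
``gene_id`` followed by condition ids; metadata and annotation tables have
one row per condition / gene.  Missing cells are a hard error: the source
compendia this layer targets are complete, and NaN appears only in derived
outputs (e.g. undefined entropy), where it serializes as ``NA``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ORGANS = (
    "leaf",
    "petiole",
    "stem",
    "bud",
    "flower",
    "seed",
    "pod",
    "root",
    "nodule",
    "mycorrhiza",
    "other",
)

ZONE_CLASSES = ("zone_I", "zone_II", "zone_II_III", "zone_III", "zone_IV")
LCM_CLASSES = ("lcm_M", "lcm_dIZ", "lcm_pIZ", "lcm_IC", "lcm_UC")
SAMPLE_CLASSES = ("whole_organ",) + ZONE_CLASSES + LCM_CLASSES

TIMEPOINT_UNITS = ("dpi", "dap", "hours")

GENE_FAMILIES = ("NCR", "senescence_marker", "bacterial_marker", "other")

METADATA_COLUMNS = (
    "condition_id",
    "organ",
    "treatment",
    "timepoint",
    "timepoint_unit",
    "sample_class",
    "replicate_group",
)

ANNOTATION_COLUMNS = ("gene_id", "family", "label")


class CompendiumError(Exception):
    """Base class for compendium I/O failures."""


class ValidationError(CompendiumError):
    """Structurally invalid compendium, metadata or annotation content."""


class ParseError(CompendiumError):
    """A cell could not be parsed; the message carries its coordinates."""


class MappingError(CompendiumError):
    """A referenced condition or gene does not exist."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class Compendium:
    """Validated signal matrix plus per-condition metadata.

    ``signals`` is genes (rows) x conditions (columns); ``conditions`` is
    indexed by condition id in the same order as the signal columns.
    """

    signals: pd.DataFrame
    conditions: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.signals.index

    @property
    def condition_ids(self) -> pd.Index:
        return self.signals.columns

    @property
    def n_genes(self) -> int:
        return self.signals.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.signals.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "Compendium":
        genes = list(genes)
        missing = [g for g in genes if g not in self.signals.index]
        if missing:
            raise MappingError(f"unknown gene_id(s): {missing[:5]}")
        return Compendium(self.signals.loc[genes], self.conditions.copy())

    def select_conditions(self, mask: pd.Series) -> list[str]:
        """Condition ids for which the boolean metadata ``mask`` holds."""
        return list(self.conditions.index[mask.reindex(self.conditions.index, fill_value=False)])

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        _check_unique(list(self.signals.index), "gene_id")
        _check_unique(list(self.signals.columns), "condition_id")
        if list(self.signals.columns) != list(self.conditions.index):
            cols = set(self.signals.columns)
            meta = set(self.conditions.index)
            only_meta = sorted(meta - cols)
            only_cols = sorted(cols - meta)
            if only_meta:
                raise ValidationError(
                    f"metadata rows without matrix column: {only_meta}"
                )
            if only_cols:
                raise ValidationError(
                    f"matrix columns without metadata: {only_cols}"
                )
            raise ValidationError(
                "condition order in metadata does not match matrix column order"
            )
        values = self.signals.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("signal matrix is not numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite signal for gene {self.signals.index[bad[0]]!r}, "
                f"condition {self.signals.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative signal for gene {self.signals.index[bad[0]]!r}, "
                f"condition {self.signals.columns[bad[1]]!r}"
            )
        validate_metadata(self.conditions)


def validate_metadata(meta: pd.DataFrame) -> None:
    for col in METADATA_COLUMNS[1:]:
        if col not in meta.columns:
            raise ValidationError(f"metadata is missing column {col!r}")
    bad_organ = sorted(set(meta["organ"]) - set(ORGANS))
    if bad_organ:
        raise ValidationError(f"unknown organ value(s): {bad_organ}")
    bad_class = sorted(set(meta["sample_class"]) - set(SAMPLE_CLASSES))
    if bad_class:
        raise ValidationError(f"unknown sample_class value(s): {bad_class}")
    zonal = meta["sample_class"].isin(ZONE_CLASSES)
    misplaced = meta.index[zonal & (meta["organ"] != "nodule")]
    if len(misplaced):
        raise ValidationError(
            f"zone sample_class outside nodule organ for condition(s) "
            f"{list(misplaced)}"
        )
    tp = meta["timepoint"]
    has_tp = tp.notna()
    if (tp[has_tp] < 0).any():
        bad = meta.index[has_tp & (tp < 0)][0]
        raise ValidationError(f"negative timepoint for condition {bad!r}")
    units = meta.loc[has_tp, "timepoint_unit"]
    bad_unit = sorted(set(units.dropna()) - set(TIMEPOINT_UNITS))
    if bad_unit:
        raise ValidationError(f"unknown timepoint_unit value(s): {bad_unit}")


@dataclass
class GeneAnnotation:
    """Gene family labels (NCR / senescence marker / bacterial marker / other)."""

    table: pd.DataFrame  # indexed by gene_id, columns: family, label

    def __post_init__(self) -> None:
        _check_unique(list(self.table.index), "gene_id")
        bad = sorted(set(self.table["family"]) - set(GENE_FAMILIES))
        if bad:
            raise ValidationError(f"unknown gene family value(s): {bad}")

    def genes_in_family(self, family: str) -> list[str]:
        return list(self.table.index[self.table["family"] == family])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False
    )


def read_compendium(matrix_path: Path | str, metadata_path: Path | str) -> Compendium:
    """Read and validate a signal matrix and its condition metadata."""
    raw = _read_tsv(matrix_path)
    if raw.columns[0] != "gene_id":
        raise ParseError(
            f"{matrix_path}: first header field must be 'gene_id', "
            f"found {raw.columns[0]!r}"
        )
    raw = raw.set_index("gene_id")
    numeric = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[converted.isna()]
        if len(bad):
            cell = raw.loc[bad[0], col]
            raise ParseError(
                f"{matrix_path}: non-numeric or missing cell {cell!r} at "
                f"gene {bad[0]!r}, condition {col!r}"
            )
        if (converted < 0).any():
            bad = raw.index[converted < 0][0]
            raise ParseError(
                f"{matrix_path}: negative signal {raw.loc[bad, col]!r} at "
                f"gene {bad!r}, condition {col!r}"
            )
        numeric[col] = converted.astype(float)

    meta = read_metadata(metadata_path)
    return Compendium(numeric, meta)


def read_metadata(path: Path | str) -> pd.DataFrame:
    meta = _read_tsv(path)
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise ValidationError(f"{path}: metadata is missing column {col!r}")
    _check_unique(list(meta["condition_id"]), "condition_id")
    meta = meta.set_index("condition_id")
    meta["timepoint"] = pd.to_numeric(meta["timepoint"], errors="coerce")
    for col in ("treatment", "timepoint_unit"):
        meta[col] = meta[col].fillna("")
    validate_metadata(meta)
    return meta


def read_annotations(path: Path | str) -> GeneAnnotation:
    table = _read_tsv(path)
    for col in ANNOTATION_COLUMNS:
        if col not in table.columns:
            raise ValidationError(f"{path}: annotation is missing column {col!r}")
    _check_unique(list(table["gene_id"]), "gene_id")
    return GeneAnnotation(table.set_index("gene_id"))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _format_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, (float, np.floating)):
        if math.isnan(value):
            return "NA"
        return format(float(value), ".12g")
    if isinstance(value, (bool, np.bool_)):
        return "True" if value else "False"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return str(value)


def write_table(rows: pd.DataFrame, path: Path | str, index: bool | None = None) -> None:
    """Write a result table as TSV with deterministic cell formatting.

    Real values are printed with 12 significant digits so a re-read
    reproduces them to that precision; NaN serializes as ``NA``.  When
    ``index`` is None the index is written iff it is named.
    """
    path = Path(path)
    if index is None:
        index = rows.index.name is not None
    out = rows.reset_index() if index else rows
    lines = ["\t".join(map(str, out.columns))]
    for row in out.itertuples(index=False):
        lines.append("\t".join(_format_cell(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_table(path: Path | str) -> pd.DataFrame:
    """Re-read a table written by :func:`write_table` (NA -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_compendium(
    compendium: Compendium, matrix_path: Path | str, metadata_path: Path | str
) -> None:
    matrix = compendium.signals.copy()
    matrix.index.name = "gene_id"
    write_table(matrix, matrix_path, index=True)
    meta = compendium.conditions.copy()
    meta.index.name = "condition_id"
    write_table(meta, metadata_path, index=True)


def write_annotations(annotation: GeneAnnotation, path: Path | str) -> None:
    table = annotation.table.copy()
    table.index.name = "gene_id"
    write_table(table, path, index=True)
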