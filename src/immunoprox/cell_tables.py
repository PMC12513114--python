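"""Per-cell segmentation tables: data model, I/O dialects, phenotype gating.

Multiplex-IHC workflows (Opal staining imaged on a Mantra/Vectra workstation,
segmented with inForm or similar) reduce each tissue field to a table with one
row per DAPI-segmented cell: an image identifier, the cell's x/y centroid in
micrometers, and either per-marker mean intensities or an already-assigned
phenotype label.  This module defines the in-memory model for those tables
(:class:`CellRecord`, :class:`ImageCellTable`), readers/writers for a canonical
CSV/TSV schema and an inForm-style tab-delimited dialect, and threshold gating
that turns marker intensities into phenotype labels
(:class:`PhenotypeRule`, :func:`apply_phenotype_rules`).

Coordinates are interpreted as micrometers in a per-image Cartesian frame.
Origin and axis orientation are irrelevant downstream: every statistic built
on these tables is a function of inter-cell distances only.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Tissue-region codes: tumor, subcapsular, peritumoral stroma, adjacent normal.
REGIONS = ("T", "SC", "PS", "A")

#: Fallback label for cells matching no gating rule.
OTHER_LABEL = "other"

MANDATORY_COLUMNS = ("cell_id", "image_id", "patient_id", "region", "x", "y")


class SchemaError(ValueError):
    """A mandatory column is missing or the file layout is unusable."""


class RowParseError(ValueError):
    """A row holds an unparseable value; carries the 0-based data row index."""

    def __init__(self, message: str, row_index: int):
        super().__init__(f"row {row_index}: {message}")
        self.row_index = row_index


class ValidationError(ValueError):
    """A parsed value violates the data model (e.g. unknown region code)."""


class ConfigurationError(ValueError):
    """A gating rule or column map references data that is not present."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CellRecord:
    """One segmented cell.

    At least one of ``markers`` (marker name -> mean intensity) and
    ``phenotype`` must be present; gating fills ``phenotype`` from ``markers``.
    """

    cell_id: str
    image_id: str
    patient_id: str
    region: str
    x: float
    y: float
    markers: dict[str, float] | None = None
    phenotype: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(
                f"cell {self.cell_id}: non-finite coordinates ({self.x}, {self.y})"
            )
        if self.region not in REGIONS:
            raise ValidationError(
                f"cell {self.cell_id}: unknown region code {self.region!r} "
                f"(expected one of {REGIONS})"
            )
        if self.markers is None and self.phenotype is None:
            raise ValidationError(
                f"cell {self.cell_id}: needs marker intensities or a phenotype label"
            )


@dataclass
class ImageCellTable:
    """All cells of one image field (one image id, patient, region)."""

    image_id: str
    patient_id: str
    region: str
    cells: list[CellRecord]
    field_width: float | None = None
    field_height: float | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.cells:
            if (c.image_id, c.patient_id, c.region) != (
                self.image_id,
                self.patient_id,
                self.region,
            ):
                raise ValidationError(
                    f"cell {c.cell_id} does not belong to image {self.image_id} "
                    f"(patient {self.patient_id}, region {self.region})"
                )
            if c.cell_id in seen:
                raise ValidationError(
                    f"duplicate cell_id {c.cell_id!r} in image {self.image_id}"
                )
            seen.add(c.cell_id)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def marker_names(self) -> list[str]:
        names: list[str] = []
        for c in self.cells:
            if c.markers:
                for m in c.markers:
                    if m not in names:
                        names.append(m)
        return names

    def coords(self, label: str | None = None) -> np.ndarray:
        """(n, 2) float array of x/y positions, optionally for one phenotype."""
        cells = self.cells if label is None else self.select(label)
        if not cells:
            return np.empty((0, 2), dtype=float)
        return np.array([[c.x, c.y] for c in cells], dtype=float)

    def select(self, label: str) -> list[CellRecord]:
        return [c for c in self.cells if c.phenotype == label]

    def to_frame(self) -> pd.DataFrame:
        markers = self.marker_names
        rows = []
        for c in self.cells:
            row: dict[str, object] = {
                "cell_id": c.cell_id,
                "image_id": c.image_id,
                "patient_id": c.patient_id,
                "region": c.region,
                "x": c.x,
                "y": c.y,
            }
            for m in markers:
                row[m] = (c.markers or {}).get(m, np.nan)
            if c.phenotype is not None:
                row["phenotype"] = c.phenotype
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhenotypeRule:
    """Threshold gate: positive markers must reach their cutoff, negative must not.

    A cell matches iff intensity >= threshold for every marker in
    ``required_positive`` and intensity < threshold for every marker in
    ``required_negative`` — a half-open split, so any cell with the referenced
    markers classifies one way or the other.
    """

    label: str
    required_positive: frozenset[str]
    required_negative: frozenset[str] = frozenset()
    thresholds: Mapping[str, float] = field(default_factory=dict)
    default_threshold: float = 1.0

    def __post_init__(self) -> None:
        overlap = set(self.required_positive) & set(self.required_negative)
        if overlap:
            raise ConfigurationError(
                f"rule {self.label!r}: markers {sorted(overlap)} are both "
                "required positive and required negative"
            )
        for m, t in self.thresholds.items():
            if t < 0:
                raise ConfigurationError(
                    f"rule {self.label!r}: negative threshold {t} for marker {m!r}"
                )

    @property
    def markers(self) -> frozenset[str]:
        return self.required_positive | self.required_negative

    def threshold(self, marker: str) -> float:
        return float(self.thresholds.get(marker, self.default_threshold))

    def matches(self, markers: Mapping[str, float]) -> bool:
        for m in self.required_positive:
            if markers[m] < self.threshold(m):
                return False
        for m in self.required_negative:
            if markers[m] >= self.threshold(m):
                return False
        return True


def default_rules(threshold: float = 1.0, pdl1_threshold: float | None = None
                  ) -> list[PhenotypeRule]:
    """The human gating panel: CD3+CD8+ T cells; CD68+CD163+ macrophages,
    split on PD-L1 into the anchor (PD-L1+) and remaining TAM populations.

    No universal intensity scale exists across staining batches, so the
    cutoffs are configuration; the synthetic generator calibrates its
    intensity model to the default of 1.0.
    """
    pt = threshold if pdl1_threshold is None else pdl1_threshold
    return [
        PhenotypeRule("CD8T", frozenset({"CD3", "CD8"}), default_threshold=threshold),
        PhenotypeRule(
            "PDL1_TAM",
            frozenset({"CD68", "CD163", "PDL1"}),
            thresholds={"PDL1": pt},
            default_threshold=threshold,
        ),
        PhenotypeRule("TAM", frozenset({"CD68", "CD163"}), default_threshold=threshold),
    ]


# ---------------------------------------------------------------------------
# I/O: canonical and inForm-style dialects
# ---------------------------------------------------------------------------

#: Default header mapping for inForm-style exports.  Keys are source headers,
#: values the canonical column names.  Override or extend via ``column_map``;
#: per-marker mean-intensity columns ("Entire Cell <marker> Mean ...") are
#: recognised by pattern when not explicitly mapped.
INFORM_COLUMN_MAP: dict[str, str] = {
    "Cell ID": "cell_id",
    "Sample Name": "image_id",
    "Patient ID": "patient_id",
    "Tissue Category": "region",
    "Cell X Position": "x",
    "Cell Y Position": "y",
    "Phenotype": "phenotype",
}

_INFORM_MARKER_RE = re.compile(r"^Entire Cell (.+?) Mean(?:\s*\(.*\))?$")


def _rename_inform_columns(columns: Iterable[str],
                           column_map: Mapping[str, str] | None) -> dict[str, str]:
    cmap = dict(INFORM_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    renames: dict[str, str] = {}
    for col in columns:
        if col in cmap:
            renames[col] = cmap[col]
        else:
            m = _INFORM_MARKER_RE.match(col)
            if m:
                renames[col] = m.group(1)
    return renames


def _frame_to_tables(df: pd.DataFrame) -> list[ImageCellTable]:
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    extra = [c for c in df.columns if c not in MANDATORY_COLUMNS and c != "phenotype"]
    for axis in ("x", "y"):
        coerced = pd.to_numeric(df[axis], errors="coerce")
        bad = coerced.isna() & df[axis].notna() | df[axis].isna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise RowParseError(
                f"non-numeric {axis} coordinate {df[axis].iloc[idx]!r}", idx
            )
        df[axis] = coerced
    has_pheno = "phenotype" in df.columns

    tables: list[ImageCellTable] = []
    # groupby(sort=False) keeps first-appearance image order; row order within
    # each image is the file order.
    for image_id, sub in df.groupby("image_id", sort=False):
        cells = []
        for _, row in sub.iterrows():
            markers = {
                m: float(row[m]) for m in extra if pd.notna(row[m])
            } or None
            phenotype = None
            if has_pheno and pd.notna(row["phenotype"]) and str(row["phenotype"]):
                phenotype = str(row["phenotype"])
            cells.append(
                CellRecord(
                    cell_id=str(row["cell_id"]),
                    image_id=str(image_id),
                    patient_id=str(row["patient_id"]),
                    region=str(row["region"]),
                    x=float(row["x"]),
                    y=float(row["y"]),
                    markers=markers,
                    phenotype=phenotype,
                )
            )
        tables.append(
            ImageCellTable(
                image_id=str(image_id),
                patient_id=cells[0].patient_id,
                region=cells[0].region,
                cells=cells,
            )
        )
    return tables


def read_cell_table(path, dialect: str = "canonical",
                    column_map: Mapping[str, str] | None = None
                    ) -> list[ImageCellTable]:
    """Read a per-cell table, one :class:`ImageCellTable` per distinct image id.

    Parameters
    ----------
    path
        CSV/TSV file.  The canonical dialect is comma- or tab-delimited with
        header ``cell_id,image_id,patient_id,region,x,y,<marker...>[,phenotype]``;
        the ``inform`` dialect is tab-delimited with inForm-style headers
        remapped through ``column_map`` (defaults in :data:`INFORM_COLUMN_MAP`).
    dialect
        ``"canonical"`` or ``"inform"``.
    column_map
        Extra/overriding source-header -> canonical-name entries (inform only).
    """
    if dialect == "canonical":
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    elif dialect == "inform":
        df = pd.read_csv(path, sep="\t", dtype=str)
        df = df.rename(columns=_rename_inform_columns(df.columns, column_map))
        df = df[[c for c in df.columns
                 if c in MANDATORY_COLUMNS or c == "phenotype"
                 or not re.search(r"\s", c)]]
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    if df.empty:
        raise SchemaError("empty cell table")
    for col in df.columns:
        if col not in MANDATORY_COLUMNS and col != "phenotype":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return _frame_to_tables(df)


def write_cell_table(tables: Sequence[ImageCellTable], path) -> None:
    """Serialize tables to the canonical CSV dialect (lossless round-trip)."""
    frames = [t.to_frame() for t in tables]
    df = pd.concat(frames, ignore_index=True)
    # mandatory columns first, then markers, then phenotype if present
    markers = [c for c in df.columns
               if c not in MANDATORY_COLUMNS and c != "phenotype"]
    order = list(MANDATORY_COLUMNS) + markers
    if "phenotype" in df.columns:
        order.append("phenotype")
    df[order].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Phenotype gating
# ---------------------------------------------------------------------------

def apply_phenotype_rules(table: ImageCellTable,
                          rules: Sequence[PhenotypeRule]) -> ImageCellTable:
    """Assign each cell the first matching rule's label, else ``"other"``.

    First-match-wins: the gating panels used here are disjoint, but user
    configurations need not be, and a deterministic order makes overlapping
    rules well-defined.  Cells already carrying a phenotype label but no
    markers pass through unchanged.  Idempotent and order-independent
    across cells.
    """
    needed = frozenset().union(*(r.markers for r in rules)) if rules else frozenset()
    labeled: list[CellRecord] = []
    for c in table.cells:
        if c.markers is None:
            labeled.append(c)  # pre-labeled input: no-op pass-through
            continue
        missing = needed - c.markers.keys()
        if missing:
            raise ConfigurationError(
                f"cell {c.cell_id}: rule markers {sorted(missing)} absent from data"
            )
        label = OTHER_LABEL
        for rule in rules:
            if rule.matches(c.markers):
                label = rule.label
                break
        labeled.append(replace(c, phenotype=label))
    return ImageCellTable(
        image_id=table.image_id,
        patient_id=table.patient_id,
        region=table.region,
        cells=labeled,
        field_width=table.field_width,
        field_height=table.field_height,
    )


def select_phenotype(table: ImageCellTable, label: str) -> list[CellRecord]:
    """All cells carrying ``label``, in original order (empty is valid)."""
    return table.select(label)
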