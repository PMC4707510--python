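"""Per-well spheroid records, shape classification, and homogeneous
sub-population selection.

The plate workflow: each well of a 96-well low-attachment plate holds one
spheroid; a brightfield image per well is segmented and measured, each
record is assigned a shape class (spherical / ellipsoidal / figure8 /
irregular), and a sub-population homogeneous in volume and sphericity is
selected — SI ≥ 0.90 (the quantitative spherical criterion) and volume
within a relative band around the population median. The default ±15% band
mirrors the ~12% relative SD of a typical selected group (0.112 ± 0.013
mm³).

Only the SI cutoff is a quantitative criterion from the source workflow;
the ellipsoidal / figure-8 / irregular boundaries (lobe-area ratio 30%,
solidity 0.95, aspect ratio 1.3) are this package's operationalization of
qualitative categories and are exposed in the classifier signature.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .images import GrayImage, SpheromorphError
from .morphometry import Morphometry2D, measure_2d
from .revolution import Decomposition, estimate_volume
from .segmentation import SegmentationError, SegmentationOptions, mask_qc, segment_spheroid

__all__ = [
    "SpheroidRecord",
    "SelectionCriteria",
    "SelectionSummary",
    "PlatePopulation",
    "measure_well",
    "classify_shape",
    "select_homogeneous",
    "save_records",
    "load_records",
    "plate_map",
]

SHAPE_CLASSES = ("spherical", "ellipsoidal", "figure8", "irregular")

_WELL_RE = re.compile(r"^([A-Ha-h])(1[0-2]|[1-9])$")

CSV_COLUMNS = [
    "well",
    "deq_um",
    "area_um2",
    "perimeter_um",
    "SI",
    "feret_um",
    "aspect",
    "solidity",
    "volume_mm3",
    "class",
    "selected",
    "qc",
]


def canonical_well(well: str) -> str:
    """Normalize a plate coordinate (rows A–H, columns 1–12) to uppercase."""
    m = _WELL_RE.match(well.strip())
    if not m:
        raise SpheromorphError(f"bad plate table: invalid well {well!r}")
    return f"{m.group(1).upper()}{int(m.group(2))}"


@dataclass
class SpheroidRecord:
    """One measured well: morphometry, volume, class, selection state."""

    well: str
    morphometry: Morphometry2D | None = None
    volume_mm3: float | None = None
    shape_class: str | None = None
    selected: bool = False
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.well = canonical_well(self.well)

    @property
    def qc_pass(self) -> bool:
        return len(self.qc_flags) == 0 and self.morphometry is not None

    @property
    def si(self) -> float | None:
        return None if self.morphometry is None else self.morphometry.si


@dataclass(frozen=True)
class SelectionCriteria:
    """Homogeneity criteria: SI floor and relative volume band.

    ``volume_center_mm3 = None`` uses the median volume of the QC-passing
    records; ``volume_tolerance`` is relative (0.15 → ±15%).
    """

    si_min: float = 0.90
    volume_center_mm3: float | None = None
    volume_tolerance: float = 0.15
    require_qc_pass: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.si_min <= 1.0):
            raise SpheromorphError("si_min must be in (0, 1]")
        if self.volume_tolerance <= 0:
            raise SpheromorphError("volume_tolerance must be positive")


@dataclass
class SelectionSummary:
    """Counts and spread statistics of the selected sub-population."""

    n_total: int
    n_qc_pass: int
    n_selected: int
    volume_center_mm3: float | None
    volume_mean_mm3: float | None
    volume_sd_mm3: float | None
    volume_cv_percent: float | None
    si_range: tuple[float, float] | None
    warnings: list[str] = field(default_factory=list)


def measure_well(
    image: GrayImage,
    well: str,
    seg_options: SegmentationOptions | None = None,
    min_diameter_um: float = 100.0,
    opening_fraction: float = 0.3,
) -> tuple[SpheroidRecord, Decomposition | None]:
    """Run the full pipeline on one well image.

    Segmentation failures become QC-failed records (flag set to the error
    message) rather than exceptions, so whole-plate runs always complete.
    Returns the record and the mask decomposition (None on failure).
    """
    well = canonical_well(well)
    try:
        mask = segment_spheroid(image, seg_options)
    except (SegmentationError, SpheromorphError) as exc:
        return SpheroidRecord(well=well, qc_flags=(str(exc),)), None
    qc = mask_qc(mask, min_diameter_um=min_diameter_um)
    morpho = measure_2d(mask)
    est = estimate_volume(mask, opening_fraction=opening_fraction)
    record = SpheroidRecord(
        well=well,
        morphometry=morpho,
        volume_mm3=est.volume_mm3,
        qc_flags=tuple(sorted(qc.flags)),
    )
    record.shape_class = classify_shape(record, est.decomposition)
    return record, est.decomposition


def classify_shape(
    record: SpheroidRecord,
    decomposition: Decomposition | None,
    si_min: float = 0.90,
    lobe_ratio: float = 0.30,
    solidity_min: float = 0.95,
    aspect_min: float = 1.3,
) -> str:
    """Assign one of the four shape classes.

    Rules, in order: spherical iff SI ≥ ``si_min``; else figure8 iff the
    second-largest decomposition part is ≥ ``lobe_ratio`` of the largest;
    else ellipsoidal iff a single main body with solidity ≥ ``solidity_min``
    and aspect ratio ≥ ``aspect_min``; else irregular. Total by
    construction: every record maps to exactly one class.
    """
    m = record.morphometry
    if m is None:
        return "irregular"
    if m.si >= si_min:
        return "spherical"
    if decomposition is not None and decomposition.n_parts >= 2:
        areas = sorted(decomposition.part_areas_px(), reverse=True)
        if areas[1] >= lobe_ratio * areas[0]:
            return "figure8"
    single_body = decomposition is None or decomposition.n_parts == 1
    if single_body and m.solidity >= solidity_min and m.aspect_ratio >= aspect_min:
        return "ellipsoidal"
    return "irregular"


def select_homogeneous(
    records: list[SpheroidRecord], criteria: SelectionCriteria | None = None
) -> tuple[list[SpheroidRecord], SelectionSummary]:
    """Mark the records forming a volume- and sphericity-homogeneous subset.

    A record is selected iff it passes QC (unless waived), its SI is at
    least ``criteria.si_min``, and its volume lies within the relative band
    around the center (default: median of the QC-passing volumes). Records
    are updated in place and returned with a summary; an empty selection is
    a warning, not an error.
    """
    criteria = criteria or SelectionCriteria()
    eligible = [
        r
        for r in records
        if r.volume_mm3 is not None and (r.qc_pass or not criteria.require_qc_pass)
    ]
    warnings: list[str] = []
    center = criteria.volume_center_mm3
    if center is None:
        if eligible:
            center = float(np.median([r.volume_mm3 for r in eligible]))
        else:
            warnings.append("no eligible records; empty selection")
    lo = hi = None
    if center is not None:
        lo = center * (1.0 - criteria.volume_tolerance)
        hi = center * (1.0 + criteria.volume_tolerance)

    for r in records:
        ok = (
            r.volume_mm3 is not None
            and (r.qc_pass or not criteria.require_qc_pass)
            and r.si is not None
            and r.si >= criteria.si_min
            and lo is not None
            and lo <= r.volume_mm3 <= hi
        )
        r.selected = bool(ok)

    chosen = [r for r in records if r.selected]
    if not chosen:
        warnings.append("empty selection")
        return records, SelectionSummary(
            n_total=len(records),
            n_qc_pass=sum(r.qc_pass for r in records),
            n_selected=0,
            volume_center_mm3=center,
            volume_mean_mm3=None,
            volume_sd_mm3=None,
            volume_cv_percent=None,
            si_range=None,
            warnings=warnings,
        )
    vols = np.array([r.volume_mm3 for r in chosen], dtype=float)
    sis = np.array([r.si for r in chosen], dtype=float)
    mean = float(vols.mean())
    sd = float(vols.std(ddof=1)) if len(vols) > 1 else 0.0
    summary = SelectionSummary(
        n_total=len(records),
        n_qc_pass=sum(r.qc_pass for r in records),
        n_selected=len(chosen),
        volume_center_mm3=center,
        volume_mean_mm3=mean,
        volume_sd_mm3=sd,
        volume_cv_percent=100.0 * sd / mean if mean else None,
        si_range=(float(sis.min()), float(sis.max())),
        warnings=warnings,
    )
    return records, summary


# ---------------------------------------------------------------------------
# plate table I/O
# ---------------------------------------------------------------------------

def records_to_frame(records: list[SpheroidRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        m = r.morphometry
        rows.append(
            {
                "well": r.well,
                "deq_um": m.deq_um if m else np.nan,
                "area_um2": m.area_um2 if m else np.nan,
                "perimeter_um": m.perimeter_um if m else np.nan,
                "SI": m.si if m else np.nan,
                "feret_um": m.feret_um if m else np.nan,
                "aspect": m.aspect_ratio if m else np.nan,
                "solidity": m.solidity if m else np.nan,
                "volume_mm3": r.volume_mm3 if r.volume_mm3 is not None else np.nan,
                "class": r.shape_class or "",
                "selected": bool(r.selected),
                "qc": "pass" if r.qc_pass else ";".join(r.qc_flags) or "fail",
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def save_records(records: list[SpheroidRecord], path: str | Path) -> None:
    """Write the plate table CSV (numerics at 6 significant digits)."""
    df = records_to_frame(records)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")


def _frame_to_records(df: pd.DataFrame) -> list[SpheroidRecord]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SpheromorphError(f"bad plate table: missing column(s) {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        morpho = None
        if np.isfinite(row["area_um2"]):
            area = float(row["area_um2"])
            morpho = Morphometry2D(
                area_um2=area,
                perimeter_um=float(row["perimeter_um"]),
                deq_um=float(row["deq_um"]),
                si=float(row["SI"]),
                feret_um=float(row["feret_um"]),
                feret_endpoints=((0, 0), (0, 0)),
                feret_angle=0.0,
                min_caliper_um=(
                    float(row["feret_um"]) / float(row["aspect"])
                    if float(row["aspect"]) > 0
                    else 0.0
                ),
                aspect_ratio=float(row["aspect"]),
                solidity=float(row["solidity"]),
                centroid=(math.nan, math.nan),
            )
        qc = str(row["qc"])
        rec = SpheroidRecord(
            well=str(row["well"]),
            morphometry=morpho,
            volume_mm3=float(row["volume_mm3"]) if np.isfinite(row["volume_mm3"]) else None,
            shape_class=str(row["class"]) or None,
            selected=bool(row["selected"]),
            qc_flags=() if qc == "pass" else tuple(f for f in qc.split(";") if f),
        )
        records.append(rec)
    return records


def load_records(path: str | Path) -> "PlatePopulation":
    """Load a plate table CSV written by :func:`save_records`."""
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        return PlatePopulation([])
    if df.empty and list(df.columns) == []:
        return PlatePopulation([])
    return PlatePopulation(_frame_to_records(df))


def plate_map(records: list[SpheroidRecord]) -> pd.DataFrame:
    """8×12 grid of {selected, rejected, empty} keyed by row letter."""
    grid = pd.DataFrame(
        "empty", index=list("ABCDEFGH"), columns=[str(c) for c in range(1, 13)]
    )
    for r in records:
        row, col = r.well[0], r.well[1:]
        grid.loc[row, col] = "selected" if r.selected else "rejected"
    return grid


def plot_plate_map(records: list[SpheroidRecord], path: str | Path) -> None:
    """Render the plate map (selected wells in green) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = plate_map(records)
    colors = {"selected": "#2ca02c", "rejected": "#d62728", "empty": "#d9d9d9"}
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, row in enumerate(grid.index):
        for j, col in enumerate(grid.columns):
            ax.add_patch(
                plt.Circle((j, 7 - i), 0.4, color=colors[grid.loc[row, col]], ec="k", lw=0.5)
            )
    ax.set_xlim(-0.6, 11.6)
    ax.set_ylim(-0.6, 7.6)
    ax.set_xticks(range(12), [str(c) for c in range(1, 13)])
    ax.set_yticks(range(8), list("HGFEDCBA"))
    ax.set_aspect("equal")
    ax.set_title("Plate map (green = selected)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class PlatePopulation:
    """A plate's worth of spheroid records with selection helpers."""

    records: list[SpheroidRecord]

    def __len__(self) -> int:
        return len(self.records)

    def select(
        self, criteria: SelectionCriteria | None = None
    ) -> SelectionSummary:
        _, summary = select_homogeneous(self.records, criteria)
        return summary

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def save(self, path: str | Path) -> None:
        save_records(self.records, path)

    def plate_map(self) -> pd.DataFrame:
        return plate_map(self.records)
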