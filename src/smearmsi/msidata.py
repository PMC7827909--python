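"""Domain model and I/O for blood-smear MSI datasets, ROIs, and metabolite tables.

Coordinate conventions
----------------------
Pixels are indexed 0-based as ``(i, j)`` with ``i`` along x (column) and
``j`` along y (row).  The physical frame is anchored at the grid corner;
the center of pixel ``(i, j)`` sits at ``((i+0.5)*pitch_x, (j+0.5)*pitch_y)``
in micrometers.  An ROI ellipse contains a pixel iff the pixel *center*
satisfies the rotated-ellipse inequality (center containment, not area
overlap — unambiguous at ~8 µm pitch).

Spectra are stored per pixel in row-major order (``j`` outer, ``i`` inner);
:meth:`MSIDataset.pixel_index` maps ``(i, j)`` to the flat index used by
downstream feature matrices.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import chemmass

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "MSIDataset",
    "ROI",
    "ROISet",
    "MetaboliteRecord",
    "FormatError",
    "read_imzml",
    "write_imzml",
    "pixels_in_roi",
    "read_roi_json",
    "write_roi_json",
    "read_metabolite_table",
    "bundled_metabolite_table",
    "reported_differential_table",
]

CELL_LABELS = ("RBC", "WBC", "plasma")


class FormatError(ValueError):
    """Malformed input file (imzML/ROI JSON/metabolite table)."""


@dataclass
class Spectrum:
    """A single-pixel mass spectrum: ascending m/z with nonnegative intensities."""

    mz: np.ndarray
    intensity: np.ndarray

    # continuous-mode datasets share one m/z axis across thousands of pixels;
    # remember the last validated axis object so it is checked once, not per pixel
    _validated_axis = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz is not Spectrum._validated_axis:
            if np.any(np.isnan(self.mz)):
                raise ValueError("NaN values in spectrum")
            if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
                raise ValueError("m/z axis must be strictly ascending")
            Spectrum._validated_axis = self.mz
        if np.any(np.isnan(self.intensity)):
            raise ValueError("NaN values in spectrum")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")

    @property
    def tic(self) -> float:
        """Total ion count (sum of intensities)."""
        return float(self.intensity.sum())


@dataclass
class MSIDataset:
    """A rectangular MSI raster with one spectrum per pixel.

    ``pitch_x``/``pitch_y`` are the raster pitches in µm; ``polarity`` is
    +1/-1; ``setting_label`` names the instrument preset (D0: 8x7 µm,
    D1: 8x6 µm); ``mz_range`` is the acquisition window in Da.
    ``uniform_axis``, when set, is the shared m/z axis of a
    continuous-mode acquisition (enables vectorized preprocessing).
    """

    n_x: int
    n_y: int
    pitch_x: float
    pitch_y: float
    polarity: int
    matrix_label: str
    setting_label: str
    mz_range: tuple[float, float]
    spectra: list[Spectrum]
    uniform_axis: np.ndarray | None = None
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.pitch_x <= 0 or self.pitch_y <= 0:
            raise ValueError("pitch values must be positive")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")
        if len(self.spectra) != self.n_x * self.n_y:
            raise ValueError(
                f"expected {self.n_x * self.n_y} spectra, got {len(self.spectra)}"
            )
        lo, hi = self.mz_range
        for k, sp in enumerate(self.spectra):
            if sp.mz.size and (sp.mz[0] < lo - 1e-9 or sp.mz[-1] > hi + 1e-9):
                raise ValueError(f"spectrum {k} outside mz_range {self.mz_range}")

    @property
    def n_pixels(self) -> int:
        return self.n_x * self.n_y

    def pixel_index(self, i: int, j: int) -> int:
        """Flat index of pixel (i, j) (row-major, j outer)."""
        if not (0 <= i < self.n_x and 0 <= j < self.n_y):
            raise IndexError(f"pixel ({i}, {j}) outside {self.n_x}x{self.n_y} grid")
        return j * self.n_x + i

    def spectrum(self, i: int, j: int) -> Spectrum:
        return self.spectra[self.pixel_index(i, j)]

    def pixel_centers(self) -> np.ndarray:
        """(n_pixels, 2) array of pixel-center (x, y) µm coordinates, flat order."""
        jj, ii = np.meshgrid(np.arange(self.n_y), np.arange(self.n_x), indexing="ij")
        x = (ii.ravel() + 0.5) * self.pitch_x
        y = (jj.ravel() + 0.5) * self.pitch_y
        return np.column_stack([x, y])

    def pixels(self) -> Iterator[tuple[int, int]]:
        for j in range(self.n_y):
            for i in range(self.n_x):
                yield i, j


@dataclass
class ROI:
    """A labeled ellipse in µm coordinates (rotation in degrees, CCW)."""

    label: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation_deg: float = 0.0
    donor_id: str = ""
    smear_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in CELL_LABELS:
            raise ValueError(f"ROI label must be one of {CELL_LABELS}, got {self.label!r}")
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValueError("ROI semi-axes must be positive")


@dataclass
class ROISet:
    rois: list[ROI] = field(default_factory=list)

    def __iter__(self) -> Iterator[ROI]:
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def by_label(self, label: str) -> list[ROI]:
        return [r for r in self.rois if r.label == label]


@dataclass
class MetaboliteRecord:
    """One row of a (frozen) metabolite database used for annotation."""

    hmdb_id: str
    kegg_id: str | None
    name: str
    formula: str | None
    monoisotopic_mass: float
    endogenous_or_essential: bool
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.monoisotopic_mass or self.monoisotopic_mass <= 0:
            raise ValueError(f"metabolite {self.name!r}: monoisotopic mass must be positive")
        if self.formula:
            computed = chemmass.monoisotopic_mass(self.formula)
            if abs(computed - self.monoisotopic_mass) > 1e-3:
                raise ValueError(
                    f"metabolite {self.name!r}: mass {self.monoisotopic_mass} disagrees "
                    f"with formula {self.formula} ({computed:.5f})"
                )


# ---------------------------------------------------------------------------
# imzML I/O


def write_imzml(dataset: MSIDataset, path: str | Path) -> None:
    """Write a dataset as imzML (+ .ibd) with a JSON sidecar for raster metadata.

    float64 is used for both axes so the round trip is lossless.  The
    sidecar ``<path>.meta.json`` carries pitch, polarity, matrix/setting
    labels, and the m/z range, which imzML itself does not standardize.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    mode = "continuous" if dataset.uniform_axis is not None else "processed"
    with ImzMLWriter(
        str(path),
        mz_dtype=np.float64,
        intensity_dtype=np.float64,
        mode=mode,
        polarity="positive" if dataset.polarity > 0 else "negative",
    ) as writer:
        for i, j in dataset.pixels():
            sp = dataset.spectrum(i, j)
            writer.addSpectrum(sp.mz, sp.intensity, (i + 1, j + 1))  # imzML is 1-based
    meta = {
        "n_x": dataset.n_x,
        "n_y": dataset.n_y,
        "pitch_x_um": dataset.pitch_x,
        "pitch_y_um": dataset.pitch_y,
        "polarity": dataset.polarity,
        "matrix_label": dataset.matrix_label,
        "setting_label": dataset.setting_label,
        "mz_range": list(dataset.mz_range),
        "uniform_axis": dataset.uniform_axis is not None,
        "dataset_id": dataset.dataset_id,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_imzml(path: str | Path, sidecar: str | Path | None = None) -> MSIDataset:
    """Read an imzML file (continuous or processed mode) into an :class:`MSIDataset`.

    Raster metadata (pitch, polarity, labels) is taken from the JSON
    sidecar written by :func:`write_imzml`, or from ``sidecar`` when
    given; defaults are used when neither exists.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # malformed XML / missing ibd
        raise FormatError(f"cannot parse imzML file {path}: {exc}") from exc

    sidecar = Path(sidecar) if sidecar else Path(str(path) + ".meta.json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    coords = [(x, y) for x, y, *_ in parser.coordinates]
    n_x = meta.get("n_x", max(x for x, _ in coords))
    n_y = meta.get("n_y", max(y for _, y in coords))

    spectra: list[Spectrum | None] = [None] * (n_x * n_y)
    axes = []
    for k, (x, y) in enumerate(coords):
        try:
            mz, inten = parser.getspectrum(k)
        except Exception as exc:
            raise FormatError(f"binary read failed at pixel index {k} ({x},{y}): {exc}") from exc
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        if mz.shape != inten.shape or np.any(np.isnan(mz)) or np.any(np.isnan(inten)) or (
            mz.size > 1 and np.any(np.diff(mz) <= 0)
        ):
            raise FormatError(f"corrupt spectrum at pixel index {k} ({x},{y})")
        spectra[(y - 1) * n_x + (x - 1)] = Spectrum(mz, np.maximum(inten, 0.0))
        axes.append(mz)
    if any(sp is None for sp in spectra):
        raise FormatError("imzML pixel coordinates do not fill the raster")

    uniform = None
    if axes and all(a.shape == axes[0].shape and np.array_equal(a, axes[0]) for a in axes[1:]):
        uniform = axes[0]
    else:
        logger.info("%s: per-pixel m/z axes (processed mode); flagged non-uniform", path.name)

    lo = meta.get("mz_range", [min(a[0] for a in axes if a.size), None])[0]
    hi = meta.get("mz_range", [None, max(a[-1] for a in axes if a.size)])[1]
    return MSIDataset(
        n_x=n_x,
        n_y=n_y,
        pitch_x=meta.get("pitch_x_um", 8.0),
        pitch_y=meta.get("pitch_y_um", 7.0),
        polarity=meta.get("polarity", -1),
        matrix_label=meta.get("matrix_label", "9AA"),
        setting_label=meta.get("setting_label", "D0"),
        mz_range=(lo, hi),
        spectra=spectra,  # type: ignore[arg-type]
        uniform_axis=uniform,
        dataset_id=meta.get("dataset_id", path.stem),
    )


# ---------------------------------------------------------------------------
# ROI geometry and I/O


def pixels_in_roi(dataset: MSIDataset, roi: ROI) -> list[tuple[int, int]]:
    """Pixels whose centers fall inside the (rotated) ROI ellipse.

    Membership is by center containment: pixel (i, j) belongs iff its
    center satisfies the rotated-ellipse inequality <= 1.  An ROI that
    covers no pixel center yields an empty list (with a warning), not an
    error.
    """
    cx, cy = roi.center
    a, b = roi.semi_axes
    theta = math.radians(roi.rotation_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)

    centers = dataset.pixel_centers()
    dx = centers[:, 0] - cx
    dy = centers[:, 1] - cy
    u = dx * cos_t + dy * sin_t
    v = -dx * sin_t + dy * cos_t
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0 + 1e-12
    idx = np.nonzero(inside)[0]
    if idx.size == 0:
        logger.warning("ROI %s at (%.1f, %.1f) µm covers no pixel center", roi.label, cx, cy)
    return [(int(k % dataset.n_x), int(k // dataset.n_x)) for k in idx]


def write_roi_json(roi_set: ROISet, path: str | Path) -> None:
    payload = {
        "rois": [
            {
                "label": r.label,
                "center_um": list(r.center),
                "semi_axes_um": list(r.semi_axes),
                "rotation_deg": r.rotation_deg,
                "donor_id": r.donor_id,
                "smear_id": r.smear_id,
            }
            for r in roi_set
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_roi_json(path: str | Path) -> ROISet:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid ROI JSON {path}: {exc}") from exc
    if "rois" not in payload:
        raise FormatError(f"ROI JSON {path} missing required key 'rois'")
    rois = []
    for k, r in enumerate(payload["rois"]):
        for key in ("label", "center_um", "semi_axes_um"):
            if key not in r:
                raise FormatError(f"ROI #{k} missing required key {key!r}")
        rois.append(
            ROI(
                label=r["label"],
                center=tuple(r["center_um"]),
                semi_axes=tuple(r["semi_axes_um"]),
                rotation_deg=r.get("rotation_deg", 0.0),
                donor_id=r.get("donor_id", ""),
                smear_id=r.get("smear_id", ""),
            )
        )
    return ROISet(rois)


# ---------------------------------------------------------------------------
# Metabolite tables

_REQUIRED_MET_COLS = ("hmdb_id", "name", "monoisotopic_mass")


def read_metabolite_table(path: str | Path) -> list[MetaboliteRecord]:
    """Read a CSV/TSV metabolite table into validated records.

    Required columns: hmdb_id, name, monoisotopic_mass.  Optional:
    kegg_id, formula, endogenous_or_essential (default false).  Unknown
    columns are preserved in ``record.extra``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for col in _REQUIRED_MET_COLS:
        if col not in df.columns:
            raise FormatError(f"metabolite table {path} missing required column {col!r}")
    known = set(_REQUIRED_MET_COLS) | {"kegg_id", "formula", "endogenous_or_essential"}
    records = []
    for _, row in df.iterrows():
        kegg = row.get("kegg_id")
        formula = row.get("formula")
        endo = row.get("endogenous_or_essential", False)
        if isinstance(endo, str):
            endo = endo.strip().lower() in ("true", "1", "yes", "t")
        records.append(
            MetaboliteRecord(
                hmdb_id=str(row["hmdb_id"]),
                kegg_id=None if pd.isna(kegg) else str(kegg),
                name=str(row["name"]),
                formula=None if (formula is None or pd.isna(formula)) else str(formula),
                monoisotopic_mass=float(row["monoisotopic_mass"]),
                endogenous_or_essential=bool(endo),
                extra={c: row[c] for c in df.columns if c not in known},
            )
        )
    return records


def bundled_metabolite_table() -> list[MetaboliteRecord]:
    """The bundled blood-smear metabolite table.

    It freezes the study's database search into a reproducible lookup:
    one record per metabolite reported as differentially expressed plus
    the cellular quality-indicator markers (ATP, IMP; heme is already
    present).  Formulas are literature values; masses are computed from
    them.  The published report prints no HMDB accessions, so ``hmdb_id``
    carries KEGG-derived placeholder identifiers.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("smearmsi.data").joinpath("metabolites_bloodsmear.tsv")
    ) as p:
        return read_metabolite_table(p)


def reported_differential_table() -> pd.DataFrame:
    """The published differential m/z report (observed m/z, adduct, KEGG id,
    instrument setting, cell type) as a DataFrame — used as input for
    annotation round-trip checks."""
    from importlib import resources

    with resources.as_file(
        resources.files("smearmsi.data").joinpath("differential_reported.tsv")
    ) as p:
        return pd.read_csv(p, sep="\t")
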