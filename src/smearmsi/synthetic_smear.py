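"""Synthetic blood-smear MSI generator with ground truth.

No public raw data accompanies the study this package operationalizes, so
every downstream stage is exercised on simulated rasters that reproduce
the *statistical* structure the analysis assumes:

* a rectangular pixel grid at the D0 (8x7 µm) or D1 (8x6 µm) raster pitch;
* RBC (~7 µm) and WBC (~12 µm) disks placed without overlap on a plasma
  background, cell centers snapped to pixel centers (at ~8 µm pitch a
  blood cell is a one-pixel object; snapping guarantees each cell ROI
  contains its pixel);
* per-pixel profile spectra: a sum of Gaussian peaks (sigma 0.01 Da,
  sampled at 7 points across ±3 sigma) whose amplitudes depend on the
  pixel class — quality-indicator markers (heme, ATP, IMP at their
  published ion m/z) enriched in cells, an easily ionized plasma-lipid
  background enriched in plasma remnants (and present at a low level
  under cells too), plus several hundred class-neutral filler peaks so
  the top-K feature cap binds;
* multiplicative log-normal per-pixel TIC variation, additive half-normal
  baseline noise, and log-normal per-(donor, peak) random effects so a
  cross-donor differential test has realistic between-sample variance.

``null_mode`` is the type-I calibration switch: it forces every
class-enrichment factor to 1 *and* the donor-effect sigma to 0, making
all ROIs exchangeable draws from one distribution (the regime in which a
two-sample t-test's nominal level is a mathematical property).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .msidata import MSIDataset, ROI, ROISet, Spectrum

__all__ = [
    "MarkerPeak",
    "SmearSimConfig",
    "SmearTruth",
    "DonorSmear",
    "SimulationError",
    "generate_smear",
    "generate_study",
    "default_markers",
    "default_plasma_peaks",
    "D0_PITCH",
    "D1_PITCH",
]

D0_PITCH = (8.0, 7.0)  # µm, x and y
D1_PITCH = (8.0, 6.0)

# published quality-indicator ion m/z (singly charged adducts)
ATP_MH_NEG = 505.988
HEME_FE2_MH_NEG = 615.170
IMP_MNA_POS = 371.037
HEME_FE3_M_POS = 616.177


class SimulationError(RuntimeError):
    """Raised when cells cannot be placed or the config is unsatisfiable."""


@dataclass(frozen=True)
class MarkerPeak:
    """A peak with class-dependent amplitude.

    ``enrichment`` maps a pixel class (RBC/WBC/plasma) to the
    multiplicative amplitude factor applied there; unlisted classes get 1.
    """

    mz: float
    amplitude: float
    enrichment: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.enrichment.values()):
            raise ValueError("enrichment factors must be >= 0")


def default_markers(polarity: int, enrichment: float = 5.0) -> list[MarkerPeak]:
    """The cellular quality-indicator panel for one ionization mode.

    Heme marks RBC; ATP is shared by RBC and WBC; IMP marks RBC.
    """
    if polarity < 0:
        return [
            MarkerPeak(ATP_MH_NEG, 3.0, {"RBC": enrichment, "WBC": enrichment}),
            MarkerPeak(HEME_FE2_MH_NEG, 3.0, {"RBC": enrichment}),
        ]
    return [
        MarkerPeak(IMP_MNA_POS, 3.0, {"RBC": enrichment}),
        MarkerPeak(HEME_FE3_M_POS, 3.0, {"RBC": enrichment}),
    ]


def default_plasma_peaks(polarity: int, enrichment: float = 3.0) -> list[MarkerPeak]:
    """Plasma-remnant background: easily ionized free fatty acids and
    phospholipids (negative mode) or lysophospholipid/phosphatidylcholine
    species (positive mode), enriched in plasma but present at a low
    level under cells as well."""
    if polarity < 0:
        mzs = [255.2330, 279.2330, 281.2486, 283.2643,  # FFA [M-H]-
               721.5024, 747.5180, 788.5447, 885.5499]  # phospholipid [M-H]-
    else:
        mzs = [496.3398, 524.3711,                      # LPC [M+H]+
               703.5749, 734.5694, 760.5851, 782.5670]  # SM/PC [M+H]+
    return [MarkerPeak(mz, 2.0, {"plasma": enrichment}) for mz in mzs]


@dataclass
class SmearSimConfig:
    """Study-design parameters for one simulated smear.

    Defaults emulate the published acquisition: D1 pitch, negative-mode
    9AA matrix, 200-600 Da window, 5 RBC + 1 WBC + 3 plasma ROIs per
    smear.  Peak width and noise levels are not published; the defaults
    (sigma 0.01 Da so a 0.020 Da bin captures one peak; TIC sigma 0.25;
    baseline sigma 0.02; donor sigma 0.15) are documented choices.
    """

    n_x: int = 48
    n_y: int = 48
    pitch: tuple[float, float] = D1_PITCH
    polarity: int = -1
    matrix_label: str = "9AA"
    setting_label: str = "D1"
    mz_range: tuple[float, float] = (200.0, 600.0)
    n_rbc: int = 40
    n_wbc: int = 4
    rbc_diameter_um: float = 7.0
    wbc_diameter_um: float = 12.0
    markers: list[MarkerPeak] | None = None  # None -> default panel for polarity
    plasma_peaks: list[MarkerPeak] | None = None
    n_background_peaks: int = 650
    peak_sigma: float = 0.01
    tic_sigma: float = 0.25
    baseline_sigma: float = 0.02
    donor_sigma: float = 0.15
    n_roi_rbc: int = 5
    n_roi_wbc: int = 1
    n_roi_plasma: int = 3
    plasma_roi_semi_axes: tuple[float, float] = (12.0, 10.0)
    null_mode: bool = False
    seed: int = 0

    def resolved_markers(self) -> list[MarkerPeak]:
        m = default_markers(self.polarity) if self.markers is None else list(self.markers)
        if self.null_mode:
            m = [replace(p, enrichment={}) for p in m]
        return m

    def resolved_plasma_peaks(self) -> list[MarkerPeak]:
        p = default_plasma_peaks(self.polarity) if self.plasma_peaks is None else list(self.plasma_peaks)
        if self.null_mode:
            p = [replace(q, enrichment={}) for q in p]
        return p

    @property
    def effective_donor_sigma(self) -> float:
        return 0.0 if self.null_mode else self.donor_sigma


@dataclass
class SmearTruth:
    """Ground truth accompanying a simulated smear.

    ``labels`` is an (n_y, n_x) array of pixel classes; ``enriched``
    lists (m/z, cell type, direction) for every peak whose cell/plasma
    expectation differs from 1 ('up' = higher in the cell type than in
    plasma); ``roi_set`` is the ROI design used for sampling.
    """

    labels: np.ndarray
    enriched: list[tuple[float, str, str]]
    roi_set: ROISet


@dataclass
class DonorSmear:
    donor_id: str
    datasets: list[MSIDataset]
    roi_set: ROISet
    truth: SmearTruth


# ---------------------------------------------------------------------------
# cell placement


def _place_cells(config: SmearSimConfig, rng: np.random.Generator):
    """Place RBC/WBC disks at pixel centers without overlap (rejection
    sampling with bounded retries); return (labels, cells).

    ``cells`` is a list of (class, center_xy_um, radius_um)."""
    px, py = config.pitch
    width, height = config.n_x * px, config.n_y * py
    radii = [config.wbc_diameter_um / 2] * config.n_wbc + [config.rbc_diameter_um / 2] * config.n_rbc
    classes = ["WBC"] * config.n_wbc + ["RBC"] * config.n_rbc

    area_demand = sum(np.pi * r**2 for r in radii)
    if area_demand > 0.25 * width * height:  # loose packing bound for rejection sampling
        raise SimulationError(
            f"cell area demand {area_demand:.0f} µm² exceeds placement capacity "
            f"of the {width:.0f}x{height:.0f} µm grid"
        )

    placed: list[tuple[str, tuple[float, float], float]] = []
    max_tries = 200
    for cls, r in zip(classes, radii):
        for _ in range(max_tries):
            i = int(rng.integers(0, config.n_x))
            j = int(rng.integers(0, config.n_y))
            cx, cy = (i + 0.5) * px, (j + 0.5) * py
            if cx < r or cy < r or cx > width - r or cy > height - r:
                continue
            if all(
                (cx - ox) ** 2 + (cy - oy) ** 2 >= (r + orad + 2.0) ** 2
                for _, (ox, oy), orad in placed
            ):
                placed.append((cls, (cx, cy), r))
                break
        else:
            raise SimulationError(
                f"could not place {cls} cell after {max_tries} tries; grid too crowded"
            )

    labels = np.full((config.n_y, config.n_x), "plasma", dtype="<U6")
    jj, ii = np.meshgrid(np.arange(config.n_y), np.arange(config.n_x), indexing="ij")
    cx_all = (ii + 0.5) * px
    cy_all = (jj + 0.5) * py
    for cls, (cx, cy), r in placed:
        inside = (cx_all - cx) ** 2 + (cy_all - cy) ** 2 <= r**2
        labels[inside] = cls
    return labels, placed


def _select_rois(config: SmearSimConfig, labels: np.ndarray, cells, rng: np.random.Generator,
                 donor_id: str, smear_id: str) -> ROISet:
    """The published ROI design: 5 RBC + 1 WBC + 3 plasma ellipses per smear."""
    px, py = config.pitch
    rbc_cells = [c for c in cells if c[0] == "RBC"]
    wbc_cells = [c for c in cells if c[0] == "WBC"]
    if len(rbc_cells) < config.n_roi_rbc or len(wbc_cells) < config.n_roi_wbc:
        raise SimulationError("not enough placed cells for the requested ROI design")

    rois: list[ROI] = []
    for idx in rng.choice(len(rbc_cells), size=config.n_roi_rbc, replace=False):
        _, center, r = rbc_cells[idx]
        rois.append(ROI("RBC", center, (r, r), 0.0, donor_id, smear_id))
    for idx in rng.choice(len(wbc_cells), size=config.n_roi_wbc, replace=False):
        _, center, r = wbc_cells[idx]
        rois.append(ROI("WBC", center, (r, r), 0.0, donor_id, smear_id))

    a, b = config.plasma_roi_semi_axes
    chosen: list[tuple[float, float]] = []
    for _ in range(2000):
        if len(chosen) == config.n_roi_plasma:
            break
        i = int(rng.integers(0, config.n_x))
        j = int(rng.integers(0, config.n_y))
        cx, cy = (i + 0.5) * px, (j + 0.5) * py
        ii0 = max(0, int((cx - a) / px - 1))
        ii1 = min(config.n_x, int((cx + a) / px + 2))
        jj0 = max(0, int((cy - b) / py - 1))
        jj1 = min(config.n_y, int((cy + b) / py + 2))
        ok = True
        for j2 in range(jj0, jj1):
            for i2 in range(ii0, ii1):
                x, y = (i2 + 0.5) * px, (j2 + 0.5) * py
                if ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0 and labels[j2, i2] != "plasma":
                    ok = False
                    break
            if not ok:
                break
        if ok and all((cx - ox) ** 2 + (cy - oy) ** 2 > (2 * a) ** 2 for ox, oy in chosen):
            chosen.append((cx, cy))
    if len(chosen) < config.n_roi_plasma:
        raise SimulationError("could not find cell-free plasma ROI locations")
    for cx, cy in chosen:
        rois.append(ROI("plasma", (cx, cy), (a, b), 0.0, donor_id, smear_id))
    return ROISet(rois)


# ---------------------------------------------------------------------------
# spectra

_PEAK_OFFSETS = np.arange(-3, 4)  # sampled at center + sigma * offsets
_PEAK_SHAPE = np.exp(-0.5 * _PEAK_OFFSETS.astype(float) ** 2)
PEAK_SHAPE_SUM = float(_PEAK_SHAPE.sum())  # ~2.5066; binned area per unit amplitude


def _build_peak_panel(config: SmearSimConfig, rng: np.random.Generator):
    """Assemble the full peak list for one m/z window: markers + plasma
    background (those inside the window) + class-neutral fillers drawn on
    a 0.1 Da candidate grid (keeps peak supports disjoint)."""
    lo, hi = config.mz_range
    fixed = [p for p in config.resolved_markers() + config.resolved_plasma_peaks()
             if lo + 0.5 <= p.mz <= hi - 0.5]
    candidates = np.arange(lo + 2.0, hi - 2.0, 0.1)
    if fixed:
        fixed_mz = np.array([p.mz for p in fixed])
        keep = np.min(np.abs(candidates[:, None] - fixed_mz[None, :]), axis=1) > 0.15
        candidates = candidates[keep]
    n_fill = min(config.n_background_peaks, candidates.size)
    centers = rng.choice(candidates, size=n_fill, replace=False)
    centers += rng.uniform(-0.02, 0.02, size=n_fill)
    amps = rng.lognormal(mean=0.0, sigma=1.0, size=n_fill)
    fillers = [MarkerPeak(float(m), float(a)) for m, a in zip(centers, amps)]
    return fixed + fillers


_CLASS_ORDER = ("RBC", "WBC", "plasma")


def _simulate_spectra(config: SmearSimConfig, labels: np.ndarray,
                      peaks: Sequence[MarkerPeak], rng: np.random.Generator,
                      donor_mult: np.ndarray | None = None):
    """Per-pixel profile intensities for a fixed peak panel.

    Returns (axis, intensity matrix of shape (n_pixels, n_points)) with
    pixels in the dataset's flat (row-major) order.
    """
    n_peaks = len(peaks)
    centers = np.array([p.mz for p in peaks])
    amps = np.array([p.amplitude for p in peaks])
    if donor_mult is None:
        donor_mult = np.ones(n_peaks)

    class_mult = np.ones((len(_CLASS_ORDER), n_peaks))
    for k, p in enumerate(peaks):
        for ci, cls in enumerate(_CLASS_ORDER):
            class_mult[ci, k] = p.enrichment.get(cls, 1.0)

    flat_labels = labels.ravel()  # row-major == dataset flat order
    class_idx = np.array([_CLASS_ORDER.index(l) for l in flat_labels])
    n_px = flat_labels.size

    # sparse profile: each peak contributes 7 points at center + sigma*(-3..3)
    points = (centers[:, None] + config.peak_sigma * _PEAK_OFFSETS[None, :]).ravel()
    order = np.argsort(points)
    axis = points[order]
    if np.any(np.diff(axis) <= 0):
        raise SimulationError("peak supports collide; lower n_background_peaks")

    amp_matrix = amps[None, :] * donor_mult[None, :] * class_mult[class_idx, :]  # (n_px, n_peaks)
    profile = (amp_matrix[:, :, None] * _PEAK_SHAPE[None, None, :]).reshape(n_px, -1)
    profile = profile[:, order]

    tic_factor = rng.lognormal(mean=0.0, sigma=config.tic_sigma, size=n_px)
    noise = np.abs(rng.normal(0.0, config.baseline_sigma, size=profile.shape))
    intensity = profile * tic_factor[:, None] + noise
    return axis, intensity


def _truth_enriched(config: SmearSimConfig) -> list[tuple[float, str, str]]:
    out: list[tuple[float, str, str]] = []
    lo, hi = config.mz_range
    for p in config.resolved_markers() + config.resolved_plasma_peaks():
        if not (lo + 0.5 <= p.mz <= hi - 0.5):
            continue
        plasma_f = p.enrichment.get("plasma", 1.0)
        for cls in ("RBC", "WBC"):
            f = p.enrichment.get(cls, 1.0) / plasma_f
            if f > 1:
                out.append((p.mz, cls, "up"))
            elif f < 1:
                out.append((p.mz, cls, "down"))
    return out


def _dataset_from_matrix(config: SmearSimConfig, axis: np.ndarray,
                         intensity: np.ndarray, dataset_id: str) -> MSIDataset:
    spectra = [Spectrum(axis, intensity[k]) for k in range(intensity.shape[0])]
    return MSIDataset(
        n_x=config.n_x,
        n_y=config.n_y,
        pitch_x=config.pitch[0],
        pitch_y=config.pitch[1],
        polarity=config.polarity,
        matrix_label=config.matrix_label,
        setting_label=config.setting_label,
        mz_range=config.mz_range,
        spectra=spectra,
        uniform_axis=axis,
        dataset_id=dataset_id,
    )


def generate_smear(config: SmearSimConfig, donor_id: str = "donor01",
                   smear_id: str = "smear01"):
    """Simulate one smear for one m/z window.

    Returns ``(MSIDataset, ROISet, SmearTruth)``; deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    labels, cells = _place_cells(config, rng)
    roi_set = _select_rois(config, labels, cells, rng, donor_id, smear_id)
    peaks = _build_peak_panel(config, rng)
    sigma_d = config.effective_donor_sigma
    donor_mult = np.exp(rng.normal(0.0, sigma_d, size=len(peaks))) if sigma_d > 0 else None
    axis, intensity = _simulate_spectra(config, labels, peaks, rng, donor_mult)
    dataset = _dataset_from_matrix(config, axis, intensity, f"{donor_id}-{smear_id}")
    truth = SmearTruth(labels=labels, enriched=_truth_enriched(config), roi_set=roi_set)
    return dataset, roi_set, truth


def generate_study(config: SmearSimConfig, n_donors: int = 6,
                   mz_ranges: Sequence[tuple[float, float]] | None = None) -> list[DonorSmear]:
    """Simulate the full study design: one smear per donor, one dataset
    per (donor, m/z window), with per-(donor, peak) log-normal random
    effects so cross-donor variance exists.

    The cell layout and ROI design of a donor's smear are shared across
    its m/z windows (they are the same physical smear).
    """
    if n_donors < 2:
        raise ValueError("differential analysis needs at least 2 donors")
    if mz_ranges is None:
        mz_ranges = [config.mz_range]
    ss = np.random.SeedSequence(config.seed)
    panel_seed, *donor_seeds = ss.spawn(n_donors + 1)

    # one peak panel per m/z window, shared by all donors: the compounds in
    # the smears are the same across donors, only amplitudes vary
    panel_rng = np.random.default_rng(panel_seed)
    panels: list[tuple[SmearSimConfig, list[MarkerPeak]]] = []
    for rge in mz_ranges:
        cfg = replace(config, mz_range=tuple(rge))
        panels.append((cfg, _build_peak_panel(cfg, panel_rng)))

    out: list[DonorSmear] = []
    for d in range(n_donors):
        donor_id = f"donor{d + 1:02d}"
        rng = np.random.default_rng(donor_seeds[d])
        labels, cells = _place_cells(config, rng)
        roi_set = _select_rois(config, labels, cells, rng, donor_id, "smear01")
        datasets = []
        enriched: list[tuple[float, str, str]] = []
        for cfg, peaks in panels:
            sigma_d = cfg.effective_donor_sigma
            donor_mult = (
                np.exp(rng.normal(0.0, sigma_d, size=len(peaks))) if sigma_d > 0 else None
            )
            axis, intensity = _simulate_spectra(cfg, labels, peaks, rng, donor_mult)
            rge = cfg.mz_range
            datasets.append(
                _dataset_from_matrix(cfg, axis, intensity, f"{donor_id}-{rge[0]:.0f}-{rge[1]:.0f}")
            )
            enriched.extend(_truth_enriched(cfg))
        truth = SmearTruth(labels=labels, enriched=enriched, roi_set=roi_set)
        out.append(DonorSmear(donor_id, datasets, roi_set, truth))
    return out
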