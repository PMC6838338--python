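"""Synthetic cohort generator with known ground truth.

Every input the analysis pipeline consumes can be simulated here: variable-TR
spin-echo image series with a known per-pixel R1, a smooth multiplicative
coil-sensitivity field, Rician magnitude noise and rigid motion jitter; a
three-group rat cohort (normal hearing NH, noise exposed NE, noise exposed +
anti-oxidants NE+AO) with protected/unprotected ear R1 effects; ABR evoked
waveforms with known hearing thresholds; and two-channel cochlear-epithelium
images (phalloidin + HO-1) with known hair-cell presence and intensity
offsets.

Default parameters are the study conditions: the 23-image / 8-TR acquisition
schedule, 192x192 matrix over a 20x20 mm^2 field of view, group sizes
11/11/8, the group-mean R1 values (s^-1) and their between-subject spreads,
the five ABR test frequencies, and HO-1 percent-change group means.

All randomness flows from explicit seeds; a global seed fans out to
sub-generators through ``numpy.random.SeedSequence`` spawn keys so that each
subject/stage draws from an independent, reproducible stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .abr import EvokedRecording
from .r1map import ImageSeries, RoiMask

# ---------------------------------------------------------------------------
# seed plumbing
# ---------------------------------------------------------------------------

def child_rng(seed: int, *keys) -> np.random.Generator:
    """Independent generator derived from a master seed and a key path.

    String keys are hashed with CRC-32 so the split is stable across runs
    and platforms.
    """
    ints = tuple(
        k if isinstance(k, (int, np.integer)) else zlib.crc32(str(k).encode())
        for k in keys
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=ints))


# ---------------------------------------------------------------------------
# acquisition protocol
# ---------------------------------------------------------------------------

#: Acquisition order: (TR seconds, number of repeats).  More repeats are
#: collected at short TRs to offset their lower signal.
DEFAULT_TR_SCHEDULE: tuple[tuple[float, int], ...] = (
    (0.15, 6), (3.50, 1), (1.00, 2), (1.90, 1),
    (0.35, 4), (2.70, 1), (0.25, 5), (0.50, 3),
)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Single-spin-echo variable-TR protocol."""

    tr_schedule: tuple[tuple[float, int], ...] = DEFAULT_TR_SCHEDULE
    te_s: float = 0.011
    fov_mm: tuple[float, float] = (20.0, 20.0)
    matrix: tuple[int, int] = (192, 192)
    slice_thickness_um: float = 400.0

    def __post_init__(self) -> None:
        if any(tr <= 0 for tr, _ in self.tr_schedule):
            raise ValueError("all TRs must be positive")
        if any(n < 1 for _, n in self.tr_schedule):
            raise ValueError("each TR needs at least one repeat")

    @property
    def n_images(self) -> int:
        return sum(n for _, n in self.tr_schedule)

    @property
    def distinct_trs(self) -> np.ndarray:
        return np.unique([tr for tr, _ in self.tr_schedule])

    @property
    def in_plane_resolution_um(self) -> tuple[float, float]:
        return (self.fov_mm[0] / self.matrix[0] * 1000.0,
                self.fov_mm[1] / self.matrix[1] * 1000.0)

    def expand(self):
        """Yield (tr, repeat_index) in acquisition order."""
        for tr, n in self.tr_schedule:
            for rep in range(n):
                yield tr, rep


# ---------------------------------------------------------------------------
# phantom / coil / noise specs
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Piecewise-constant digital phantom.

    ``label_map`` assigns a tissue class per pixel; class 0 is background
    with zero equilibrium signal.  ``class_r1`` (s^-1) and ``class_s0``
    (arbitrary units) give ground truth per class.  ``roi_masks`` name pixel
    sets (e.g. left/right cochlea) for ROI statistics.
    """

    label_map: np.ndarray
    class_r1: dict
    class_s0: dict
    roi_masks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=int)
        labels = set(np.unique(self.label_map)) - {0}
        for cls in labels:
            if cls not in self.class_r1 or cls not in self.class_s0:
                raise ValueError(f"class {cls} missing r1/s0")
            if self.class_r1[cls] <= 0:
                raise ValueError(f"class {cls} has nonpositive R1")
        if self.class_s0.get(0, 0.0) != 0.0:
            raise ValueError("background class must have zero signal")
        tissue = self.label_map > 0
        for name, mask in self.roi_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.label_map.shape:
                raise ValueError(f"ROI {name!r} shape mismatch")
            if np.any(mask & ~tissue):
                raise ValueError(f"ROI {name!r} extends outside tissue")
            self.roi_masks[name] = mask

    @property
    def shape(self):
        return self.label_map.shape

    def r1_map(self) -> np.ndarray:
        out = np.zeros(self.shape)
        for cls, r1 in self.class_r1.items():
            out[self.label_map == cls] = r1
        return out

    def s0_map(self) -> np.ndarray:
        out = np.zeros(self.shape)
        for cls, s0 in self.class_s0.items():
            out[self.label_map == cls] = s0
        return out


def two_region_phantom(shape=(96, 96), r1_left=0.2, r1_right=0.4,
                       s0=1.0) -> PhantomSpec:
    """Disc phantom split into two R1 regions; ROIs cover each half."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    disc = (yy - ny / 2) ** 2 + (xx - nx / 2) ** 2 < (0.4 * min(ny, nx)) ** 2
    labels = np.zeros(shape, dtype=int)
    labels[disc & (xx < nx / 2)] = 1
    labels[disc & (xx >= nx / 2)] = 2
    return PhantomSpec(
        labels, {1: r1_left, 2: r1_right}, {0: 0.0, 1: s0, 2: s0},
        {"left": labels == 1, "right": labels == 2},
    )


def cochlea_phantom(shape=(192, 192), tissue_r1=0.5, cochlea_r1=(0.25, 0.25),
                    s0=1.0) -> PhantomSpec:
    """Head-slice phantom: brain-tissue disc with left/right cochlear ROIs."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    head = (yy - ny / 2) ** 2 / (0.42 * ny) ** 2 + \
        (xx - nx / 2) ** 2 / (0.38 * nx) ** 2 < 1
    labels = np.where(head, 1, 0)
    r = max(3, int(0.035 * min(ny, nx)))
    centers = {"left-cochlea": (int(0.68 * ny), int(0.30 * nx)),
               "right-cochlea": (int(0.68 * ny), int(0.70 * nx))}
    rois = {}
    for cls, (name, (cy, cx)) in enumerate(centers.items(), start=2):
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 < r ** 2
        labels[blob] = cls
        rois[name] = blob
    return PhantomSpec(
        labels,
        {1: tissue_r1, 2: cochlea_r1[0], 3: cochlea_r1[1]},
        {0: 0.0, 1: s0, 2: s0, 3: s0},
        rois,
    )


@dataclass
class CoilFieldSpec:
    """Smooth, strictly positive multiplicative receive-coil profile."""

    field_kind: str = "uniform"          # uniform | low-order-polynomial | gaussian-bump
    amplitude_range: tuple[float, float] = (1.0, 1.0)
    smoothness_scale: float = 40.0       # pixels

    def __post_init__(self) -> None:
        lo, hi = self.amplitude_range
        if lo <= 0 or hi < lo:
            raise ValueError("amplitude range must be positive and ordered")

    def render(self, shape, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.amplitude_range
        if self.field_kind == "uniform" or hi == lo:
            return np.full(shape, (lo + hi) / 2.0)
        ny, nx = shape
        y = np.linspace(-1, 1, ny)[:, None]
        x = np.linspace(-1, 1, nx)[None, :]
        if self.field_kind == "low-order-polynomial":
            coef = rng.uniform(-1, 1, size=5)
            raw = coef[0] * y + coef[1] * x + coef[2] * y * x \
                + coef[3] * y ** 2 + coef[4] * x ** 2
        elif self.field_kind == "gaussian-bump":
            cy, cx = rng.uniform(-0.5, 0.5, size=2)
            s = 2.0 * self.smoothness_scale / max(ny, nx)
            raw = np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * s ** 2))
        else:
            raise ValueError(f"unknown field kind {self.field_kind!r}")
        raw = raw - raw.min()
        span = raw.max() or 1.0
        return lo + (hi - lo) * raw / span


@dataclass
class NoiseSpec:
    """Magnitude-image noise and motion jitter for the MRI generator."""

    model: str = "rician"        # none | rician
    sigma: float = 0.03          # same units as S0; SNR ~ 20 at the longest TR
    jitter_sigma: float = 0.5    # px, rigid per-image translation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in {"none", "rician"}:
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma < 0 or self.jitter_sigma < 0:
            raise ValueError("sigma and jitter_sigma must be nonnegative")


# ---------------------------------------------------------------------------
# MRI forward model and series generator
# ---------------------------------------------------------------------------

def signal_model(r1, s0, tr):
    """Saturation-recovery signal S(TR) = S0 * (1 - exp(-TR * R1)).

    This equals the three-parameter fit form ``a + b*exp(-c*TR)`` with
    a = S0, b = -S0 and c = R1, so the pixel fit is exactly specified.
    Accepts scalars or broadcastable arrays; ``r1`` must be positive
    wherever ``s0`` is nonzero (zero-signal background pixels may carry
    a placeholder rate).
    """
    r1 = np.asarray(r1, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    tr = np.asarray(tr, dtype=float)
    if np.any((r1 <= 0) & (s0 != 0)):
        raise ValueError("R1 must be positive for signal-bearing pixels")
    if np.any(s0 < 0) or np.any(tr < 0):
        raise ValueError("S0 and TR must be nonnegative")
    with np.errstate(invalid="ignore"):
        out = s0 * (1.0 - np.exp(-tr * np.where(r1 > 0, r1, 1.0)))
    return out if out.ndim else float(out)


@dataclass
class SeriesTruth:
    """Ground truth emitted alongside a generated series."""

    r1_map: np.ndarray
    s0_map: np.ndarray
    coil_field: np.ndarray
    shifts: np.ndarray           # (n, 2) applied (dy, dx) per image
    sigma: float


def generate_series(phantom: PhantomSpec, protocol: AcquisitionProtocol,
                    coil: CoilFieldSpec, noise: NoiseSpec,
                    rng: np.random.Generator | None = None):
    """Render one subject's image series from the forward model.

    Each scheduled repeat becomes one image: coil field x signal model per
    pixel, rigidly translated by a sampled jitter, with Rician noise applied
    as the magnitude of a complex Gaussian perturbation.  Returns
    ``(ImageSeries, SeriesTruth)``; fully reproducible from ``noise.seed``.
    """
    if phantom.shape != tuple(protocol.matrix):
        raise ValueError(
            f"phantom shape {phantom.shape} does not match protocol matrix "
            f"{tuple(protocol.matrix)}"
        )
    rng = rng if rng is not None else child_rng(noise.seed, "series")
    r1 = phantom.r1_map()
    s0 = phantom.s0_map()
    fieldmap = coil.render(phantom.shape, rng)
    if np.any(fieldmap <= 0):
        raise ValueError("coil field must be strictly positive")

    trs, reps = zip(*protocol.expand())
    n = len(trs)
    shifts = np.zeros((n, 2))
    if noise.jitter_sigma > 0:
        shifts = rng.normal(0.0, noise.jitter_sigma, size=(n, 2))
    images = np.empty((n,) + phantom.shape)
    for i, tr in enumerate(trs):
        ideal = fieldmap * signal_model(r1, s0, tr)
        if np.any(shifts[i] != 0):
            ideal = ndimage.shift(ideal, shifts[i], order=3, mode="nearest")
        if noise.model == "rician" and noise.sigma > 0:
            re = ideal + rng.normal(0.0, noise.sigma, size=ideal.shape)
            im = rng.normal(0.0, noise.sigma, size=ideal.shape)
            ideal = np.hypot(re, im)
        images[i] = ideal
    series = ImageSeries(images, np.asarray(trs), np.asarray(reps))
    return series, SeriesTruth(r1, s0, fieldmap, shifts, noise.sigma)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

#: Printed group-mean R1 (s^-1) and SEM-implied between-subject SDs.
#: SD = SEM * sqrt(n) with n = 11, 11, 8.
DEFAULT_GROUP_R1 = {
    "NH":    {"unprotected": (0.236, 0.009 * np.sqrt(11)),
              "protected":   (0.249, 0.012 * np.sqrt(11))},
    "NE":    {"unprotected": (0.301, 0.010 * np.sqrt(11)),
              "protected":   (0.228, 0.021 * np.sqrt(11))},
    "NE+AO": {"unprotected": (0.240, 0.007 * np.sqrt(8)),
              "protected":   (0.234, 0.012 * np.sqrt(8))},
}

DEFAULT_GROUP_SIZES = {"NH": 11, "NE": 11, "NE+AO": 8}

#: Ear ROI names: in the scanner, the unprotected (noise-exposed) ear is the
#: right cochlea and the silicone-protected ear the left.
EAR_TO_ROI = {"protected": "left-cochlea", "unprotected": "right-cochlea"}


@dataclass
class CohortSpec:
    """Three-group cohort with protected/unprotected ear R1 effects."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    group_r1: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_GROUP_R1.items()})
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    coil: CoilFieldSpec = field(default_factory=CoilFieldSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    phantom_shape: tuple[int, int] | None = None   # defaults to protocol matrix
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs at least 2 subjects")
            if g not in self.group_r1:
                raise ValueError(f"group {g!r} missing R1 means")
        for g, ears in self.group_r1.items():
            for ear, (mean, sd) in ears.items():
                if mean <= 0 or sd < 0:
                    raise ValueError(f"invalid R1 spec for {g}/{ear}")


@dataclass
class CohortResult:
    truth_table: pd.DataFrame                 # subject, group, ear, value
    subjects: dict                            # subject -> (ImageSeries, SeriesTruth)
    roi_masks: dict                           # subject -> {ear: RoiMask}


def cohort_truth_table(spec: CohortSpec) -> pd.DataFrame:
    """Draw subject-level true ROI-mean R1 from the group/ear distributions."""
    rng = child_rng(spec.seed, "cohort-truth")
    rows = []
    for group in spec.group_sizes:
        for k in range(spec.group_sizes[group]):
            subject = f"{group}-{k + 1:02d}"
            for ear in ("protected", "unprotected"):
                mean, sd = spec.group_r1[group][ear]
                value = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
                while value <= 0:   # R1 is a rate; redraw pathological tails
                    value = float(rng.normal(mean, sd))
                rows.append({"subject": subject, "group": group,
                             "ear": ear, "value": value})
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, render_images: bool = True) -> CohortResult:
    """Generate the cohort truth table and (optionally) per-subject series.

    With ``render_images=True`` each subject gets an image series whose
    cochlear ROI classes carry the subject's true per-ear R1.  Statistical
    simulations that only need the truth table can skip rendering.
    """
    truth = cohort_truth_table(spec)
    subjects: dict = {}
    rois: dict = {}
    if render_images:
        shape = tuple(spec.phantom_shape or spec.protocol.matrix)
        protocol = spec.protocol
        if shape != tuple(protocol.matrix):
            protocol = AcquisitionProtocol(
                tr_schedule=protocol.tr_schedule, te_s=protocol.te_s,
                fov_mm=protocol.fov_mm, matrix=shape,
                slice_thickness_um=protocol.slice_thickness_um)
        for subject, sub in truth.groupby("subject", sort=False):
            by_ear = dict(zip(sub["ear"], sub["value"]))
            phantom = cochlea_phantom(
                shape,
                cochlea_r1=(by_ear["protected"], by_ear["unprotected"]),
            )
            sub_noise = NoiseSpec(spec.noise.model, spec.noise.sigma,
                                  spec.noise.jitter_sigma, spec.noise.seed)
            srng = child_rng(spec.seed, "cohort-images", subject)
            series, struth = generate_series(phantom, protocol, spec.coil,
                                             sub_noise, rng=srng)
            subjects[subject] = (series, struth)
            rois[subject] = {
                ear: RoiMask(roi_name, phantom.roi_masks[roi_name])
                for ear, roi_name in EAR_TO_ROI.items()
            }
    return CohortResult(truth, subjects, rois)


def r1_change_from_reference(table: pd.DataFrame, reference_group: str = "NH",
                             reference_ear: str = "protected") -> pd.DataFrame:
    """Re-express R1 values as change from the NH protected-ear mean.

    Provided for display conventions that plot deltas rather than absolute
    rates; the statistics are invariant to this shift.
    """
    ref = table.query("group == @reference_group and ear == @reference_ear")
    offset = float(ref["value"].mean())
    out = table.copy()
    out["value"] = out["value"] - offset
    return out


# ---------------------------------------------------------------------------
# ABR generator
# ---------------------------------------------------------------------------

#: Baseline (pre-exposure, protected-ear) thresholds: region -> (mean dB SPL,
#: between-subject SD implied by SEM at n = 6).
DEFAULT_BASELINE_THRESHOLDS = {
    "apex": (29.0, 0.6 * np.sqrt(6)),
    "middle": (35.0, 0.8 * np.sqrt(6)),
    "base": (35.0, 1.4 * np.sqrt(6)),
}

#: Post-exposure shifts (dB): protected ears show small elevations, the
#: unprotected ear a profound (> 60 dB) loss.
DEFAULT_PROTECTED_SHIFTS = {"apex": (10.0, 5.0 * np.sqrt(6)),
                            "middle": (9.0, 3.0 * np.sqrt(6)),
                            "base": (12.0, 7.0 * np.sqrt(6))}
DEFAULT_UNPROTECTED_SHIFT = (65.0, 8.0)

DEFAULT_ABR_FREQUENCIES = (4.0, 12.0, 20.0, 25.0, 36.0)


@dataclass
class ABRSimSpec:
    """Evoked-waveform simulation with known thresholds.

    ``true_thresholds`` maps (subject, ear, frequency_khz) to a threshold in
    dB SPL (snapped to the level grid) or ``None`` for no response anywhere
    in the tested range.  The wave-1 amplitude is zero strictly below
    threshold and grows linearly above it.
    """

    true_thresholds: dict
    frequencies_khz: tuple = DEFAULT_ABR_FREQUENCIES
    level_grid_db: tuple = tuple(range(100, 5, -5))
    sample_rate_hz: float = 24400.0
    duration_ms: float = 15.0
    amp_at_threshold_uv: float = 1.0
    amp_slope_uv_per_db: float = 0.04
    baseline_noise_sd_uv: float = 0.15
    noise_smoothness_ms: float = 1.0
    wave1_peak_ms: float = 12.0
    wave1_trough_ms: float = 12.4
    wave1_width_ms: float = 0.12
    n_trials: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.level_grid_db:
            raise ValueError("level grid is empty")
        levels = np.asarray(self.level_grid_db, dtype=float)
        if np.any(np.diff(levels) >= 0) or levels[0] != 100:
            raise ValueError("levels must descend strictly from 100 dB SPL")
        grid = set(levels)
        for key, thr in self.true_thresholds.items():
            if thr is not None and thr not in grid:
                raise ValueError(f"threshold {thr} for {key} not on level grid")


def _smooth_noise(n: int, sd: float, smooth_samples: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise with unit-calibrated ensemble SD."""
    if sd == 0:
        return np.zeros(n)
    raw = ndimage.gaussian_filter1d(rng.standard_normal(n), smooth_samples)
    kernel = np.zeros(n)
    kernel[0] = 1.0
    kernel = ndimage.gaussian_filter1d(kernel, smooth_samples, mode="wrap")
    return raw * (sd / np.sqrt(np.sum(kernel ** 2)))


def wave1_amplitude(level_db: float, threshold_db: float | None,
                    spec: ABRSimSpec) -> float:
    """Peak-to-trough wave-1 amplitude (uV): 0 below threshold, linear above."""
    if threshold_db is None or level_db < threshold_db:
        return 0.0
    return spec.amp_at_threshold_uv + \
        spec.amp_slope_uv_per_db * (level_db - threshold_db)


def generate_abr_recordings(spec: ABRSimSpec):
    """Simulate the full descending-level sweep for every truth entry.

    Returns ``(recordings, truth_table)`` where the truth table has columns
    (subject, ear, frequency_khz, threshold_db, censored).
    """
    n = int(round(spec.duration_ms / 1000.0 * spec.sample_rate_hz))
    t_ms = np.arange(n) / spec.sample_rate_hz * 1000.0
    smooth_samples = spec.noise_smoothness_ms / 1000.0 * spec.sample_rate_hz
    peak = np.exp(-(t_ms - spec.wave1_peak_ms) ** 2 / (2 * spec.wave1_width_ms ** 2))
    trough = np.exp(-(t_ms - spec.wave1_trough_ms) ** 2 / (2 * spec.wave1_width_ms ** 2))
    shape = (peak - trough)
    shape = shape / (shape.max() - shape.min())   # unit peak-to-trough

    recordings = []
    truth_rows = []
    for (subject, ear, freq), threshold in sorted(spec.true_thresholds.items()):
        rng = child_rng(spec.seed, "abr", subject, ear, int(freq * 1000))
        truth_rows.append({"subject": subject, "ear": ear,
                           "frequency_khz": freq,
                           "threshold_db": np.nan if threshold is None else threshold,
                           "censored": threshold is None})
        for level in spec.level_grid_db:
            amp = wave1_amplitude(level, threshold, spec)
            wave = amp * shape + _smooth_noise(
                n, spec.baseline_noise_sd_uv, smooth_samples, rng)
            recordings.append(EvokedRecording(
                subject=subject, ear=ear, frequency_khz=freq,
                level_db=float(level), waveform=wave,
                sample_rate_hz=spec.sample_rate_hz, n_trials=spec.n_trials))
    return recordings, pd.DataFrame(truth_rows)


def abr_cohort_thresholds(n_subjects: int = 6, stage: str = "baseline",
                          level_step: int = 5, seed: int = 0) -> dict:
    """Draw a truth-threshold map for a simulated cohort.

    ``stage`` is "baseline" (both ears at normal-hearing levels) or "post"
    (protected ears shifted by ~10 dB, unprotected by ~65 dB; shifts above
    the 100 dB ceiling are censored to ``None``).
    """
    from .abr import region_of

    rng = child_rng(seed, "abr-truth", stage)
    grid = np.arange(100, 5 - 1, -level_step)
    out: dict = {}
    for k in range(n_subjects):
        subject = f"S{k + 1:02d}"
        for freq in DEFAULT_ABR_FREQUENCIES:
            region = region_of(freq)
            base_mean, base_sd = DEFAULT_BASELINE_THRESHOLDS[region]
            base = rng.normal(base_mean, base_sd)
            for ear in ("protected", "unprotected"):
                value = base
                if stage == "post":
                    if ear == "protected":
                        mean, sd = DEFAULT_PROTECTED_SHIFTS[region]
                    else:
                        mean, sd = DEFAULT_UNPROTECTED_SHIFT
                    value = base + max(0.0, rng.normal(mean, sd))
                snapped = float(grid[np.argmin(np.abs(grid - value))])
                out[(subject, ear, freq)] = None if value > 100 else snapped
    return out


# ---------------------------------------------------------------------------
# histology generator
# ---------------------------------------------------------------------------

HAIR_CELL_ROWS = ("IHC", "OHC1", "OHC2", "OHC3")

#: HO-1 channel group means sized so the percent change from background
#: reproduces the observed group levels (21.7 / 119.1 / 20.4 %).
DEFAULT_HO1_MEANS = {"NH": 121.7, "NE": 219.1, "NE+AO": 120.4}
DEFAULT_BACKGROUND_MEAN = 100.0


def ne_missing_prob(row: str, position_pct: float) -> float:
    """Noise-exposed hair-cell loss profile along the spiral.

    Outer-hair-cell loss peaks 20-30% and 45-50% from the apex; inner-hair-
    cell loss concentrates in the apical 30%.
    """
    if row == "IHC":
        return 0.5 if position_pct <= 30 else 0.05
    if 20 <= position_pct <= 30 or 45 <= position_pct <= 50:
        return 0.95
    return 0.25


def nh_missing_prob(row: str, position_pct: float) -> float:
    """Normal-hearing profile: minimal scattered loss."""
    return 0.02


@dataclass
class HistologySimSpec:
    """Cochlear whole-mount simulation: hair-cell grid + two-channel images.

    ``missing_prob`` is a scalar or a callable ``(row, position_pct) -> p``.
    Positions run 0-100% of the spiral from the apex; each subdivision
    (apex/middle/base) contributes ``images_per_subdivision`` fields of
    ``cells_per_image`` serial cells.
    """

    missing_prob: object = 0.0
    ho1_mean: float = DEFAULT_HO1_MEANS["NH"]
    background_mean: float = DEFAULT_BACKGROUND_MEAN
    intensity_sd: float = 5.0
    images_per_subdivision: int = 3
    cells_per_image: int = 12
    image_shape: tuple[int, int] = (64, 96)
    cell_amplitude: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not callable(self.missing_prob):
            p = float(self.missing_prob)
            if not 0.0 <= p <= 1.0:
                raise ValueError("missing_prob must be in [0, 1]")
        if self.ho1_mean < 0 or self.background_mean < 0:
            raise ValueError("intensities must be nonnegative")
        if self.intensity_sd < 0:
            raise ValueError("intensity_sd must be nonnegative")

    def prob(self, row: str, position_pct: float) -> float:
        if callable(self.missing_prob):
            return float(self.missing_prob(row, position_pct))
        return float(self.missing_prob)


@dataclass
class CellLattice:
    """Expected cell centers for scoring: (row, position_pct) -> (y, x)."""

    centers: dict
    footprint_radius: int = 3


@dataclass
class HistologyImage:
    subdivision: str
    image_id: str
    phalloidin: np.ndarray
    ho1: np.ndarray
    lattice: CellLattice
    epithelium_mask: np.ndarray
    background_mask: np.ndarray


SUBDIVISION_SPAN = {"apex": (0.0, 33.0), "middle": (33.0, 66.0),
                    "base": (66.0, 100.0)}


def _render_field(present: dict, positions, spec: HistologySimSpec,
                  rng: np.random.Generator):
    """Render one microscope field (4 rows x cells_per_image cells)."""
    ny, nx = spec.image_shape
    row_y = np.linspace(0.25 * ny, 0.75 * ny, len(HAIR_CELL_ROWS))
    col_x = np.linspace(0.12 * nx, 0.88 * nx, len(positions))
    yy, xx = np.mgrid[0:ny, 0:nx]
    phall = np.zeros((ny, nx))
    centers = {}
    for ri, row in enumerate(HAIR_CELL_ROWS):
        for ci, pos in enumerate(positions):
            cy, cx = row_y[ri], col_x[ci]
            centers[(row, pos)] = (float(cy), float(cx))
            if present[(row, pos)]:
                phall += spec.cell_amplitude * np.exp(
                    -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.0 ** 2))
    epithelium = (yy > 0.15 * ny) & (yy < 0.85 * ny)
    background = yy >= 0.92 * ny
    ho1 = np.full((ny, nx), spec.background_mean)
    ho1[epithelium] = spec.ho1_mean
    if spec.intensity_sd > 0:
        phall = np.clip(phall + rng.normal(0, spec.intensity_sd, phall.shape), 0, None)
        ho1 = np.clip(ho1 + rng.normal(0, spec.intensity_sd, ho1.shape), 0, None)
    return HistologyImage("", "", phall, ho1, CellLattice(centers),
                          epithelium, background)


def generate_histology(spec: HistologySimSpec):
    """Simulate one ear's whole-mount survey.

    Returns ``(images, truth_grid, truth_intensities)``: the rendered
    two-channel fields, a truth table of hair-cell presence per
    (row, position % from apex), and the configured epithelium/background
    intensity means.
    """
    rng = child_rng(spec.seed, "histology")
    images: list[HistologyImage] = []
    truth_rows = []
    for subdivision, (lo, hi) in SUBDIVISION_SPAN.items():
        edges = np.linspace(lo, hi, spec.images_per_subdivision + 1)
        for im in range(spec.images_per_subdivision):
            positions = np.linspace(edges[im], edges[im + 1],
                                    spec.cells_per_image + 2)[1:-1]
            positions = np.round(positions, 3)
            present = {}
            for row in HAIR_CELL_ROWS:
                for pos in positions:
                    p = spec.prob(row, pos)
                    is_present = bool(rng.random() >= p)
                    present[(row, pos)] = is_present
                    truth_rows.append({"row": row, "position_pct": pos,
                                       "present": is_present})
            field = _render_field(present, positions, spec, rng)
            field.subdivision = subdivision
            field.image_id = f"{subdivision}-{im + 1}"
            images.append(field)
    truth_grid = pd.DataFrame(truth_rows)
    truth_intensities = {"ho1_mean": spec.ho1_mean,
                         "background_mean": spec.background_mean}
    return images, truth_grid, truth_intensities


#: Between-rat HO-1 spread (percent-change units ~ intensity units at
#: background 100), implied by the printed group SEMs: SD = SEM * sqrt(n).
DEFAULT_HO1_RAT_SD = {"NH": 19.4 * np.sqrt(11), "NE": 12.2 * np.sqrt(11),
                      "NE+AO": 15.9 * np.sqrt(8)}


def generate_histology_cohort(group_sizes=None, ho1_means=None,
                              rat_sd=None, intensity_sd: float = 5.0,
                              seed: int = 0) -> pd.DataFrame:
    """Per-image HO-1 intensity records for a three-group cohort.

    Emits the long-format table consumed by the heteroscedastic mixed-model
    analysis: one row per (rat, ear, subdivision image) with epithelium and
    background mean intensities.  Rat-level variation enters as a shared
    intensity offset sized from the observed group SEMs; the unprotected ear
    carries extra residual spread.
    """
    group_sizes = group_sizes or dict(DEFAULT_GROUP_SIZES)
    ho1_means = ho1_means or dict(DEFAULT_HO1_MEANS)
    rat_sd = rat_sd or dict(DEFAULT_HO1_RAT_SD)
    rng = child_rng(seed, "histology-cohort")
    ear_resid_sd = {"protected": 8.0, "unprotected": 16.0}
    rows = []
    for group, n in group_sizes.items():
        for k in range(n):
            rat = f"{group}-{k + 1:02d}"
            rat_offset = rng.normal(0.0, rat_sd[group])
            for ear in ("protected", "unprotected"):
                for img in range(3):
                    epi = ho1_means[group] + rat_offset + \
                        rng.normal(0.0, ear_resid_sd[ear])
                    bg = DEFAULT_BACKGROUND_MEAN + rng.normal(0.0, intensity_sd)
                    rows.append({"rat": rat, "group": group, "ear": ear,
                                 "subdivision": "apex", "image_id": f"apex-{img + 1}",
                                 "roi_mean": max(epi, 0.0),
                                 "background_mean": max(bg, 1e-6)})
    return pd.DataFrame(rows)
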