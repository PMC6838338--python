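"""Pixel-wise R1 (= 1/T1) mapping from a variable-TR single-spin-echo series.

The analysis chain mirrors the standard saturation-recovery workflow for
small-animal cochlear relaxometry:

1. rigid registration of repeats acquired at the same TR,
2. averaging within TR (more repeats are acquired at short TRs to
   compensate for their lower SNR),
3. registration of the TR-averaged images across TRs,
4. heavy smoothing of the shortest-TR image to act as a low-pass estimate
   of the receive-coil sensitivity (B1) profile,
5. division of every other TR image by that smoothed reference, and
6. a three-parameter exponential fit ``intensity = a + b*exp(-c*TR)`` per
   pixel, where ``c`` is the spin-lattice relaxation rate R1 in 1/s.

Because the reference division is a per-pixel constant across TRs it cancels
multiplicative coil inhomogeneity exactly without biasing the fitted rate.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

#: Reference (shortest) repetition time in seconds used for normalization.
DEFAULT_REFERENCE_TR = 0.15

#: 3x3 binomial kernel, the discrete Gaussian (sigma ~ 0.85 px) applied to
#: the reference image; three sequential passes give an effective 7x7 support.
GAUSSIAN_3X3 = np.outer([1.0, 2.0, 1.0], [1.0, 2.0, 1.0]) / 16.0

_FIT_BOUND_C_MIN = 1e-6
_FIT_BOUND_C_MAX_DEFAULT = 100.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ImageSeries:
    """Stack of 2-D magnitude images, each tagged with its TR and repeat index."""

    images: np.ndarray          # (n, H, W)
    tr: np.ndarray              # (n,) seconds
    repeat_index: np.ndarray    # (n,) 0-based repeat within each TR group

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.tr = np.asarray(self.tr, dtype=float)
        self.repeat_index = np.asarray(self.repeat_index, dtype=int)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, H, W) stack")
        n = self.images.shape[0]
        if self.tr.shape != (n,) or self.repeat_index.shape != (n,):
            raise ValueError("tr and repeat_index must have one entry per image")
        if np.any(self.tr <= 0):
            raise ValueError("all repetition times must be positive")

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    @property
    def distinct_trs(self) -> np.ndarray:
        return np.unique(self.tr)


@dataclass
class AveragedSeries:
    """One image per distinct TR, sorted by ascending TR."""

    images: np.ndarray  # (m, H, W)
    tr: np.ndarray      # (m,) strictly increasing seconds

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.tr = np.asarray(self.tr, dtype=float)
        if self.images.shape[0] != self.tr.shape[0]:
            raise ValueError("one image per TR required")
        if np.any(np.diff(self.tr) <= 0):
            raise ValueError("TRs must be strictly increasing")

    def __len__(self) -> int:
        return self.images.shape[0]


@dataclass
class NormalizedSeries:
    """Ratio images (each TR divided by the smoothed reference-TR image)."""

    images: np.ndarray      # (k, H, W)
    tr: np.ndarray          # (k,) seconds, reference TR excluded
    mask: np.ndarray        # (H, W) valid-pixel mask
    reference_tr: float

    def __len__(self) -> int:
        return self.images.shape[0]


@dataclass
class R1Map:
    """Per-pixel three-parameter fit; ``c`` is R1 in 1/s where converged."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    converged: np.ndarray       # bool mask; False pixels carry NaN parameters
    residual_rms: np.ndarray

    @property
    def fraction_converged(self) -> float:
        return float(np.mean(self.converged))


@dataclass
class RoiMask:
    """Named boolean pixel mask (0-based, row-major coordinates)."""

    name: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if not self.pixels.any():
            raise ValueError(f"ROI {self.name!r} is empty")


# ---------------------------------------------------------------------------
# registration and averaging
# ---------------------------------------------------------------------------

def _estimate_shift(reference: np.ndarray, moving: np.ndarray,
                    upsample_factor: int = 100,
                    normalization=None) -> tuple[np.ndarray, bool]:
    """Subpixel translation of ``moving`` relative to ``reference``.

    Returns (shift to apply to align moving onto reference, degenerate flag).
    Constant images carry no registration information; they get an identity
    transform and a warning flag rather than an arbitrary shift.

    ``normalization=None`` (plain cross-correlation) is the accurate choice
    for same-contrast images; ``"phase"`` (whitened spectrum) is invariant to
    the TR-dependent contrast differences between TR-averaged images.
    """
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        return np.zeros(2), True
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsample_factor,
        normalization=normalization
    )
    return np.asarray(shift, dtype=float), False


def _apply_shift(image: np.ndarray, shift: np.ndarray) -> np.ndarray:
    if np.all(shift == 0):
        return image.copy()
    return ndimage.shift(image, shift, order=3, mode="nearest")


def register_rigid(series, grouping: str = "within_tr", upsample_factor: int = 100):
    """Rigidly (translation-only) align a series.

    grouping="within_tr" takes an :class:`ImageSeries` and aligns the repeats
    of each TR to the first repeat of that TR.  grouping="across_tr" takes an
    :class:`AveragedSeries` and aligns every TR image to the longest-TR image
    (the highest-SNR anatomy).  Returns ``(registered, info)`` where ``info``
    holds the estimated per-image shifts and degenerate-image flags.
    """
    if grouping == "within_tr":
        if not isinstance(series, ImageSeries):
            raise TypeError("within_tr registration expects an ImageSeries")
        out = np.empty_like(series.images)
        shifts = np.zeros((len(series), 2))
        degenerate = np.zeros(len(series), dtype=bool)
        for tr in series.distinct_trs:
            idx = np.flatnonzero(series.tr == tr)
            order = idx[np.argsort(series.repeat_index[idx])]
            ref = series.images[order[0]]
            out[order[0]] = ref
            for i in order[1:]:
                shifts[i], degenerate[i] = _estimate_shift(
                    ref, series.images[i], upsample_factor, normalization=None
                )
                out[i] = _apply_shift(series.images[i], shifts[i])
        if degenerate.any():
            warnings.warn("degenerate (constant) images registered with identity")
        registered = ImageSeries(out, series.tr.copy(), series.repeat_index.copy())
        return registered, {"shifts": shifts, "degenerate": degenerate}

    if grouping == "across_tr":
        if not isinstance(series, AveragedSeries):
            raise TypeError("across_tr registration expects an AveragedSeries")
        ref_idx = int(np.argmax(series.tr))
        out = np.empty_like(series.images)
        shifts = np.zeros((len(series), 2))
        degenerate = np.zeros(len(series), dtype=bool)
        ref = series.images[ref_idx]
        for i in range(len(series)):
            if i == ref_idx:
                out[i] = ref
                continue
            shifts[i], degenerate[i] = _estimate_shift(
                ref, series.images[i], upsample_factor, normalization="phase"
            )
            out[i] = _apply_shift(series.images[i], shifts[i])
        if degenerate.any():
            warnings.warn("degenerate (constant) images registered with identity")
        registered = AveragedSeries(out, series.tr.copy())
        return registered, {"shifts": shifts, "degenerate": degenerate}

    raise ValueError(f"unknown grouping {grouping!r}")


def average_by_tr(series: ImageSeries, expected_trs=None) -> AveragedSeries:
    """Pixel-wise mean over the repeats of each TR, sorted by ascending TR."""
    trs = series.distinct_trs
    if expected_trs is not None:
        missing = sorted(set(np.round(expected_trs, 9)) - set(np.round(trs, 9)))
        if missing:
            warnings.warn(f"TR groups missing from series: {missing}; proceeding")
    if trs.size < 4:
        raise ValueError(
            f"only {trs.size} distinct TRs; at least 4 are required for a "
            "three-parameter fit"
        )
    images = np.stack([series.images[series.tr == tr].mean(axis=0) for tr in trs])
    return AveragedSeries(images, trs)


# ---------------------------------------------------------------------------
# smoothing and normalization
# ---------------------------------------------------------------------------

def smooth_reference(avg: AveragedSeries,
                     reference_tr: float = DEFAULT_REFERENCE_TR,
                     n_passes: int = 3) -> np.ndarray:
    """Three passes of the 3x3 binomial Gaussian over the reference-TR image."""
    match = np.isclose(avg.tr, reference_tr)
    if not match.any():
        raise ValueError(
            f"reference TR {reference_tr} s not present; available TRs: "
            f"{list(np.round(avg.tr, 4))}"
        )
    image = avg.images[int(np.argmax(match))]
    for _ in range(n_passes):
        image = ndimage.convolve(image, GAUSSIAN_3X3, mode="nearest")
    return image


def normalize(avg: AveragedSeries, smoothed_ref: np.ndarray,
              reference_tr: float = DEFAULT_REFERENCE_TR,
              floor_frac: float = 1e-6) -> NormalizedSeries:
    """Divide every non-reference TR image by the smoothed reference image.

    Pixels where the smoothed reference falls below ``floor_frac`` of its
    maximum (air / background) are masked out of the subsequent fit.
    """
    if smoothed_ref.shape != avg.images.shape[1:]:
        raise ValueError("smoothed reference shape does not match series")
    keep = ~np.isclose(avg.tr, reference_tr)
    if keep.all():
        raise ValueError(f"reference TR {reference_tr} s not present in series")
    mask = smoothed_ref > floor_frac * float(smoothed_ref.max())
    if not mask.any():
        raise ValueError("normalization mask is empty (all pixels below floor)")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mask, avg.images[keep] / smoothed_ref, 0.0)
    return NormalizedSeries(ratio, avg.tr[keep], mask, float(reference_tr))


# ---------------------------------------------------------------------------
# three-parameter fit
# ---------------------------------------------------------------------------

def _initial_guess(intensities: np.ndarray, trs: np.ndarray) -> tuple[float, float, float]:
    a0 = float(intensities[np.argmax(trs)])
    diff = a0 - intensities
    pos = diff > 0
    if pos.sum() >= 2:
        # log-linear: log(a0 - y) = log(-b) - c*TR
        slope, _ = np.polyfit(trs[pos], np.log(diff[pos]), 1)
        c0 = -float(slope)
        if not np.isfinite(c0) or c0 <= 0:
            c0 = 1.0 / float(np.median(trs))
    else:
        c0 = 1.0 / float(np.median(trs))
    return a0, -a0, c0


def fit_t1_pixel(intensities, trs, c_max: float = _FIT_BOUND_C_MAX_DEFAULT):
    """Nonlinear least squares for ``intensity = a + b*exp(-c*TR)`` at one pixel.

    Returns ``(a, b, c, residual_rms, converged)``; ``c`` is R1 in 1/s.
    Non-finite input or a solver failure (including ``c`` pinned at a bound)
    yields NaN parameters with ``converged=False``.
    """
    y = np.asarray(intensities, dtype=float)
    t = np.asarray(trs, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("intensities and trs must be matching 1-D arrays")
    if len(np.unique(t)) < 4:
        raise ValueError("at least 4 distinct TRs are required")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(t))):
        return np.nan, np.nan, np.nan, np.nan, False

    a0, b0, c0 = _initial_guess(y, t)
    c0 = min(max(c0, _FIT_BOUND_C_MIN * 10), c_max * 0.99)

    def residual(p):
        return p[0] + p[1] * np.exp(-p[2] * t) - y

    def jacobian(p):
        e = np.exp(-p[2] * t)
        return np.column_stack([np.ones_like(t), e, -p[1] * t * e])

    try:
        res = optimize.least_squares(
            residual, x0=[a0, b0, c0], jac=jacobian,
            bounds=([-np.inf, -np.inf, _FIT_BOUND_C_MIN], [np.inf, np.inf, c_max]),
            method="trf", xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=200,
        )
    except Exception:  # pragma: no cover - defensive
        return np.nan, np.nan, np.nan, np.nan, False

    a, b, c = res.x
    at_bound = c <= _FIT_BOUND_C_MIN * 1.01 or c >= c_max * 0.999999
    if not res.success or at_bound:
        return np.nan, np.nan, np.nan, np.nan, False
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    return float(a), float(b), float(c), rms, True


def _fit_pixels_vectorized(pix: np.ndarray, trs: np.ndarray, c_max: float,
                           max_iter: int = 200, rel_tol: float = 1e-8):
    """Batched Levenberg-Marquardt for ``a + b*exp(-c*TR)`` over many pixels.

    Same model, initialization and bounds as :func:`fit_t1_pixel`, solved
    simultaneously for all pixels (columns of ``pix``); minima agree with the
    per-pixel solver, which remains the reference implementation.
    """
    t = trs
    npx = pix.shape[1]
    finite = np.all(np.isfinite(pix), axis=0)

    # initialization (vectorized form of _initial_guess)
    a0 = pix[np.argmax(t)].copy()
    diff = a0[None, :] - pix
    c0 = np.full(npx, 1.0 / float(np.median(t)))
    with np.errstate(divide="ignore", invalid="ignore"):
        logd = np.where(diff > 0, np.log(np.where(diff > 0, diff, 1.0)), np.nan)
    npos = np.sum(diff > 0, axis=0)
    tw = np.where(np.isfinite(logd), t[:, None], 0.0)
    lw = np.where(np.isfinite(logd), logd, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tbar = tw.sum(0) / npos
        lbar = lw.sum(0) / npos
        sxx = np.sum(np.where(np.isfinite(logd), (t[:, None] - tbar) ** 2, 0.0), 0)
        sxy = np.sum(np.where(np.isfinite(logd),
                              (t[:, None] - tbar) * (logd - lbar), 0.0), 0)
        slope = sxy / sxx
    use = (npos >= 2) & np.isfinite(slope) & (slope < 0)
    c0[use] = -slope[use]
    c0 = np.clip(c0, _FIT_BOUND_C_MIN * 10, c_max * 0.99)

    params = np.stack([a0, -a0, c0], axis=1)
    params[~finite] = 1.0   # placeholder; reported as non-converged

    def residual(p):
        return p[:, 0:1] + p[:, 1:2] * np.exp(-p[:, 2:3] * t[None, :]) - pix.T

    lam = np.full(npx, 1e-3)
    r = residual(params)
    cost = np.einsum("ij,ij->i", r, r)
    active = finite.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        p = params[active]
        e = np.exp(-p[:, 2:3] * t[None, :])
        J = np.stack([np.ones_like(e), e, -p[:, 1:2] * t[None, :] * e], axis=2)
        ra = r[active]
        g = np.einsum("ijk,ij->ik", J, ra)
        H = np.einsum("ijk,ijl->ikl", J, J)
        dg = np.einsum("ikk->ik", H).copy()
        Hd = H + lam[active, None, None] * \
            (dg[:, :, None] * np.eye(3)[None] + 1e-12 * np.eye(3)[None])
        try:
            step = -np.linalg.solve(Hd, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = -np.einsum("ikl,il->ik", np.linalg.pinv(Hd), g)
        trial = p + step
        trial[:, 2] = np.clip(trial[:, 2], _FIT_BOUND_C_MIN, c_max)
        rt = trial[:, 0:1] + trial[:, 1:2] * np.exp(-trial[:, 2:3] * t[None, :]) \
            - pix.T[active]
        new_cost = np.einsum("ij,ij->i", rt, rt)
        better = new_cost <= cost[active]
        idx = np.flatnonzero(active)
        good = idx[better]
        params[good] = trial[better]
        r[good] = rt[better]
        cost[good] = new_cost[better]
        lam[good] = np.maximum(lam[good] * 0.3, 1e-12)
        lam[idx[~better]] = np.minimum(lam[idx[~better]] * 3.0, 1e8)
        # stop pixels whose accepted relative step is small
        relstep = np.max(np.abs(step) / (np.abs(p) + 1e-12), axis=1)
        done = np.zeros(npx, dtype=bool)
        done[idx[better & (relstep < rel_tol)]] = True
        active &= ~done

    a, b, c = params[:, 0], params[:, 1], params[:, 2]
    rms = np.sqrt(cost / t.size)
    interior = (c > _FIT_BOUND_C_MIN * 1.01) & (c < c_max * 0.999999)
    conv = finite & interior & np.isfinite(cost)
    a = np.where(conv, a, np.nan)
    b = np.where(conv, b, np.nan)
    c = np.where(conv, c, np.nan)
    rms = np.where(conv, rms, np.nan)
    return a, b, c, rms, conv


def fit_t1_map(norm: NormalizedSeries, c_max: float = _FIT_BOUND_C_MAX_DEFAULT,
               engine: str = "vectorized") -> R1Map:
    """Fit every unmasked pixel of the series.

    ``engine="vectorized"`` (default) runs a batched Levenberg-Marquardt
    across all pixels; ``engine="per_pixel"`` calls :func:`fit_t1_pixel`
    pixel by pixel (slower, reference path).
    """
    if not norm.mask.any():
        raise ValueError("no unmasked pixels to fit")
    shape = norm.mask.shape
    a = np.full(shape, np.nan)
    b = np.full(shape, np.nan)
    c = np.full(shape, np.nan)
    rms = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    rows, cols = np.nonzero(norm.mask)
    pix = norm.images[:, rows, cols]
    if engine == "vectorized":
        av, bv, cv, rv, kv = _fit_pixels_vectorized(pix, norm.tr, c_max)
        a[rows, cols] = av
        b[rows, cols] = bv
        c[rows, cols] = cv
        rms[rows, cols] = rv
        conv[rows, cols] = kv
    elif engine == "per_pixel":
        for k in range(rows.size):
            i, j = rows[k], cols[k]
            a[i, j], b[i, j], c[i, j], rms[i, j], conv[i, j] = fit_t1_pixel(
                pix[:, k], norm.tr, c_max=c_max
            )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    frac = conv.sum() / rows.size
    logger.info("fit_t1_map: %d/%d masked pixels converged (%.1f%%)",
                conv.sum(), rows.size, 100 * frac)
    return R1Map(a, b, c, conv, rms)


def roi_mean_r1(r1_map: R1Map, roi: RoiMask) -> tuple[float, int, float]:
    """Mean fitted R1 over the converged pixels inside a ROI.

    Returns ``(mean, n_pixels, sd)``; sd is 0 for a single pixel.
    """
    if roi.pixels.shape != r1_map.c.shape:
        raise ValueError("ROI shape does not match map")
    sel = roi.pixels & r1_map.converged
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"ROI {roi.name!r} has no converged pixels")
    values = r1_map.c[sel]
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return float(values.mean()), n, sd


def compute_r1_map(series: ImageSeries,
                   reference_tr: float = DEFAULT_REFERENCE_TR,
                   register: bool = True,
                   c_max: float = _FIT_BOUND_C_MAX_DEFAULT) -> R1Map:
    """Run the full chain: register, average, smooth, normalize, fit."""
    if register:
        series, _ = register_rigid(series, "within_tr")
    avg = average_by_tr(series)
    if register:
        avg, _ = register_rigid(avg, "across_tr")
    smoothed = smooth_reference(avg, reference_tr)
    norm = normalize(avg, smoothed, reference_tr)
    return fit_t1_map(norm, c_max=c_max)


# ---------------------------------------------------------------------------
# I/O: NIfTI series + JSON TR sidecar, ROI masks, ROI summary tables
# ---------------------------------------------------------------------------

def save_series_nifti(series: ImageSeries, path, sidecar_path=None) -> None:
    """Write a series as a (H, W, 1, n) NIfTI plus a JSON sidecar of TRs."""
    import nibabel as nib

    path = Path(path)
    data = np.transpose(series.images, (1, 2, 0))[:, :, np.newaxis, :]
    nib.save(nib.Nifti1Image(data.astype(np.float32), np.eye(4)), str(path))
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix("").with_suffix(".json")
    sidecar.write_text(json.dumps({
        "tr_seconds": series.tr.tolist(),
        "repeat_index": series.repeat_index.tolist(),
    }, indent=2))


def load_series_nifti(path, sidecar_path=None) -> ImageSeries:
    import nibabel as nib

    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix("").with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    data = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    images = np.transpose(data[:, :, 0, :], (2, 0, 1))
    return ImageSeries(images, np.asarray(meta["tr_seconds"]),
                       np.asarray(meta["repeat_index"]))


def save_r1_map_nifti(r1_map: R1Map, path) -> None:
    """Write the fitted rate map (1/s) and its convergence mask as NIfTI."""
    import nibabel as nib

    path = Path(path)
    nib.save(nib.Nifti1Image(r1_map.c.astype(np.float32), np.eye(4)), str(path))
    mask_path = path.parent / (path.name.replace(".nii", "_converged.nii"))
    nib.save(nib.Nifti1Image(r1_map.converged.astype(np.uint8), np.eye(4)),
             str(mask_path))


def load_roi_mask(path, name=None, shape=None) -> RoiMask:
    """Load a ROI as a NIfTI/PNG mask image or a CSV pixel list (row, col)."""
    path = Path(path)
    name = name or path.stem
    if path.suffix in {".nii", ".gz"}:
        import nibabel as nib
        data = np.asanyarray(nib.load(str(path)).dataobj)
        return RoiMask(name, np.squeeze(data) > 0)
    if path.suffix == ".png":
        import imageio.v3 as iio
        return RoiMask(name, np.asarray(iio.imread(path)) > 0)
    if path.suffix == ".csv":
        if shape is None:
            raise ValueError("shape is required for CSV pixel lists")
        table = pd.read_csv(path)
        mask = np.zeros(shape, dtype=bool)
        mask[table["row"].to_numpy(), table["col"].to_numpy()] = True
        return RoiMask(name, mask)
    raise ValueError(f"unsupported ROI format: {path.suffix}")


def roi_summary_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-(subject, ear, roi) summaries into the standard CSV layout."""
    return pd.DataFrame(rows, columns=["subject", "ear", "roi", "mean_r1", "n", "sd"])
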