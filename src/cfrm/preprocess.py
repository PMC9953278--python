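"""Spectral preprocessing: despiking, SNV, baseline removal, reference fitting.

The central operation is the robust normalization that fits every spectrum
to one shared reference spectrum R through the transform

    S_hat(a, P) = a * S + P,      P_j = p(x_j),  p a degree-n polynomial,

by minimizing the Huber loss of the residual ``S_hat - R`` over the scale
``a`` and the n+1 polynomial coefficients.  The quadratic/linear Huber loss
ignores large residuals, so sharp Raman peaks (which must survive
normalization) do not drag the fit: only the smooth baseline and the
overall intensity are matched to the reference.  This simultaneously
removes the laser-power scale fluctuation (a) and the fluorescence baseline
(P) that corrupt raw cell spectra.

The polynomial is evaluated on the channel coordinate mapped affinely to
[-1, 1]; raw channel indices 0..m-1 would make the system hopelessly
ill-conditioned at degree 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import minimize

from .errors import (
    AxisError,
    BoundsError,
    DegenerateInputError,
    ParameterError,
)
from .spectral_io import RamanMap, Spectrum

__all__ = [
    "SpikeMask",
    "FitConfig",
    "FitResult",
    "PreprocessResult",
    "snv",
    "huber",
    "huber_grad",
    "local_median_mad",
    "detect_cosmic_rays",
    "remove_cosmic_rays",
    "polynomial_baseline",
    "fit_to_reference",
    "average_background",
    "preprocess_map",
]

logger = logging.getLogger(__name__)

# Finite-sample calibration of the windowed MAD under Gaussian noise, keyed by
# the neighbor count k = window - 1: (E[MAD_k] for N(0,1), sqrt(1 + Var[median_k])).
# The first constant makes MAD/c_k a consistent sigma estimate at small k (the
# asymptotic 0.6745 is badly biased for k=4); the second absorbs the extra
# residual variance contributed by the window median itself.
_MAD_CALIBRATION = {
    2: (0.5640, 1.2245), 4: (0.4959, 1.1401), 6: (0.5669, 1.1022),
    8: (0.5985, 1.0809), 10: (0.6157, 1.0668), 12: (0.6266, 1.0572),
    14: (0.6344, 1.0497), 16: (0.6394, 1.0441), 18: (0.6438, 1.0398),
    20: (0.6468, 1.0359), 22: (0.6497, 1.0331), 24: (0.6518, 1.0305),
    26: (0.6536, 1.0283), 28: (0.6549, 1.0263), 30: (0.6566, 1.0248),
}


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum mean 0, sample sd 1 (n-1 denominator)."""
    y = s.intensities
    sd = float(np.std(y, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateInputError("constant spectrum has zero variance; SNV undefined")
    return s.with_intensities((y - y.mean()) / sd)


def huber(x, delta: float = 0.02):
    """Huber loss: x^2 for |x| <= delta, 2*delta*|x| - delta^2 beyond."""
    if delta <= 0:
        raise ParameterError("delta must be positive")
    ax = np.abs(x)
    return np.where(ax <= delta, np.square(x), 2.0 * delta * ax - delta * delta)


def huber_grad(x, delta: float = 0.02):
    """Derivative of :func:`huber`: 2x inside the knot, 2*delta*sign(x) outside."""
    if delta <= 0:
        raise ParameterError("delta must be positive")
    return np.where(np.abs(x) <= delta, 2.0 * x, 2.0 * delta * np.sign(x))


# ---------------------------------------------------------------------------
# cosmic-ray despiking


@dataclass(frozen=True)
class SpikeMask:
    """Set of (row, col, channel) triples flagged as cosmic-ray hits."""

    entries: tuple[tuple[int, int, int], ...]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        ent = tuple(sorted((int(r), int(c), int(t)) for r, c, t in self.entries))
        if len(set(ent)) != len(ent):
            raise ParameterError("duplicate spike entries")
        h, w, m = self.shape
        for r, c, t in ent:
            if not (0 <= r < h and 0 <= c < w and 0 <= t < m):
                raise BoundsError(f"spike entry ({r},{c},{t}) outside {self.shape}")
        object.__setattr__(self, "entries", ent)

    def __len__(self) -> int:
        return len(self.entries)

    def to_boolean(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for r, c, t in self.entries:
            out[r, c, t] = True
        return out

    @classmethod
    def from_boolean(cls, flags: np.ndarray) -> "SpikeMask":
        idx = np.argwhere(flags)
        return cls(tuple(map(tuple, idx.tolist())), tuple(flags.shape))


def local_median_mad(cube: np.ndarray, window: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel median and robust residual scale of the spectral window.

    For each channel the statistics come from the ``window - 1`` spectral
    neighbors (the center is excluded so a spike cannot mask itself): the
    median, and a MAD-based scale calibrated so that on Gaussian noise
    ``(x - median) / scale`` is a standard z-score.  Calibration divides
    the raw MAD by its finite-sample Gaussian expectation and multiplies
    by the extra residual spread the window median introduces.  The scale
    is floored at the per-spectrum median of the windowed scales (a
    handful of neighbors occasionally gives a near-zero MAD even on pure
    noise) and at a tiny absolute value.  The same floored scale defines
    "local MAD units" wherever spike amplitudes are expressed in them.
    """
    if window % 2 == 0 or window < 3:
        raise ParameterError("spectral window must be odd and >= 3")
    m = cube.shape[-1]
    if window >= m:
        raise ParameterError(f"spectral window {window} must be smaller than m={m}")
    half = window // 2
    padded = np.pad(cube, [(0, 0)] * (cube.ndim - 1) + [(half, half)], mode="reflect")
    win = sliding_window_view(padded, window, axis=-1)
    keep = [i for i in range(window) if i != half]
    neigh = win[..., keep]
    med = np.median(neigh, axis=-1)
    mad = np.median(np.abs(neigh - med[..., None]), axis=-1)
    c_k, inflation = _MAD_CALIBRATION.get(window - 1, (0.6745, 1.0))
    scale = mad * (inflation / c_k)
    floor = np.median(scale, axis=-1, keepdims=True)
    tiny = 1e-12 * max(1.0, float(np.ptp(cube))) + 1e-300
    return med, np.maximum(np.maximum(scale, floor), tiny)


def detect_cosmic_rays(
    raman_map: RamanMap, z_thresh: float = 8.0, spectral_window: int = 5
) -> SpikeMask:
    """Flag single-channel, single-pixel outliers as cosmic-ray hits.

    A channel is a candidate when its robust z-score against the local
    spectral window (median / calibrated MAD, see
    :func:`local_median_mad`) exceeds ``z_thresh``.  Candidates are
    vetoed when the same channel at any 4-connected spatial neighbor
    co-exceeds ``z_thresh / 2``: genuine Raman peaks are spatially
    coherent across neighboring pixels, cosmic rays are single-pixel
    events.
    """
    med, mad = local_median_mad(raman_map.cube, spectral_window)
    z = (raman_map.cube - med) / mad
    candidate = z > z_thresh
    hot = z > z_thresh / 2.0
    neighbor_hot = np.zeros_like(hot)
    neighbor_hot[1:] |= hot[:-1]
    neighbor_hot[:-1] |= hot[1:]
    neighbor_hot[:, 1:] |= hot[:, :-1]
    neighbor_hot[:, :-1] |= hot[:, 1:]
    return SpikeMask.from_boolean(candidate & ~neighbor_hot)


def remove_cosmic_rays(raman_map: RamanMap, mask: SpikeMask) -> RamanMap:
    """Replace flagged channels by linear interpolation from unflagged neighbors."""
    if mask.shape != raman_map.cube.shape:
        raise BoundsError(f"mask shape {mask.shape} does not match map {raman_map.cube.shape}")
    cube = raman_map.cube.copy()
    m = cube.shape[-1]
    by_pixel: dict[tuple[int, int], list[int]] = {}
    for r, c, t in mask.entries:
        by_pixel.setdefault((r, c), []).append(t)
    for (r, c), channels in by_pixel.items():
        flagged = np.zeros(m, dtype=bool)
        flagged[channels] = True
        good = np.flatnonzero(~flagged)
        if good.size == 0:
            raise DegenerateInputError(f"all channels flagged at pixel ({r}, {c})")
        bad = np.flatnonzero(flagged)
        # np.interp clamps to the nearest unflagged value at the spectrum ends
        cube[r, c, bad] = np.interp(bad, good, cube[r, c, good])
    return replace(raman_map, cube=cube)


# ---------------------------------------------------------------------------
# baseline correction (iterative modified polyfit)


def polynomial_baseline(
    s: Spectrum, order: int = 5, max_iter: int = 100, tol: float = 1e-6
) -> tuple[Spectrum, Spectrum]:
    """Iterative polynomial baseline: fit, clip to min(spectrum, fit), repeat.

    Returns ``(baseline, corrected)`` with ``corrected = s - baseline``.
    Convergence when the relative change of the fitted baseline drops
    below ``tol``.
    """
    if order < 0:
        raise ParameterError("order must be nonnegative")
    if order >= s.axis.m:
        raise ParameterError(f"order {order} must be below the channel count {s.axis.m}")
    x = np.linspace(-1.0, 1.0, s.axis.m)
    y = s.intensities.copy()
    prev = None
    base = y
    for _ in range(max_iter):
        coeffs = np.polynomial.polynomial.polyfit(x, y, order)
        base = np.polynomial.polynomial.polyval(x, coeffs)
        if prev is not None:
            denom = max(float(np.max(np.abs(base))), 1e-30)
            if float(np.max(np.abs(base - prev))) / denom < tol:
                break
        prev = base
        y = np.minimum(y, base)
    return s.with_intensities(base), s.with_intensities(s.intensities - base)


# ---------------------------------------------------------------------------
# Huber reference fitting


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the reference fit.

    n : polynomial order of the baseline term (degree-5 default).
    delta : Huber knot; with SNV-scaled spectra 0.02 is a scale-free constant.
    snv_first : apply SNV to both spectra before fitting (the default), so
        that delta keeps one meaning across cells and instruments.
    loss : 'huber' (robust, default) or 'squared' (for comparison runs).
    """

    n: int = 5
    delta: float = 0.02
    snv_first: bool = True
    max_iter: int = 300
    tol: float = 1e-13
    loss: str = "huber"

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ParameterError("polynomial order n must be >= 0")
        if self.delta <= 0:
            raise ParameterError("delta must be positive")
        if self.tol <= 0:
            raise ParameterError("tol must be positive")
        if self.loss not in ("huber", "squared"):
            raise ParameterError(f"unknown loss {self.loss!r}")


@dataclass
class FitResult:
    """Outcome of fitting one spectrum to the reference."""

    a: float
    coefficients: np.ndarray
    fitted: Spectrum
    loss: float
    converged: bool
    iterations: int
    space: str = "snv"  # coordinate space in which the fit was performed


def _design_matrix(m: int, n: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, m)
    return np.polynomial.polynomial.polyvander(x, n)


def fit_to_reference(s: Spectrum, r: Spectrum, config: FitConfig = FitConfig()) -> FitResult:
    """Fit ``a * s + P`` to the reference ``r`` under the configured loss.

    Deterministic L-BFGS-B from the start point (a=1, p=0) with analytic
    gradient; the returned objective never exceeds the start-point
    objective.  The fitted spectrum is reported in the space in which the
    optimization ran (SNV space when ``snv_first``).
    """
    if s.axis != r.axis:
        raise AxisError("spectrum and reference must share one wavenumber axis")
    ys = snv(s).intensities if config.snv_first else s.intensities
    yr = snv(r).intensities if config.snv_first else r.intensities
    v = _design_matrix(s.axis.m, config.n)
    delta = config.delta
    squared = config.loss == "squared"

    def objective(theta):
        e = theta[0] * ys + v @ theta[1:] - yr
        if squared:
            f = 0.5 * float(np.sum(e * e))
            g = e
        else:
            f = 0.5 * float(np.sum(huber(e, delta)))
            g = 0.5 * huber_grad(e, delta)
        return f, np.concatenate([[float(g @ ys)], v.T @ g])

    x0 = np.zeros(config.n + 2)
    x0[0] = 1.0
    f0, _ = objective(x0)
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": config.max_iter, "ftol": config.tol, "gtol": 1e-10},
    )
    theta, fval, converged = res.x, float(res.fun), bool(res.success)
    if fval > f0:  # descent guarantee: never return worse than the start point
        theta, fval, converged = x0, f0, False
    a = float(theta[0])
    if a <= 0:
        logger.warning("fit_to_reference: non-positive scale a=%g", a)
    coeffs = np.asarray(theta[1:], dtype=float)
    fitted = Spectrum(a * ys + v @ coeffs, s.axis)
    return FitResult(
        a=a,
        coefficients=coeffs,
        fitted=fitted,
        loss=fval,
        converged=converged,
        iterations=int(res.nit),
        space="snv" if config.snv_first else "raw",
    )


def average_background(maps: list[RamanMap], background_masks: list[np.ndarray]) -> Spectrum:
    """Channelwise mean spectrum over all masked pixels of all maps."""
    if len(maps) != len(background_masks) or not maps:
        raise ParameterError("need one mask per map and at least one map")
    axis = maps[0].axis
    total = np.zeros(axis.m)
    count = 0
    for m, mask in zip(maps, background_masks):
        if m.axis != axis:
            raise AxisError("all maps must share one wavenumber axis")
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (m.height, m.width):
            raise BoundsError("mask shape does not match map")
        total += m.cube[mask].sum(axis=0)
        count += int(mask.sum())
    if count == 0:
        raise DegenerateInputError("no background pixels selected")
    return Spectrum(total / count, axis)


# ---------------------------------------------------------------------------
# whole-map pipeline


@dataclass
class PreprocessResult:
    """Preprocessed map plus per-pixel fit metadata (row-major order)."""

    map: RamanMap
    fits: list[FitResult] = field(default_factory=list)
    spike_mask: SpikeMask | None = None

    @property
    def n_not_converged(self) -> int:
        return sum(1 for f in self.fits if not f.converged)


def preprocess_map(
    raman_map: RamanMap,
    reference: Spectrum,
    config: FitConfig = FitConfig(),
    despike: bool = True,
    z_thresh: float = 8.0,
    spectral_window: int = 5,
) -> PreprocessResult:
    """Despike, then fit every pixel spectrum to the reference.

    Returns the map of fitted spectra (in the fitting space) together with
    the per-pixel :class:`FitResult` list; non-convergent pixels are logged
    with their coordinates, never silently dropped.
    """
    m = raman_map
    spike_mask = None
    if despike:
        spike_mask = detect_cosmic_rays(m, z_thresh=z_thresh, spectral_window=spectral_window)
        m = remove_cosmic_rays(m, spike_mask)
    out = np.empty_like(m.cube)
    fits: list[FitResult] = []
    for rr in range(m.height):
        for cc in range(m.width):
            fit = fit_to_reference(Spectrum(m.cube[rr, cc], m.axis), reference, config)
            if not fit.converged:
                logger.warning("pixel (%d, %d): fit did not converge", rr, cc)
            out[rr, cc] = fit.fitted.intensities
            fits.append(fit)
    return PreprocessResult(map=replace(m, cube=out), fits=fits, spike_mask=spike_mask)
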