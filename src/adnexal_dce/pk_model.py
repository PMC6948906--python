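"""Extended Tofts tracer-kinetic model: forward simulation and fitting.

The extended Tofts model describes tissue contrast concentration as the sum
of an intravascular term and leakage into the extravascular extracellular
space (EES):

    Ct(t) = vp Cp(t - d) + Ktrans  Integral_0^t Cp(u - d) exp(-kep (t - u)) du

with ``vp`` the fractional plasma volume, ``Ktrans`` (1/min) the
plasma-to-EES volume transfer constant, ``kep`` (1/min) the efflux rate
constant, and ``d`` (delta) a bolus lag between the arterial input and the
onset of tissue enhancement.  The EES volume fraction follows as
``ve = Ktrans / kep``.

Fitting is bounded nonlinear least squares over (Ktrans, kep, vp) with the
lag selected by exhaustive search over a grid of whole-frame shifts: the
sampling interval of the dynamic series is the finest lag the data can
resolve, so delta is stepped one frame at a time and the shift minimising
the residual sum of squares wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from adnexal_dce.aif import ConcentrationCurve

__all__ = [
    "PKParams",
    "ParameterMap",
    "FitSettings",
    "forward_extended_tofts",
    "fit_curve",
    "fit_voxelwise",
    "signal_to_enhancement",
]

#: Fit status codes used in :class:`PKParams` and :class:`ParameterMap`.
FIT_OK = "ok"
FIT_ZERO = "zero-signal"
FIT_FAILED = "failed"
FIT_ABSENT = "absent"


@dataclass(frozen=True)
class PKParams:
    """Extended Tofts parameters for one curve or voxel.

    ``ktrans`` and ``kep`` are in 1/min, ``vp`` and ``ve`` are volume
    fractions, ``delta`` is the bolus lag in seconds (a whole number of
    frame intervals).  ``sse`` and ``r2`` describe fit quality; ``status``
    is one of ``"ok"``, ``"zero-signal"``, ``"failed"``.
    """

    ktrans: float
    kep: float
    vp: float
    delta: float = 0.0
    sse: float = np.nan
    r2: float = np.nan
    status: str = FIT_OK

    def __post_init__(self) -> None:
        if self.ktrans < 0 or self.kep < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0 <= self.vp <= 1:
            raise ValueError("vp must lie in [0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")

    @property
    def ve(self) -> float:
        """EES volume fraction, Ktrans/kep (0 when kep is 0)."""
        return self.ktrans / self.kep if self.kep > 0 else 0.0


@dataclass(frozen=True)
class FitSettings:
    """Bounds, initialisation and lag grid for the nonlinear fit.

    ``delay_grid`` lists candidate lags as whole-frame shifts.  On optimizer
    failure the fit is restarted from ``n_restarts`` jittered initial points
    drawn with ``restart_seed``.
    """

    ktrans_bounds: tuple[float, float] = (0.0, 5.0)
    kep_bounds: tuple[float, float] = (0.0, 50.0)
    vp_bounds: tuple[float, float] = (0.0, 1.0)
    x0: tuple[float, float, float] = (0.05, 1.0, 0.1)
    delay_grid: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    n_restarts: int = 3
    restart_seed: int = 20150301


DEFAULT_FIT_SETTINGS = FitSettings()


def _shifted_cp(cp: ConcentrationCurve, times: np.ndarray, delta: float) -> np.ndarray:
    """Cp(t - delta) on ``times``, zero before the (shifted) record starts."""
    return np.interp(times - delta, cp.times, cp.values, left=0.0)


def _trapz_weights(times: np.ndarray) -> np.ndarray:
    """Row i holds the trapezoid quadrature weights for integrating over
    [t_0, t_i] on the (possibly non-uniform) grid; depends only on the grid,
    so it is computed once per fit."""
    n = times.size
    steps = np.diff(times)
    w = np.zeros((n, n))
    for i in range(1, n):
        w[i, 0] = steps[0] / 2.0
        w[i, i] = steps[i - 1] / 2.0
        if i > 1:
            w[i, 1:i] = (steps[: i - 1] + steps[1:i]) / 2.0
    return w


def _tofts_curve(ktrans: float, kep: float, vp: float,
                 cps: np.ndarray, times: np.ndarray,
                 weights: np.ndarray | None = None) -> np.ndarray:
    """Discrete extended Tofts forward model on an arbitrary increasing grid.

    The convolution integral is evaluated by trapezoidal quadrature: with
    f_j(i) = Cp(t_j - d) exp(-kep (t_i - t_j)), the integral at t_i is the
    trapezoid sum of f over j <= i.  Rates arrive in 1/min and the grid in
    seconds, hence the /60 conversions.
    """
    kep_s = kep / 60.0
    ktrans_s = ktrans / 60.0
    if weights is None:
        weights = _trapz_weights(times)
    # E[i, j] = exp(-kep_s (t_i - t_j)) for j <= i; weights zero out j > i.
    dt_mat = times[:, None] - times[None, :]
    with np.errstate(over="ignore"):
        E = np.exp(-kep_s * np.clip(dt_mat, 0.0, None))
    conv = ((E * cps[None, :]) * weights).sum(axis=1)
    return vp * cps + ktrans_s * conv


def forward_extended_tofts(
    params: PKParams, cp: ConcentrationCurve, times: np.ndarray
) -> ConcentrationCurve:
    """Simulate the tissue concentration curve for given kinetic parameters.

    ``cp`` may be sampled on the same grid as ``times`` or a finer one; the
    lag ``params.delta`` shifts the plasma input later in time.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    cps = _shifted_cp(cp, times, params.delta)
    ct = _tofts_curve(params.ktrans, params.kep, params.vp, cps, times)
    return ConcentrationCurve(times=times, values=ct, compartment="tissue")


def _r2(ct: np.ndarray, residuals: np.ndarray) -> float:
    ss_tot = float(np.sum((ct - ct.mean()) ** 2))
    sse = float(np.sum(residuals**2))
    return 1.0 - sse / ss_tot if ss_tot > 0 else np.nan


def fit_curve(
    ct: ConcentrationCurve,
    cp: ConcentrationCurve,
    delay_grid: Sequence[int] | None = None,
    settings: FitSettings = DEFAULT_FIT_SETTINGS,
    frame_interval: float | None = None,
) -> PKParams:
    """Fit the extended Tofts model to one tissue curve.

    For every candidate lag (a whole number of frame shifts) a bounded
    least-squares problem in (Ktrans, kep, vp) is solved; the lag with the
    smallest residual sum of squares is returned.  An all-zero tissue curve
    short-circuits to zero parameters with status ``"zero-signal"``.
    """
    times = ct.times
    y = ct.values
    if frame_interval is None:
        frame_interval = float(np.median(np.diff(times)))
    if delay_grid is None:
        delay_grid = settings.delay_grid

    if not np.any(y != 0.0):
        return PKParams(0.0, 0.0, 0.0, 0.0, sse=0.0, r2=np.nan, status=FIT_ZERO)

    lb = np.array([settings.ktrans_bounds[0], settings.kep_bounds[0],
                   settings.vp_bounds[0]])
    ub = np.array([settings.ktrans_bounds[1], settings.kep_bounds[1],
                   settings.vp_bounds[1]])
    x0 = np.clip(np.asarray(settings.x0, dtype=float), lb, ub)
    rng = np.random.default_rng(settings.restart_seed)

    weights = _trapz_weights(times)
    best: tuple[float, np.ndarray, float] | None = None  # (sse, x, delta)
    for shift in delay_grid:
        delta = float(shift) * frame_interval
        cps = _shifted_cp(cp, times, delta)

        def residuals(x: np.ndarray) -> np.ndarray:
            return _tofts_curve(x[0], x[1], x[2], cps, times, weights) - y

        sol = None
        for attempt in range(settings.n_restarts + 1):
            if attempt == 0:
                start = x0
            else:
                start = np.clip(x0 * rng.uniform(0.2, 3.0, size=3), lb, ub)
            try:
                res = least_squares(residuals, start, bounds=(lb, ub),
                                    method="trf", xtol=1e-10, ftol=1e-10)
            except Exception:  # pragma: no cover - optimizer crash
                continue
            if res.success:
                sse = float(np.sum(res.fun**2))
                if sol is None or sse < sol[0]:
                    sol = (sse, res.x)
                if attempt == 0:
                    break  # converged from the default start
        if sol is None:
            continue
        if best is None or sol[0] < best[0]:
            best = (sol[0], sol[1], delta)

    if best is None:
        return PKParams(0.0, 0.0, 0.0, 0.0, sse=np.nan, r2=np.nan,
                        status=FIT_FAILED)
    sse, x, delta = best
    cps = _shifted_cp(cp, times, delta)
    resid = _tofts_curve(x[0], x[1], x[2], cps, times, weights) - y
    return PKParams(
        ktrans=float(x[0]), kep=float(x[1]), vp=float(x[2]), delta=delta,
        sse=sse, r2=_r2(y, resid), status=FIT_OK,
    )


@dataclass
class ParameterMap:
    """Voxelwise extended Tofts parameter maps on a common 3-D grid.

    ``status`` distinguishes fitted voxels from unmasked (``"absent"``) and
    failed ones; failed voxels are flagged, never silently zeroed.
    """

    shape: tuple[int, int, int]
    ktrans: np.ndarray = field(repr=False, default=None)
    kep: np.ndarray = field(repr=False, default=None)
    ve: np.ndarray = field(repr=False, default=None)
    vp: np.ndarray = field(repr=False, default=None)
    delta: np.ndarray = field(repr=False, default=None)
    sse: np.ndarray = field(repr=False, default=None)
    r2: np.ndarray = field(repr=False, default=None)
    status: np.ndarray = field(repr=False, default=None)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("ktrans", "kep", "ve", "vp", "delta", "sse", "r2"):
            if getattr(self, name) is None:
                setattr(self, name, np.full(self.shape, np.nan))
        if self.status is None:
            self.status = np.full(self.shape, FIT_ABSENT, dtype=object)
        for name in ("ktrans", "kep", "ve", "vp", "delta", "sse", "r2", "status"):
            if getattr(self, name).shape != self.shape:
                raise ValueError("all maps must share one shape")

    @property
    def ok(self) -> np.ndarray:
        """Boolean mask of successfully fitted voxels."""
        return self.status == FIT_OK


def signal_to_enhancement(signal: np.ndarray, n_baseline: int) -> np.ndarray:
    """Convert signal to relative enhancement (SI - SI0)/SI0 along the last axis.

    Under the low-dose linearity assumption relative enhancement is
    proportional to tissue concentration; the proportionality constant is
    absorbed by the AIF calibration.
    """
    si0 = np.asarray(signal, dtype=float)[..., :n_baseline].mean(axis=-1)
    if np.any(si0 <= 0):
        raise ValueError("non-positive baseline signal; cannot normalise")
    return (signal - si0[..., None]) / si0[..., None]


def fit_voxelwise(
    series: np.ndarray,
    cp: ConcentrationCurve,
    mask: np.ndarray,
    times: np.ndarray | None = None,
    n_baseline: int = 2,
    settings: FitSettings = DEFAULT_FIT_SETTINGS,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ParameterMap:
    """Fit the extended Tofts model in every masked voxel of a 4-D series.

    ``series`` is (x, y, z, t) signal intensity; each masked voxel's curve is
    converted to relative enhancement and fitted independently against the
    common plasma input ``cp``.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must be 4-D (x, y, z, t)")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != series.shape[:3]:
        raise ValueError("mask shape must match the spatial dimensions")
    if not mask.any():
        raise ValueError("mask is empty")
    if times is None:
        times = cp.times
    if series.shape[3] != times.size:
        raise ValueError("series time axis does not match the time grid")

    pmap = ParameterMap(shape=series.shape[:3], voxel_size_mm=voxel_size_mm)
    for idx in np.argwhere(mask):
        i, j, k = idx
        sig = series[i, j, k]
        try:
            enh = signal_to_enhancement(sig, n_baseline)
        except ValueError:
            pmap.status[i, j, k] = FIT_FAILED
            continue
        fit = fit_curve(
            ConcentrationCurve(times=times, values=enh, compartment="tissue"),
            cp, settings=settings,
        )
        pmap.ktrans[i, j, k] = fit.ktrans
        pmap.kep[i, j, k] = fit.kep
        pmap.ve[i, j, k] = fit.ve
        pmap.vp[i, j, k] = fit.vp
        pmap.delta[i, j, k] = fit.delta
        pmap.sse[i, j, k] = fit.sse
        pmap.r2[i, j, k] = fit.r2
        pmap.status[i, j, k] = fit.status
    return pmap
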