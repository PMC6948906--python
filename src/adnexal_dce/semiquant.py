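"""Semi-quantitative enhancement-curve descriptors.

Model-free descriptors of a signal-time curve SI(t) characterise how fast and
how strongly a lesion enhances without reference to an arterial input
function:

* ``si0`` — native (pre-injection) signal, the mean of the baseline frames;
* ``si_max`` — maximum post-injection signal;
* ``si_peak`` — maximum of the 3-point moving-average smoothed curve, a
  noise-robust peak estimate;
* ``si_end`` — signal of the final dynamic frame;
* ``si_rel`` — relative enhancement, (SI_max - SI_0)/SI_0 x 100 (%);
* ``ttp`` — time to peak, measured from the injection, in seconds;
* ``wir`` — wash-in rate, (SI_max - SI_0)/TTP;
* ``wor`` — wash-out rate, (SI_max - SI_end)/(SI_max - SI_0);
* ``iauc60`` — area under the baseline-subtracted curve over the first 60 s
  after injection (trapezoidal).

Malignant lesions typically show a fast, strong wash-in (short TTP, high
``si_rel`` and ``wir``), benign lesions a slow progressive enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = ["EnhancementCurve", "SemiQuantParams", "compute_descriptors"]


@dataclass(frozen=True)
class EnhancementCurve:
    """Signal intensity versus time for one ROI or voxel.

    ``times`` must be uniformly spaced at ``frame_interval`` seconds and at
    least one frame must precede ``injection_time``.
    """

    times: np.ndarray
    signal: np.ndarray
    injection_time: float = 10.0
    frame_interval: float = 7.6

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "signal", signal)
        if times.ndim != 1 or signal.shape != times.shape:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if times.size < 2:
            raise ValueError("curve needs at least two frames")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, self.frame_interval, rtol=1e-6, atol=1e-9):
            raise ValueError("times must be uniformly spaced at frame_interval")
        if not np.any(times < self.injection_time):
            raise ValueError("curve must contain at least one pre-injection frame")

    @property
    def n_baseline_frames(self) -> int:
        return int(np.sum(self.times < self.injection_time))

    def baseline_signal(self) -> float:
        """Mean signal over the pre-injection frames."""
        return float(self.signal[: self.n_baseline_frames].mean())


@dataclass(frozen=True)
class SemiQuantParams:
    """Descriptor set for one enhancement curve (units as described above)."""

    si0: float
    si_max: float
    si_peak: float
    si_end: float
    si_rel: float
    ttp: float
    wir: float
    wor: float
    iauc60: float
    flat: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "si0": self.si0,
            "si_max": self.si_max,
            "si_peak": self.si_peak,
            "si_end": self.si_end,
            "si_rel": self.si_rel,
            "ttp": self.ttp,
            "wir": self.wir,
            "wor": self.wor,
            "iauc60": self.iauc60,
        }


def _iauc(times: np.ndarray, signal: np.ndarray, si0: float,
          start: float, window: float) -> float:
    """Trapezoidal integral of (signal - si0) over [start, start + window].

    The curve is linearly interpolated at the window edges so the integral
    covers exactly ``window`` seconds regardless of grid alignment.
    """
    stop = min(start + window, times[-1])
    if stop <= start:
        return 0.0
    inner = times[(times > start) & (times < stop)]
    grid = np.concatenate(([start], inner, [stop]))
    vals = np.interp(grid, times, signal) - si0
    return float(np.trapezoid(vals, grid))


def compute_descriptors(curve: EnhancementCurve) -> SemiQuantParams:
    """Compute the full semi-quantitative descriptor set for one curve.

    Raises
    ------
    ValueError
        If the baseline signal is zero, which leaves the relative
        enhancement undefined.
    """
    times = curve.times
    signal = curve.signal
    si0 = curve.baseline_signal()
    if si0 == 0.0:
        raise ValueError("baseline signal is zero; relative enhancement undefined")

    post = times >= curve.injection_time
    post_signal = signal[post]
    post_times = times[post]
    if post_signal.size == 0:
        raise ValueError("curve has no post-injection frames")

    imax = int(np.argmax(post_signal))
    si_max = float(post_signal[imax])
    si_end = float(signal[-1])

    # Noise-robust peak: maximum of the 3-point moving average (edges use
    # nearest-neighbour padding, so smoothing never exceeds the raw max).
    smoothed = uniform_filter1d(signal, size=3, mode="nearest")
    si_peak = float(smoothed[post].max())

    if si_max <= si0:
        # Flat / non-enhancing curve: rates are defined as zero.
        return SemiQuantParams(
            si0=si0, si_max=si_max, si_peak=si_peak, si_end=si_end,
            si_rel=100.0 * (si_max - si0) / si0 if si_max != si0 else 0.0,
            ttp=0.0, wir=0.0, wor=0.0,
            iauc60=_iauc(times, signal, si0, curve.injection_time, 60.0),
            flat=si_max == si0,
        )

    ttp = float(post_times[imax] - curve.injection_time)
    si_rel = 100.0 * (si_max - si0) / si0
    wir = (si_max - si0) / ttp if ttp > 0 else 0.0
    wor = (si_max - si_end) / (si_max - si0)
    iauc60 = _iauc(times, signal, si0, curve.injection_time, 60.0)
    return SemiQuantParams(
        si0=si0, si_max=si_max, si_peak=si_peak, si_end=si_end,
        si_rel=si_rel, ttp=ttp, wir=wir, wor=wor, iauc60=iauc60,
    )
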