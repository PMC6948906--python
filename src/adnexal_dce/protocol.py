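"""Acquisition protocol for the dynamic series.

The dynamic T1-weighted series is acquired on a uniform time grid starting a
few seconds before the contrast bolus is injected, so that every curve carries
a pre-injection baseline from which the native signal is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and dosing of a dynamic contrast-enhanced acquisition.

    Parameters
    ----------
    frame_interval_s
        Temporal resolution of the dynamic series in seconds.
    n_frames
        Number of dynamic frames.
    pre_injection_s
        Delay between the start of the acquisition and the bolus injection,
        in seconds.  Frames acquired before this time form the baseline.
    dose_mmol_per_kg
        Contrast agent dose in mmol per kg body weight.

    The defaults describe a 7.6 s / 50-frame series beginning 10 s before a
    0.1 mmol/kg bolus, i.e. 380 s of dynamic coverage.
    """

    frame_interval_s: float = 7.6
    n_frames: int = 50
    pre_injection_s: float = 10.0
    dose_mmol_per_kg: float = 0.1

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least two dynamic frames")
        if not 0 < self.pre_injection_s:
            raise ValueError("pre_injection_s must be positive")
        if self.dose_mmol_per_kg <= 0:
            raise ValueError("dose must be positive")
        if self.n_baseline_frames < 1:
            raise ValueError("protocol must include at least one pre-injection frame")

    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def injection_time_s(self) -> float:
        """Time of the bolus injection on the scan clock."""
        return self.pre_injection_s

    @property
    def n_baseline_frames(self) -> int:
        """Number of frames acquired strictly before the injection."""
        return int(np.sum(np.arange(self.n_frames) * self.frame_interval_s
                          < self.pre_injection_s))

    @property
    def total_duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


DEFAULT_PROTOCOL = AcquisitionProtocol()
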