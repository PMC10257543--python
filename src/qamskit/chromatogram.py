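"""Core chromatogram container.

A chromatogram is a single-wavelength LC-UV trace: a strictly increasing
time axis (minutes) and a detector-response vector of equal length, plus
free-form run metadata (wavelength, injection volume, sample identifier).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = ["Chromatogram"]


@dataclass
class Chromatogram:
    """A sampled time/intensity trace.

    Parameters
    ----------
    time:
        Retention-time axis in minutes, strictly increasing, length >= 8.
    intensity:
        Detector response (arbitrary absorbance units), same length as ``time``.
    metadata:
        Run metadata, e.g. ``{"wavelength_nm": 283, "injection_volume_ul": 2.0}``.
    """

    time: np.ndarray
    intensity: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("time and intensity must be one-dimensional")
        if self.time.size != self.intensity.size:
            raise ValueError(
                f"time ({self.time.size}) and intensity ({self.intensity.size}) "
                "must have the same length"
            )
        if self.time.size < 8:
            raise ValueError(f"chromatogram too short: {self.time.size} points (need >= 8)")
        diffs = np.diff(self.time)
        bad = np.nonzero(diffs <= 0)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"time axis not strictly increasing at index {i + 1} "
                f"(t[{i}]={self.time[i]:g}, t[{i + 1}]={self.time[i + 1]:g})"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def sampling_interval(self) -> float:
        """Median spacing of the time axis, minutes."""
        return float(np.median(np.diff(self.time)))

    def with_intensity(self, intensity: np.ndarray, **extra_meta: Any) -> "Chromatogram":
        """Copy of this trace with a replaced intensity vector."""
        meta = dict(self.metadata)
        meta.update(extra_meta)
        return Chromatogram(self.time.copy(), np.asarray(intensity, dtype=float), meta)

    def scaled_time(self, factor: float) -> "Chromatogram":
        """Copy with the time axis multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("time-scale factor must be positive")
        return Chromatogram(self.time * factor, self.intensity.copy(), dict(self.metadata))
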