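"""External-standard calibration and method-validation statistics.

Calibration is ordinary least squares of peak area on standard
concentration (free intercept), with the detection and quantification
limits taken from the residual scatter in the ICH style:
LOD = 3.3 s / slope, LOQ = 10 s / slope, where s is the residual
standard deviation of the fit.

Relative standard deviations use the sample (n-1) convention throughout,
as is usual in analytical method validation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import linregress

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "fit_calibration",
    "esm_quantify",
    "recovery",
    "rsd",
    "validation_stats",
]


@dataclass
class CalibrationCurve:
    """A per-analyte straight-line calibration: area = slope x conc + intercept."""

    analyte_name: str
    slope: float
    intercept: float
    r: float
    conc_range: tuple[float, float]
    lod: float
    loq: float
    residual_sd: float = 0.0
    n_levels: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"{self.analyte_name}: calibration slope must be positive")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("correlation coefficient outside [-1, 1]")
        if self.lod > self.loq:
            raise ValueError("LOD must not exceed LOQ")

    def concentration(self, area: float) -> float:
        """Invert the line: area -> concentration (mg/mL)."""
        return (area - self.intercept) / self.slope


@dataclass
class QuantResult:
    """A quantified content with its below-LOD flag."""

    analyte_name: str
    content: float  # mg/g
    concentration: float  # mg/mL in the extract
    below_lod: bool = False
    flag: str | None = None

    def __float__(self) -> float:
        return float(self.content)


def fit_calibration(
    levels: Sequence[tuple[float, float]], analyte_name: str = ""
) -> CalibrationCurve:
    """OLS calibration from (concentration, area) pairs.

    Requires at least three distinct concentration levels.  ``r`` is the
    Pearson correlation of the fitted pairs; the residual SD uses n-2
    degrees of freedom.
    """
    pts = np.asarray(list(levels), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("levels must be (concentration, area) pairs")
    conc, area = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 3:
        raise ValueError(
            f"{analyte_name or 'calibration'}: need >= 3 distinct concentration "
            f"levels, got {np.unique(conc).size}"
        )
    fit = linregress(conc, area)
    resid = area - (fit.slope * conc + fit.intercept)
    s = float(np.sqrt(np.sum(resid**2) / (conc.size - 2)))
    if fit.slope <= 0:
        raise ValueError(f"{analyte_name or 'calibration'}: non-positive slope")
    return CalibrationCurve(
        analyte_name=analyte_name,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        conc_range=(float(conc.min()), float(conc.max())),
        lod=3.3 * s / float(fit.slope),
        loq=10.0 * s / float(fit.slope),
        residual_sd=s,
        n_levels=int(np.unique(conc).size),
    )


def esm_quantify(
    curve: CalibrationCurve,
    area: float,
    *,
    sample_mass_g: float,
    extract_volume_ml: float = 45.0,
    dilution: float = 1.0,
) -> QuantResult:
    """External-standard content (mg/g) from one peak area.

    content = ((area - intercept)/slope) x extract_volume x dilution / mass.
    A response below the curve's LOD is still quantified but flagged.
    """
    if sample_mass_g <= 0 or extract_volume_ml <= 0 or dilution <= 0:
        raise ValueError("sample mass, extract volume and dilution must be positive")
    top = curve.slope * curve.conc_range[1] + curve.intercept
    if area < 0 or (top > 0 and area > 1.2 * top):
        raise ValueError(
            f"{curve.analyte_name}: area {area:g} outside the calibrated response "
            f"range [0, {1.2 * top:g}]"
        )
    conc = curve.concentration(area)
    below = conc < curve.lod
    content = conc * extract_volume_ml * dilution / sample_mass_g
    return QuantResult(
        analyte_name=curve.analyte_name,
        content=float(content),
        concentration=float(conc),
        below_lod=bool(below),
        flag="below LOD" if below else None,
    )


def recovery(measured_added: float, true_added: float) -> float:
    """Spike recovery in percent: 100 x measured / nominal."""
    if true_added <= 0:
        raise ValueError("true added amount must be positive")
    return 100.0 * measured_added / true_added


def rsd(values: Iterable[float]) -> float:
    """Relative standard deviation in percent (sample SD, n-1 denominator)."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("RSD needs at least two replicates")
    m = x.mean()
    if m == 0:
        raise ValueError("RSD undefined for zero-mean replicates")
    return float(100.0 * x.std(ddof=1) / m)


def validation_stats(
    replicate_measurements: Iterable[float] | None = None,
    spiked_pairs: Sequence[tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Repeatability RSD and/or mean spike recovery for a validation run.

    ``spiked_pairs`` are (measured_added, true_added) tuples.
    """
    out: dict[str, float] = {}
    if replicate_measurements is not None:
        out["rsd_pct"] = rsd(replicate_measurements)
    if spiked_pairs is not None:
        recs = [recovery(m, t) for m, t in spiked_pairs]
        out["recovery_pct"] = float(np.mean(recs))
        if len(recs) >= 2:
            out["recovery_rsd_pct"] = rsd(recs)
    if not out:
        raise ValueError("provide replicate measurements and/or spiked pairs")
    return out
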