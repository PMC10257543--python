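"""Single-marker quantification (QAMS) core.

Quantitative analysis of multicomponents via a single marker replaces one
calibration standard per analyte with a single marker compound (here
naringin) plus pre-established relative correction factors (RCFs).  For
marker k and analyte m, with W = amount (or content) and A = peak area:

    f_{k/m} = (W_k * A_m) / (W_m * A_k)          relative correction factor
    W_m     = (W_k * A_m) / (f_{k/m} * A_k)      single-marker content

Peaks are located across instruments via relative retention time
rrt = t_m / t_k, which is invariant under uniform stretches of the time
axis.  Agreement between QAMS and conventional external-standard (ESM)
contents is scored by the standard method difference

    SMD = (W_QAMS - W_ESM) / W_QAMS * 100%.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibrate import CalibrationCurve, QuantResult, esm_quantify
from .peaks import Peak

__all__ = [
    "AnalytePanel",
    "RCFTable",
    "ContentTable",
    "AssignmentResult",
    "SmdReport",
    "MarkerNotFoundError",
    "AmbiguousAssignmentError",
    "compute_rcf",
    "rcf_table",
    "relative_retention",
    "assign_peaks",
    "qams_quantify",
    "smd",
    "robustness_report",
    "default_panel",
]


class MarkerNotFoundError(ValueError):
    """No candidate marker peak inside the expected retention window."""


class AmbiguousAssignmentError(ValueError):
    """Two detected peaks compete for the same analyte window."""


@dataclass
class AnalytePanel:
    """Ordered analyte roster with the marker designation and expected RRTs.

    ``expected_rrt`` must be exactly 1 for the marker and strictly
    increasing along the elution order; ``rrt_tolerance`` is fractional
    (default 3%, the empirical cross-instrument reproducibility of RRTs).
    ``marker_time_window`` is the absolute retention window (minutes) used
    to identify the marker peak before any relative matching is possible.
    """

    analytes: tuple[str, ...]
    marker: str
    expected_rrt: dict[str, float]
    rrt_tolerance: float = 0.03
    marker_time_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.analytes = tuple(self.analytes)
        if self.marker not in self.analytes:
            raise ValueError(f"marker {self.marker!r} not in the analyte list")
        missing = [a for a in self.analytes if a not in self.expected_rrt]
        if missing:
            raise ValueError(f"expected_rrt missing for: {missing}")
        if self.expected_rrt[self.marker] != 1.0:
            raise ValueError("the marker's expected relative retention time must be 1")
        rrts = [self.expected_rrt[a] for a in self.analytes]
        if any(b <= a for a, b in zip(rrts[:-1], rrts[1:])):
            raise ValueError("expected_rrt must be strictly increasing in elution order")
        if not 0 < self.rrt_tolerance < 1:
            raise ValueError("rrt_tolerance must be a fraction in (0, 1)")


def default_panel(rrt_tolerance: float = 0.03) -> AnalytePanel:
    """The ten-flavonoid panel matching the simulator's default layout."""
    from .simulate import ANALYTES, DEFAULT_RETENTION_TIMES, MARKER

    t_marker = DEFAULT_RETENTION_TIMES[MARKER]
    return AnalytePanel(
        analytes=ANALYTES,
        marker=MARKER,
        expected_rrt={a: DEFAULT_RETENTION_TIMES[a] / t_marker for a in ANALYTES},
        rrt_tolerance=rrt_tolerance,
        marker_time_window=(t_marker - 1.5, t_marker + 1.5),
    )


def compute_rcf(
    marker_conc: float, marker_area: float, analyte_conc: float, analyte_area: float
) -> float:
    """Relative correction factor f_{k/m} = (W_k A_m) / (W_m A_k).

    k is the marker, m the analyte; all four inputs must be positive.
    The marker against itself gives exactly 1.
    """
    for name, v in (
        ("marker_conc", marker_conc),
        ("marker_area", marker_area),
        ("analyte_conc", analyte_conc),
        ("analyte_area", analyte_area),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v!r}")
    return (marker_conc * analyte_area) / (analyte_conc * marker_area)


def _mean_rsd(values: np.ndarray) -> tuple[float, float]:
    m = float(values.mean())
    s = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return m, (100.0 * s / m if m != 0 else float("nan"))


@dataclass
class RCFTable:
    """Per-analyte RCFs across injection volumes, with mean and RSD.

    The marker row is identically 1.000 with RSD 0.00.  Analytes whose
    peak was missing in some run appear in ``incomplete`` with NaN cells.
    """

    values: pd.DataFrame  # analytes x condition labels
    mean_f: pd.Series
    rsd_pct: pd.Series
    marker: str
    incomplete: set[str] = field(default_factory=set)

    @property
    def analytes(self) -> list[str]:
        return list(self.values.index)

    @classmethod
    def from_f_values(
        cls, f_values: Mapping[str, Sequence[float]] | pd.DataFrame, marker: str
    ) -> "RCFTable":
        """Aggregate pre-computed f values (arithmetic mean, n-1 RSD)."""
        df = pd.DataFrame(f_values).T if not isinstance(f_values, pd.DataFrame) else f_values.copy()
        if (df.to_numpy(dtype=float) <= 0).any():
            raise ValueError("all relative correction factors must be positive")
        means, rsds = {}, {}
        for a in df.index:
            means[a], rsds[a] = _mean_rsd(df.loc[a].to_numpy(dtype=float))
        if marker in df.index:
            means[marker], rsds[marker] = 1.0, 0.0
        return cls(
            values=df,
            mean_f=pd.Series(means, name="mean_f").loc[df.index],
            rsd_pct=pd.Series(rsds, name="rsd_pct").loc[df.index],
            marker=marker,
        )

    def to_frame(self, decimals: int = 3) -> pd.DataFrame:
        """Export layout: one row per analyte, volume columns, mean and RSD."""
        out = self.values.round(decimals).copy()
        out["mean"] = self.mean_f.round(decimals)
        out["rsd_pct"] = self.rsd_pct.round(2)
        return out


def rcf_table(
    standard_runs: Mapping[str, Mapping[str, tuple[float, float]]],
    marker: str,
) -> RCFTable:
    """Build an RCF table from standard runs at several injection volumes.

    ``standard_runs`` maps a run label (e.g. "1 uL") to a per-analyte
    ``(concentration, area)`` mapping; the marker must be present in every
    run.  Requires at least two runs.  Analytes missing from some run get
    NaN there and are flagged incomplete (their mean uses the runs where
    they were seen).
    """
    if len(standard_runs) < 2:
        raise ValueError("need at least two standard runs (injection volumes)")
    labels = list(standard_runs)
    analytes: list[str] = []
    for run in standard_runs.values():
        if marker not in run:
            raise ValueError(f"marker {marker!r} missing from a standard run")
        for a in run:
            if a not in analytes:
                analytes.append(a)
    values = pd.DataFrame(index=analytes, columns=labels, dtype=float)
    incomplete: set[str] = set()
    for label, run in standard_runs.items():
        wk, ak = run[marker]
        for a in analytes:
            if a not in run:
                incomplete.add(a)
                continue
            wm, am = run[a]
            values.loc[a, label] = compute_rcf(wk, ak, wm, am)
    means, rsds = {}, {}
    for a in analytes:
        row = values.loc[a].dropna().to_numpy(dtype=float)
        if row.size == 0:
            means[a], rsds[a] = float("nan"), float("nan")
            continue
        means[a], rsds[a] = _mean_rsd(row)
    means[marker], rsds[marker] = 1.0, 0.0
    values.loc[marker] = 1.0
    return RCFTable(
        values=values,
        mean_f=pd.Series(means, name="mean_f").loc[analytes],
        rsd_pct=pd.Series(rsds, name="rsd_pct").loc[analytes],
        marker=marker,
        incomplete=incomplete,
    )


def relative_retention(marker_time: float, analyte_time: float) -> float:
    """Relative retention time t_m / t_k; the marker itself maps to 1."""
    if marker_time <= 0:
        raise ValueError("marker retention time must be positive")
    return analyte_time / marker_time


@dataclass
class AssignmentResult:
    """Outcome of relative-retention-time peak assignment."""

    assigned: dict[str, Peak]  # analyte -> annotated peak, panel order
    absent: list[str]
    marker_peak: Peak

    def peak(self, analyte: str) -> Peak | None:
        return self.assigned.get(analyte)


def _find_marker_peak(peaks: Sequence[Peak], panel: AnalytePanel) -> Peak:
    if panel.marker_time_window is None:
        raise ValueError(
            "panel.marker_time_window must be set to identify the marker peak"
        )
    lo, hi = panel.marker_time_window
    candidates = [p for p in peaks if lo <= p.apex_time <= hi]
    if not candidates:
        raise MarkerNotFoundError(
            f"no peak found for marker {panel.marker!r} in window "
            f"[{lo:g}, {hi:g}] min among {len(peaks)} detected peaks"
        )
    return max(candidates, key=lambda p: p.area)


def assign_peaks(peaks: Sequence[Peak], panel: AnalytePanel) -> AssignmentResult:
    """Match detected peaks to panel analytes by relative retention time.

    The marker is the largest-area peak inside the panel's absolute marker
    window; every other analyte is matched to the peak whose RRT lies
    within ``rrt_tolerance`` (fractional) of its expected RRT.  Two peaks
    inside one window, or one peak claimed by two analytes, raise
    :class:`AmbiguousAssignmentError`; unmatched analytes are reported
    absent.  The assignment is invariant under any uniform positive
    rescaling of the time axis.
    """
    marker_peak = _find_marker_peak(peaks, panel)
    tk = marker_peak.apex_time
    assigned: dict[str, Peak] = {}
    absent: list[str] = []
    used: dict[int, str] = {}
    for analyte in panel.analytes:
        if analyte == panel.marker:
            assigned[analyte] = marker_peak.named(analyte)
            used[id(marker_peak)] = analyte
            continue
        expected = panel.expected_rrt[analyte]
        cands = [
            p
            for p in peaks
            if abs(relative_retention(tk, p.apex_time) / expected - 1.0)
            <= panel.rrt_tolerance
        ]
        if not cands:
            absent.append(analyte)
            continue
        if len(cands) > 1:
            times = ", ".join(f"{p.apex_time:.3f} min" for p in cands)
            raise AmbiguousAssignmentError(
                f"{analyte!r}: {len(cands)} peaks inside the RRT window ({times})"
            )
        peak = cands[0]
        if id(peak) in used:
            raise AmbiguousAssignmentError(
                f"peak at {peak.apex_time:.3f} min matches both "
                f"{used[id(peak)]!r} and {analyte!r}"
            )
        used[id(peak)] = analyte
        assigned[analyte] = peak.named(analyte)
    return AssignmentResult(assigned=assigned, absent=absent, marker_peak=marker_peak)


@dataclass
class ContentTable:
    """Per-sample x per-analyte contents (mg/g) under one method."""

    data: pd.DataFrame
    method: str  # "ESM" | "QAMS"

    def __post_init__(self) -> None:
        if self.method not in ("ESM", "QAMS"):
            raise ValueError("method must be 'ESM' or 'QAMS'")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("contents must be non-negative")


def qams_quantify(
    marker_curve: CalibrationCurve,
    sample_peaks: Mapping[str, Peak] | AssignmentResult,
    rcf: RCFTable,
    *,
    sample_mass_g: float,
    extract_volume_ml: float = 45.0,
    dilution: float = 1.0,
    analytes: Sequence[str] | None = None,
) -> tuple[pd.Series, dict[str, str]]:
    """One sample's contents by the single-marker method.

    The marker's content comes from its own external-standard calibration
    (so the marker's QAMS value is identical to its ESM value); every
    other analyte uses W_m = (W_k A_m)/(f_{k/m} A_k) with its mean RCF.
    Returns a contents Series (mg/g) plus a flags dict; absent analytes
    get content 0 and flag "not detected".
    """
    peaks = (
        sample_peaks.assigned if isinstance(sample_peaks, AssignmentResult) else dict(sample_peaks)
    )
    marker = rcf.marker
    if marker not in peaks or peaks[marker] is None:
        raise ValueError(f"marker peak {marker!r} absent from sample")
    wanted = list(analytes) if analytes is not None else rcf.analytes
    marker_peak = peaks[marker]
    marker_quant: QuantResult = esm_quantify(
        marker_curve,
        marker_peak.area,
        sample_mass_g=sample_mass_g,
        extract_volume_ml=extract_volume_ml,
        dilution=dilution,
    )
    wk, ak = marker_quant.content, marker_peak.area
    contents: dict[str, float] = {}
    flags: dict[str, str] = {}
    for a in wanted:
        if a == marker:
            contents[a] = wk
            if marker_quant.flag:
                flags[a] = marker_quant.flag
            continue
        f = float(rcf.mean_f.get(a, np.nan))
        if not np.isfinite(f):
            raise ValueError(f"RCF table incomplete for analyte {a!r}")
        p = peaks.get(a)
        if p is None:
            contents[a] = 0.0
            flags[a] = "not detected"
            continue
        contents[a] = wk * p.area / (f * ak)
    return pd.Series(contents, name="QAMS"), flags


@dataclass
class SmdReport:
    """Signed per-cell standard method differences plus |SMD| summary."""

    per_cell: pd.DataFrame  # %, signed; NaN where a pair is unavailable
    summary: dict[str, float]  # min_abs / max_abs / mean_abs over evaluated cells
    n_cells: int

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        return self.per_cell.round(decimals)


def smd(
    content_esm: ContentTable | pd.DataFrame, content_qams: ContentTable | pd.DataFrame
) -> SmdReport:
    """Standard method difference, SMD = (W_QAMS - W_ESM)/W_QAMS x 100%.

    Tables must share rows and columns exactly.  Cells where both methods
    report 0 are defined as SMD 0; cells where either value is missing
    (NaN) are excluded from the summary.
    """
    esm = content_esm.data if isinstance(content_esm, ContentTable) else content_esm
    qams = content_qams.data if isinstance(content_qams, ContentTable) else content_qams
    if list(esm.index) != list(qams.index) or list(esm.columns) != list(qams.columns):
        raise ValueError("ESM and QAMS tables must share identical rows and columns")
    e = esm.to_numpy(dtype=float)
    q = qams.to_numpy(dtype=float)
    out = np.full_like(q, np.nan)
    both_zero = (e == 0) & (q == 0)
    valid = np.isfinite(e) & np.isfinite(q) & (q > 0)
    out[valid] = (q[valid] - e[valid]) / q[valid] * 100.0
    out[both_zero] = 0.0
    bad = np.isfinite(e) & np.isfinite(q) & (q <= 0) & ~both_zero
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"SMD undefined: QAMS content is 0 but ESM is {e[i, j]:g} "
            f"at ({esm.index[i]!r}, {esm.columns[j]!r})"
        )
    per_cell = pd.DataFrame(out, index=esm.index, columns=esm.columns)
    finite = np.abs(out[np.isfinite(out)])
    summary = {
        "min_abs": float(finite.min()) if finite.size else float("nan"),
        "max_abs": float(finite.max()) if finite.size else float("nan"),
        "mean_abs": float(finite.mean()) if finite.size else float("nan"),
    }
    return SmdReport(per_cell=per_cell, summary=summary, n_cells=int(finite.size))


def robustness_report(
    rcf_tables: Mapping[str, RCFTable], threshold: float = 3.0
) -> pd.DataFrame:
    """RSD of mean RCFs across labelled conditions (instruments, columns...).

    Returns one row per analyte with the across-condition mean, RSD (%)
    and a flag for analytes whose RSD exceeds ``threshold`` percent.
    """
    if len(rcf_tables) < 2:
        raise ValueError("need at least two condition labels")
    means = pd.DataFrame({label: t.mean_f for label, t in rcf_tables.items()})
    rows = []
    for a in means.index:
        vals = means.loc[a].dropna().to_numpy(dtype=float)
        m, r = _mean_rsd(vals)
        rows.append({"analyte": a, "mean_f": m, "rsd_pct": r, "flagged": r > threshold})
    out = pd.DataFrame(rows).set_index("analyte")
    if out["flagged"].any():
        warnings.warn(
            "RCF robustness exceeded the threshold for: "
            + ", ".join(out.index[out["flagged"]]),
            stacklevel=2,
        )
    return out
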