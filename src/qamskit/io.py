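"""CSV readers and writers for chromatograms, peak lists and content tables.

Chromatograms travel as two-column CSV (``time_min,intensity``); content
tables as CSV with a ``sample`` column, an optional ``method`` column
(ESM/QAMS) and one column per analyte.  Every writer's output re-parses
through the matching reader.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chromatogram import Chromatogram
from .peaks import Peak
from .qams import AnalytePanel, ContentTable

__all__ = [
    "read_chromatogram",
    "write_chromatogram",
    "read_peaks",
    "write_peaks",
    "read_content_table",
    "write_content_table",
    "write_manifest",
]

CHROM_COLUMNS = ("time_min", "intensity")


def read_chromatogram(path: str | Path) -> Chromatogram:
    """Read a two-column time/intensity CSV into a validated trace.

    Malformed (non-numeric) rows and a non-monotone time axis are rejected
    with the 1-based file line number of the first offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_min,intensity)")
    cols = list(df.columns[:2])
    t = pd.to_numeric(df[cols[0]], errors="coerce")
    y = pd.to_numeric(df[cols[1]], errors="coerce")
    bad = t.isna() | y.isna()
    if bad.any():
        lines = [str(i + 2) for i in np.nonzero(bad.to_numpy())[0][:5]]  # +2: header, 1-based
        raise ValueError(f"{path}: non-numeric rows at line(s) {', '.join(lines)}")
    if len(df) < 8:
        raise ValueError(f"{path}: only {len(df)} data rows (need >= 8)")
    tv = t.to_numpy(dtype=float)
    non_mono = np.nonzero(np.diff(tv) <= 0)[0]
    if non_mono.size:
        raise ValueError(
            f"{path}: time axis not strictly increasing at line {int(non_mono[0]) + 3}"
        )
    return Chromatogram(tv, y.to_numpy(dtype=float), metadata={"source": str(path)})


def write_chromatogram(chromatogram: Chromatogram, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {CHROM_COLUMNS[0]: chromatogram.time, CHROM_COLUMNS[1]: chromatogram.intensity}
    )
    # 17 significant digits + round-trip parsing make write->read lossless
    df.to_csv(path, index=False, float_format="%.17g")


def write_manifest(manifest, path: str | Path) -> None:
    """Ground-truth sidecar in a simple ``key = value`` text format."""
    lines = [f"seed = {manifest.seed}", f"injection_volume_ul = {manifest.injection_volume:g}"]
    for e in manifest.entries:
        lines.append(
            f"peak.{e.analyte_name} = rt:{e.retention_time:.6g} "
            f"area:{e.area:.10g} apex:{e.apex_time:.6g} height:{e.height:.10g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    rows = [
        {
            "analyte": p.analyte_name or "",
            "apex_time": p.apex_time,
            "area": p.area,
            "height": p.height,
            "left_bound": p.left_bound,
            "right_bound": p.right_bound,
        }
        for p in peaks
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_peaks(path: str | Path) -> list[Peak]:
    df = pd.read_csv(path)
    return [
        Peak(
            apex_time=float(r.apex_time),
            area=float(r.area),
            height=float(r.height),
            left_bound=float(r.left_bound),
            right_bound=float(r.right_bound),
            analyte_name=(str(r.analyte) if isinstance(r.analyte, str) and r.analyte else None),
        )
        for r in df.itertuples()
    ]


def read_content_table(
    path: str | Path, panel: AnalytePanel | None = None
) -> dict[str, ContentTable] | ContentTable:
    """Read a content-table CSV (mg/g).

    With a ``method`` column the file may carry both ESM and QAMS blocks
    and a dict keyed by method is returned; otherwise a single table.
    Analyte columns not in ``panel`` (when given) raise a warning but are
    retained.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty content table")
    if "sample" not in df.columns:
        raise ValueError(f"{path}: missing 'sample' column")
    if panel is not None:
        unknown = [
            c for c in df.columns if c not in ("sample", "method") and c not in panel.analytes
        ]
        if unknown:
            warnings.warn(f"{path}: unknown analyte column(s) {unknown}, retained")
    if "method" in df.columns:
        out: dict[str, ContentTable] = {}
        for method, block in df.groupby("method"):
            data = block.drop(columns=["method"]).set_index("sample")
            out[str(method)] = ContentTable(data=data.astype(float), method=str(method))
        return out
    return ContentTable(data=df.set_index("sample").astype(float), method="ESM")


def write_content_table(
    tables: ContentTable | Sequence[ContentTable], path: str | Path, decimals: int = 2
) -> None:
    """Write one or several method blocks to a single CSV (2-decimal export)."""
    if isinstance(tables, ContentTable):
        tables = [tables]
    blocks = []
    for t in tables:
        block = t.data.round(decimals).reset_index(names="sample")
        block.insert(1, "method", t.method)
        blocks.append(block)
    pd.concat(blocks, ignore_index=True).to_csv(
        path, index=False, float_format=f"%.{decimals}f"
    )
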