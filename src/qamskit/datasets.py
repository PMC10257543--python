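"""Packaged reference tables for the ten-flavonoid panel.

Two small CSVs ship with the package:

* ``rcf_reference.csv`` — marker-relative correction factors of the nine
  non-marker flavonoids (marker: naringin) measured at five injection
  volumes (1-3 uL), with the published mean and RSD per analyte.
* ``content_reference.csv`` — contents (mg/g) of the ten flavonoids in 20
  fermented samples determined by both the external-standard method (ESM)
  and the single-marker method (QAMS).  The marker naringin is
  single-valued (its QAMS value is by construction its ESM value) and is
  stored only under ESM.

Values are as printed (3 decimals for RCFs, 2 for contents), which limits
the precision of anything recomputed from them.
"""
from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .qams import ContentTable

__all__ = ["load_rcf_reference", "load_content_reference", "RCF_VOLUME_COLUMNS"]

RCF_VOLUME_COLUMNS = ["vol_1.0", "vol_1.5", "vol_2.0", "vol_2.5", "vol_3.0"]


def _data_path(name: str):
    return files("qamskit.data").joinpath(name)


def load_rcf_reference() -> pd.DataFrame:
    """Reference RCF table: per-volume f values plus printed mean/RSD."""
    with _data_path("rcf_reference.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return df.set_index("analyte")


def load_content_reference() -> dict[str, ContentTable]:
    """Reference ESM/QAMS content tables (20 samples x 10 analytes).

    Returns ``{"ESM": ..., "QAMS": ...}``; the QAMS table's naringin
    column is NaN (marker quantified only by its own calibration).
    """
    with _data_path("content_reference.csv").open("r") as fh:
        df = pd.read_csv(fh)
    out: dict[str, ContentTable] = {}
    for method, block in df.groupby("method"):
        data = block.drop(columns=["method"]).set_index("sample")
        out[str(method)] = ContentTable(data=data.astype(float), method=str(method))
    return out
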