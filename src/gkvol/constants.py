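"""Published correction-factor constants shipped as package data.

Provides the literature volume-averaging correction factors and clin/msr
ratios for Gamma Knife Perfexion fields, and the IAEA TRS-483 field output
correction factors k_Q, as pandas DataFrames indexed by detector name with
one column per field size (16/8/4 mm).  Cells the source tabulates as
N.A. are NaN.  ``inconsistent_cells`` lists published ratio/k cells that
do not reproduce from the printed 3-decimal inputs (the source evidently
chained unrounded intermediates); arithmetic cross-checks skip them.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "load_published_corrections",
    "published_table",
    "inconsistent_cells",
    "FIELD_SIZES_MM",
    "MSR_FIELD_MM",
]

FIELD_SIZES_MM = (16, 8, 4)
MSR_FIELD_MM = 16


@lru_cache(maxsize=1)
def load_published_corrections() -> dict:
    text = resources.files("gkvol.data").joinpath(
        "published_corrections.yaml").read_text()
    return yaml.safe_load(text)


def published_table(which: str) -> pd.DataFrame:
    """One published table as a DataFrame: ``which`` in
    {'kvol', 'ratio', 'kq', 'k'}; columns are field sizes in mm."""
    raw = load_published_corrections()
    if which not in ("kvol", "ratio", "kq", "k"):
        raise ValueError(f"unknown table {which!r}")
    fields = raw["fields_mm"]
    rows = {name: [np.nan if v is None else float(v) for v in vals]
            for name, vals in raw[which].items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=fields)
    df.index.name = "detector"
    return df


def inconsistent_cells(which: str) -> set[tuple[str, int]]:
    """(detector, field_mm) cells excluded from table-arithmetic checks."""
    raw = load_published_corrections()
    cells = raw.get("inconsistent_cells", {}).get(which, [])
    return {(name, int(f)) for name, f in cells}
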