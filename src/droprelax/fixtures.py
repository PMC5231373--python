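"""Packaged reference data: the published KWW fit table.

The 30-row table of stretched-exponential parameters (a, b, lambda_c,
beta) and R^2 for 5 droplets x 3 geometric magnitudes x 2 processes is
shipped as a CSV so the statistical layer can be exercised without any
micrographs.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

_TABLE1_SHA256 = "e2f83fbc341464bfaba929784b6c7857ccb27c2f0fb23e47f8db85f1830b8852"

__all__ = ["load_table1"]


def load_table1() -> pd.DataFrame:
    """Load the packaged KWW parameter table as a 30-row factor table.

    Columns: magnitude (area|ar|major), droplet (1..5), process
    (elongation|recovery), a, b, lambda_c, beta, r2.  The file's SHA-256
    is verified on every load.
    """
    ref = resources.files("droprelax").joinpath("data/table1.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise RuntimeError(f"fixture corruption: table1.csv sha256 {digest}")
    with ref.open("r") as fh:
        df = pd.read_csv(fh)
    if len(df) != 30:
        raise RuntimeError("table1 fixture must have 30 rows (5 x 3 x 2)")
    df["droplet"] = df["droplet"].astype(int)
    return df
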