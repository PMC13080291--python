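"""Packaged fixtures of the published summary tables.

Two tables are shipped as plain CSV, checksummed so silent edits are
caught at load time:

``table2_cluster1``
    Three-way age x sex x race/ethnicity counts for the full sample
    (N=1103) and Cluster 1 (n=272), with the published O/E percentage,
    the published overrepresentation marker, and an ``erratum`` flag on
    the one cell whose printed O/E contradicts its own printed counts.

``table4_summary``
    Per-cluster variable counts and percentages for the five clusters and
    the supplemental gender cluster; ``erratum`` names the column(s) whose
    printed count and percentage disagree.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

TABLE2_N = 1103
TABLE2_CLUSTER_SIZE = 272

CLUSTER_SIZES = {"all": 1103, "c1": 272, "c2": 223, "c3": 302,
                 "c4": 57, "c5": 249, "supp": 8}

_FIXTURES = ("table2_cluster1", "table4_summary")


def _data_dir():
    return resources.files("personakit") / "data"


def _read_checked(name: str) -> pd.DataFrame:
    data = (_data_dir() / f"{name}.csv").read_bytes()
    sums = json.loads((_data_dir() / "CHECKSUMS.json").read_text())
    digest = hashlib.sha256(data).hexdigest()
    if digest != sums[f"{name}.csv"]:
        raise RuntimeError(f"fixture {name} failed its checksum")
    from io import BytesIO
    return pd.read_csv(BytesIO(data), keep_default_na=False, na_values=[])


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table by name; raises KeyError if unknown."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {_FIXTURES}")
    return _read_checked(name)


def table2_counts(include_margin: bool = False) -> pd.DataFrame:
    """Cluster 1 contingency counts (race margin rows excluded by default)."""
    t = load_fixture("table2_cluster1")
    if not include_margin:
        t = t[t["race_ethnicity"] != "All"].reset_index(drop=True)
    return t
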