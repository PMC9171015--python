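"""Bundled example endpoint tables from a DES exposure screen.

Three group x category contingency tables from a diethylstilbestrol (DES)
dose–response screen on bovine oocytes/embryos (groups: untreated control,
DMSO vehicle, and DES at 1e-9, 1e-7, 1e-5 M):

* ``nuclear_maturation`` — MII vs abnormal meiotic status after maturation
  with DES exposure during IVM;
* ``cleavage_ivm_exposure`` — Day-5 cleavage categories (uncleaved, <=8-cell,
  >8-cell) for embryos from DES-exposed oocytes;
* ``cleavage_ivc_exposure`` — the same categories for embryos exposed to DES
  during the 8 days of culture.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import ParameterError

_DATASETS = {
    "nuclear_maturation": "nuclear_maturation_counts.csv",
    "cleavage_ivm_exposure": "cleavage_ivm_exposure_counts.csv",
    "cleavage_ivc_exposure": "cleavage_ivc_exposure_counts.csv",
}


def available_datasets() -> list[str]:
    return sorted(_DATASETS)


def load_counts(name: str) -> pd.DataFrame:
    """Load a bundled contingency table as a group x category count matrix."""
    if name not in _DATASETS:
        raise ParameterError(f"unknown dataset {name!r}; have {available_datasets()}")
    ref = resources.files("cocscreen.data").joinpath(_DATASETS[name])
    with resources.as_file(ref) as path:
        long = pd.read_csv(path)
    wide = long.pivot(index="group", columns="category", values="count")
    # preserve file row order for groups and categories
    wide = wide.loc[long["group"].unique(), long["category"].unique()]
    wide.index.name = None
    wide.columns.name = None
    return wide.astype(int)
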