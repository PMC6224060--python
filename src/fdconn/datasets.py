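"""Access to the packaged reference tables.

The package ships the small summary tables printed in the reference study
(cohort composition, emerging-link frequencies and intensities, centrality
indices, merged grouping scheme, published p-values) together with the
94-node Harvard-Oxford atlas table.  See ``fdconn/data/README.md`` for the
provenance of each file and the one documented typo correction.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

_FIXTURES = {
    "atlas": ("atlas.tsv", "\t"),
    "table1": ("table1.csv", ","),
    "table3_male": ("table3_male.csv", ","),
    "table3_female": ("table3_female.csv", ","),
    "table4_male": ("table4_male.csv", ","),
    "table5_female": ("table5_female.csv", ","),
    "table6_male": ("table6_male.csv", ","),
    "table6_female": ("table6_female.csv", ","),
    "table9": ("table9.csv", ","),
    "table10": ("table10.csv", ","),
    "table11": ("table11.csv", ","),
}


def available_fixtures() -> list[str]:
    """Names accepted by :func:`load_fixture`."""
    return sorted(_FIXTURES)


@lru_cache(maxsize=None)
def _read_fixture(name: str) -> pd.DataFrame:
    fname, sep = _FIXTURES[name]
    ref = resources.files("fdconn.data").joinpath(fname)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep=sep)


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged reference table as a DataFrame (cached read).

    Raises
    ------
    KeyError
        If ``name`` is unknown; the message lists the available names.
    """
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
        )
    return _read_fixture(name).copy()


def link_set(table: pd.DataFrame) -> set[tuple[int, int]]:
    """The set of (i, j) node pairs (i < j) in a link-frequency table."""
    return {
        (int(min(i, j)), int(max(i, j)))
        for i, j in table[["node_i", "node_j"]].itertuples(index=False)
    }
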