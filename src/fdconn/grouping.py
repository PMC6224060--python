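"""Age/sex grouping, group averaging, second threshold, emerging links.

Subjects are split by sex into 14 five-year-wide age groups (the packaged
composition table); group FD-weight matrices are the arithmetic means of
their members.  A second, group-level threshold keeps only links whose mean
weight reaches half the centre of the top-intensity bin, and the links
surviving in any group form the "emerging link" table with per-group
intensities and a frequency count.

For the statistical comparison the 14 groups are pairwise merged into 7
wider classes (the merged scheme table) to raise per-group sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .cohort import SEXES, SubjectRecord
from .datasets import load_fixture
from .weights import FDWeightMatrix


@dataclass(frozen=True)
class AgeBand:
    label: str
    age_lo: int
    age_hi: int


@dataclass(frozen=True)
class GroupScheme:
    """Ordered, non-overlapping age bands applied separately per sex."""

    name: str
    bands: tuple[AgeBand, ...]

    def band_for(self, age: int) -> AgeBand:
        for band in self.bands:
            if band.age_lo <= age <= band.age_hi:
                return band
        raise ValueError(f"age {age} outside scheme {self.name!r}")

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]


@lru_cache(maxsize=1)
def scheme_14() -> GroupScheme:
    """The 14-band scheme from the packaged cohort composition table."""
    t = load_fixture("table1")
    bands = tuple(
        AgeBand(f"{r.age_lo}-{r.age_hi}", int(r.age_lo), int(r.age_hi))
        for r in t.itertuples(index=False)
    )
    return GroupScheme("scheme14", bands)


@lru_cache(maxsize=1)
def scheme_7() -> GroupScheme:
    """The merged 7-band scheme (each band the union of two original bands)."""
    t = load_fixture("table9")
    bands = tuple(
        AgeBand(str(r.label), int(r.age_lo), int(r.age_hi))
        for r in t.itertuples(index=False)
    )
    return GroupScheme("scheme7", bands)


def assign_groups(
    cohort: list[SubjectRecord], scheme: GroupScheme
) -> dict[tuple[str, str], list[SubjectRecord]]:
    """Map (sex, band label) -> member subjects; every subject lands once.

    Empty groups are present (and flagged with a warning); ages outside the
    scheme raise, listing the offending subjects.
    """
    out: dict[tuple[str, str], list[SubjectRecord]] = {
        (sex, label): [] for sex in SEXES for label in scheme.labels
    }
    bad = []
    for s in cohort:
        try:
            band = scheme.band_for(s.age)
        except ValueError:
            bad.append(s.subject_id)
            continue
        out[(s.sex, band.label)].append(s)
    if bad:
        raise ValueError(f"ages outside scheme {scheme.name!r} for subjects: {bad}")
    empty = [key for key, members in out.items() if not members]
    if empty:
        warnings.warn(f"empty groups: {empty}", stacklevel=2)
    return out


@dataclass
class GroupMatrix:
    """Mean FD-weight matrix of one (sex, age band) group."""

    Wbar: np.ndarray
    member_count: int
    group_label: str


def average_group(
    members: list[FDWeightMatrix | np.ndarray], group_label: str = ""
) -> GroupMatrix:
    """Elementwise mean of the members' weight matrices."""
    if not members:
        raise ValueError(f"cannot average empty group {group_label!r}")
    mats = [m.W if isinstance(m, FDWeightMatrix) else np.asarray(m) for m in members]
    return GroupMatrix(np.mean(mats, axis=0), len(mats), group_label)


@dataclass
class SecondThresholdReport:
    """Second-threshold outcome: top-bin centre m, cut lam = m/2, W*."""

    m: float
    lam: float
    Wstar: np.ndarray
    mode: str
    group_label: str = ""


def second_threshold(
    g: GroupMatrix | np.ndarray,
    mode: str = "top_decile_midpoint",
    n_bins: int = 10,
) -> SecondThresholdReport:
    """Threshold a group matrix at half the centre of its top-intensity bin.

    ``top_decile_midpoint`` (default) treats the top decile of nonzero
    off-diagonal entries as one bin: m = (q90 + max)/2 with nearest-rank
    q90.  ``top_bin_of_10`` instead takes the centre of the highest bin of
    an ``n_bins``-bin histogram spanning [min, max] of the nonzero entries.
    Entries below lam = m/2 are zeroed.
    """
    label = g.group_label if isinstance(g, GroupMatrix) else ""
    Wbar = g.Wbar if isinstance(g, GroupMatrix) else np.asarray(g, dtype=float)
    off = ~np.eye(Wbar.shape[0], dtype=bool)
    vals = Wbar[off & (Wbar != 0)]
    if vals.size == 0:
        raise ValueError(f"all-zero group matrix {label!r}")
    if mode == "top_decile_midpoint":
        v = np.sort(vals)
        q90 = v[max(int(np.ceil(0.9 * v.size)) - 1, 0)]  # nearest rank
        m = (q90 + v[-1]) / 2.0
    elif mode == "top_bin_of_10":
        lo, hi = float(vals.min()), float(vals.max())
        m = lo + (n_bins - 0.5) * (hi - lo) / n_bins
    else:
        raise ValueError(f"unknown second-threshold mode {mode!r}")
    lam = m / 2.0
    Wstar = np.where(Wbar >= lam, Wbar, 0.0)
    np.fill_diagonal(Wstar, 0.0)
    return SecondThresholdReport(float(m), float(lam), Wstar, mode, label)


@dataclass
class LinkTable:
    """Emerging links of one sex with per-group intensities and frequency.

    ``table`` has columns node_i, node_j (1-based, i < j), frequency, and
    one intensity column per group label; rows sorted by descending
    frequency then lexicographic pair.  Groups that were empty in the
    cohort are simply absent from the columns.
    """

    table: pd.DataFrame
    group_labels: list[str]

    @property
    def links(self) -> list[tuple[int, int]]:
        return [
            (int(i), int(j))
            for i, j in self.table[["node_i", "node_j"]].itertuples(index=False)
        ]

    def frequency(self, link: tuple[int, int]) -> int:
        i, j = sorted(link)
        sel = (self.table["node_i"] == i) & (self.table["node_j"] == j)
        if not sel.any():
            return 0
        return int(self.table.loc[sel, "frequency"].iloc[0])


def extract_links(
    thresholded: dict[str, SecondThresholdReport] | list[SecondThresholdReport],
) -> LinkTable:
    """Collect links with a nonzero entry in any group's W*.

    Frequency is the number of groups with a nonzero intensity at the link;
    absent groups contribute a zero intensity column entry.
    """
    if isinstance(thresholded, dict):
        items = list(thresholded.items())
    else:
        items = [(r.group_label or f"g{k+1}", r) for k, r in enumerate(thresholded)]
    labels = [lab for lab, _ in items]
    links: dict[tuple[int, int], dict[str, float]] = {}
    for lab, rep in items:
        ii, jj = np.nonzero(np.triu(rep.Wstar, k=1))
        for i, j in zip(ii, jj):
            links.setdefault((int(i) + 1, int(j) + 1), {})[lab] = float(rep.Wstar[i, j])
    rows = []
    for (i, j), intens in links.items():
        row = {"node_i": i, "node_j": j}
        row.update({lab: intens.get(lab, 0.0) for lab in labels})
        row["frequency"] = sum(1 for v in intens.values() if v != 0)
        rows.append(row)
    cols = ["node_i", "node_j", "frequency", *labels]
    if not rows:
        return LinkTable(pd.DataFrame(columns=cols), labels)
    table = (
        pd.DataFrame(rows)[cols]
        .sort_values(["frequency", "node_i", "node_j"], ascending=[False, True, True])
        .reset_index(drop=True)
    )
    return LinkTable(table, labels)


def frequencies_from_intensities(intensities: pd.DataFrame) -> pd.Series:
    """Recompute link frequencies as nonzero counts over intensity columns."""
    value_cols = [c for c in intensities.columns if c not in ("node_i", "node_j")]
    return (intensities[value_cols] != 0).sum(axis=1)


def merged_membership(
    cohort: list[SubjectRecord],
) -> dict[tuple[str, str], list[SubjectRecord]]:
    """Assign subjects to the merged 7-band scheme (per sex)."""
    return assign_groups(cohort, scheme_7())
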