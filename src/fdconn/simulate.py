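"""Synthetic cohorts with the correlation structure the pipeline assumes.

Subjects are simulated from a latent-factor time-series model: every node
carries a weak cohort-wide factor (baseline correlation ``rho_out``
between any two nodes) and nodes inside a community share an additional
factor raising their pairwise correlation to ``rho_in``.  Empirical
correlation matrices computed from the finite series are therefore valid
(symmetric, unit diagonal, positive semidefinite) by construction, with
realistic sampling noise set by the series length ``t_points``.

The default community is the 12-node medial/posterior block that the
representative-graph analysis identifies with the default mode network, so
graph-recovery tests have a known ground truth; the default composition
matches the published cohort (14 age bands per sex, 51 M / 82 F / 133).
Sex-specific effects add a shared latent component to the two endpoint
nodes of a chosen link for subjects of a chosen sex and merged age band,
raising that link's expected correlation by ``delta`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import N_NODES
from .cohort import SubjectRecord
from .datasets import load_fixture
from .grouping import scheme_7

#: Nodes of the DMN-like community: bilateral precuneus, cingulate,
#: paracingulate, frontal pole and superior lateral occipital cortex.
DMN_NODES = frozenset({1, 22, 28, 29, 30, 31, 48, 69, 75, 76, 77, 78})


@dataclass(frozen=True)
class Effect:
    """Injected sex difference: link (i, j), merged band label, sex, delta."""

    link: tuple[int, int]
    group_label: str
    sex: str
    delta: float


@dataclass
class CohortConfig:
    """Generator settings; defaults emulate the published study conditions."""

    group_sizes: pd.DataFrame | None = None  # defaults to the packaged table
    communities: tuple[frozenset[int], ...] = (DMN_NODES,)
    rho_in: float = 0.6
    rho_out: float = 0.05
    t_points: int = 160
    effects: tuple[Effect, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.rho_out < self.rho_in < 1:
            raise ValueError("need 0 <= rho_out < rho_in < 1")
        for eff in self.effects:
            if eff.delta < 0:
                raise ValueError("effect delta must be >= 0")

    def sizes(self) -> pd.DataFrame:
        return self.group_sizes if self.group_sizes is not None else load_fixture("table1")


@dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    centroids: pd.DataFrame
    truth: dict = field(default_factory=dict)


def generate_centroids(seed: int = 0, n_nodes: int = N_NODES) -> pd.DataFrame:
    """Mirrored-hemisphere centroid set (mm): right nodes are x-mirrors.

    Left-hemisphere nodes get coordinates in plausible MNI-like ranges;
    each right node 48..94 is the x-reflection of its homologue 1..47.
    """
    rng = np.random.default_rng(seed)
    n_left = (n_nodes + 1) // 2
    x = -rng.uniform(5.0, 70.0, n_left)
    y = rng.uniform(-100.0, 70.0, n_left)
    z = rng.uniform(-45.0, 75.0, n_left)
    left = pd.DataFrame(
        {"node_id": np.arange(1, n_left + 1), "x": x, "y": y, "z": z}
    )
    right = left.iloc[: n_nodes - n_left].copy()
    right["node_id"] = np.arange(n_left + 1, n_nodes + 1)
    right["x"] = -right["x"]
    return pd.concat([left, right], ignore_index=True)


def _community_labels(
    communities: tuple[frozenset[int], ...], n_nodes: int
) -> np.ndarray:
    labels = np.full(n_nodes, -1, dtype=int)
    for c, nodes in enumerate(communities):
        for v in nodes:
            if not 1 <= v <= n_nodes:
                raise ValueError(f"community node {v} outside 1..{n_nodes}")
            if labels[v - 1] != -1:
                raise ValueError(f"node {v} in more than one community")
            labels[v - 1] = c
    return labels


def _merged_label(age: int) -> str:
    return scheme_7().band_for(age).label


def generate_subject(
    cfg: CohortConfig,
    sex: str,
    age: int,
    rng: np.random.Generator,
    subject_id: str = "S0",
    n_nodes: int = N_NODES,
) -> SubjectRecord:
    """Simulate one subject's time series and return its correlation matrix.

    Node signal: sqrt(rho_out) * g + sqrt(rho_in - rho_out) * f_c (if the
    node sits in community c) + idiosyncratic noise, all unit variance, so
    expected correlations are rho_in within and rho_out between.  Effects
    targeting this subject add a shared latent to both endpoint nodes,
    lifting that link's expected correlation by delta.
    """
    labels = _community_labels(cfg.communities, n_nodes)
    t = cfg.t_points
    g = rng.standard_normal(t)
    factors = rng.standard_normal((len(cfg.communities), t))
    noise = rng.standard_normal((n_nodes, t))
    a_out = np.sqrt(cfg.rho_out)
    series = a_out * g + noise * np.sqrt(1.0 - cfg.rho_out)
    in_comm = labels >= 0
    if in_comm.any():
        extra = cfg.rho_in - cfg.rho_out
        series[in_comm] = (
            a_out * g
            + np.sqrt(extra) * factors[labels[in_comm]]
            + np.sqrt(1.0 - cfg.rho_in) * noise[in_comm]
        )
    merged = _merged_label(age)
    for eff in cfg.effects:
        if eff.sex != sex or eff.group_label != merged or eff.delta == 0:
            continue
        i, j = eff.link
        li, lj = labels[i - 1], labels[j - 1]
        rho0 = cfg.rho_in if (li >= 0 and li == lj) else cfg.rho_out
        if eff.delta >= 1.0 - rho0:
            raise ValueError(
                f"delta {eff.delta} too large for baseline correlation {rho0}"
            )
        # replace a fraction of each endpoint's idiosyncratic noise with a
        # shared component: corr(i, j) rises by exactly delta while node
        # variances and every other pairwise correlation stay untouched
        idio = {
            v: np.sqrt(1.0 - (cfg.rho_in if labels[v] >= 0 else cfg.rho_out))
            for v in (i - 1, j - 1)
        }
        c = eff.delta / (idio[i - 1] * idio[j - 1])
        if c >= 1.0:
            raise ValueError(
                f"delta {eff.delta} too large for the endpoints' noise budget"
            )
        h = rng.standard_normal(t)
        for v in (i - 1, j - 1):
            series[v] = series[v] + idio[v] * (
                (np.sqrt(1.0 - c) - 1.0) * noise[v] + np.sqrt(c) * h
            )
    F = np.corrcoef(series)
    return SubjectRecord(subject_id, sex, int(age), F)


def generate_cohort(cfg: CohortConfig | None = None) -> SyntheticCohort:
    """Simulate a full cohort plus centroids; deterministic in cfg.seed."""
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.sizes()
    subjects = []
    k = 0
    for row in sizes.itertuples(index=False):
        for sex, n in (("M", int(row.n_male)), ("F", int(row.n_female))):
            for _ in range(n):
                age = int(rng.integers(row.age_lo, row.age_hi + 1))
                k += 1
                subjects.append(
                    generate_subject(cfg, sex, age, rng, subject_id=f"S{k:03d}")
                )
    centroids = generate_centroids(seed=cfg.seed)
    truth = {
        "seed": cfg.seed,
        "rho_in": cfg.rho_in,
        "rho_out": cfg.rho_out,
        "t_points": cfg.t_points,
        "communities": [sorted(c) for c in cfg.communities],
        "effects": [
            {
                "link": list(e.link),
                "group": e.group_label,
                "sex": e.sex,
                "delta": e.delta,
            }
            for e in cfg.effects
        ],
    }
    return SyntheticCohort(subjects, centroids, truth)
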