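"""Model/results facade tying the pipeline stages together.

:class:`FDConnectivity` is constructed from a cohort (list of subject
correlation matrices with sex and age) plus a normalized distance matrix,
and holds the analysis configuration.  ``fit()`` runs the deterministic
part of the pipeline — per-subject thresholding and FD weighting, group
averaging, the second threshold, emerging-link extraction, centrality and
the representative graph per sex — and returns
:class:`FDConnectivityResults`, from which the stochastic analyses
(permutation tests, model comparison) are launched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from . import compare as compare_mod
from .cohort import SEXES, SubjectRecord
from .grouping import (
    GroupMatrix,
    LinkTable,
    SecondThresholdReport,
    assign_groups,
    average_group,
    extract_links,
    scheme_14,
    second_threshold,
)
from .graph import GraphSpec, centrality_index, graph_properties, select_representative_graph
from .simulate import CohortConfig, generate_cohort
from .stats import (
    DEFAULT_N_PERM,
    StatDataset,
    build_stat_dataset,
    run_global_analysis,
    run_local_analysis,
)
from .weights import FDWeightMatrix, clip_negatives, fd_weights, first_threshold


@dataclass
class FDConnectivity:
    """Degree-distance-correlation connectivity model for a cohort.

    Parameters
    ----------
    subjects
        Cohort of :class:`SubjectRecord`.
    distance
        Normalized 94x94 distance matrix (entries in [0, 1]).
    first_cut
        First-threshold cut on correlations (upper edge of histogram bin 2).
    eta
        Distance weighting constant (1 after distance normalization).
    second_mode
        Second-threshold rule: "top_decile_midpoint" or "top_bin_of_10".
    min_freq
        Group-frequency floor for secondary vertex attachment.
    """

    subjects: list[SubjectRecord]
    distance: np.ndarray
    first_cut: float = 0.2
    eta: float = 1.0
    second_mode: str = "top_decile_midpoint"
    min_freq: int = 7
    ci_bins: int = 10
    mask_zero_correlation: bool = False

    @classmethod
    def from_manifest(cls, manifest_path, centroids_path=None, distance_path=None, **kw):
        """Build from a cohort manifest plus centroids or a distance matrix."""
        from .cohort import read_cohort

        subjects = read_cohort(manifest_path)
        if (centroids_path is None) == (distance_path is None):
            raise ValueError("give exactly one of centroids_path / distance_path")
        if centroids_path is not None:
            cents = atlas_mod.load_centroids(centroids_path)
            D = atlas_mod.distance_matrix(cents, normalize=True)
        else:
            D = atlas_mod.load_distance_matrix(distance_path, normalize=True)
        return cls(subjects, D, **kw)

    @classmethod
    def from_synthetic(cls, cfg: CohortConfig | None = None, **kw):
        """Build from a simulated cohort (see :mod:`fdconn.simulate`)."""
        cohort = generate_cohort(cfg)
        D = atlas_mod.distance_matrix(cohort.centroids, normalize=True)
        model = cls(cohort.subjects, D, **kw)
        model._truth = cohort.truth
        return model

    def fit(self) -> "FDConnectivityResults":
        """Run the deterministic pipeline and return the results object."""
        D = np.asarray(self.distance, dtype=float)
        subject_w: dict[str, FDWeightMatrix] = {}
        subject_fpos: dict[str, np.ndarray] = {}
        subject_fs: dict[str, np.ndarray] = {}
        for s in self.subjects:
            Fpos = clip_negatives(s.F)
            np.fill_diagonal(Fpos, 0.0)
            Fs = first_threshold(Fpos, cut=self.first_cut)
            subject_w[s.subject_id] = fd_weights(
                Fs, D, eta=self.eta, mask_zero_correlation=self.mask_zero_correlation
            )
            subject_fpos[s.subject_id] = Fpos
            subject_fs[s.subject_id] = Fs.values
        scheme = scheme_14()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty groups flagged below
            membership = assign_groups(self.subjects, scheme)
        group_matrices: dict[str, dict[str, GroupMatrix]] = {s: {} for s in SEXES}
        reports: dict[str, dict[str, SecondThresholdReport]] = {s: {} for s in SEXES}
        empty_groups = []
        for (sex, label), members in membership.items():
            if not members:
                empty_groups.append((sex, label))
                continue
            gm = average_group([subject_w[m.subject_id] for m in members], label)
            group_matrices[sex][label] = gm
            reports[sex][label] = second_threshold(gm, mode=self.second_mode)
        link_tables = {sex: extract_links(reports[sex]) for sex in SEXES}
        centrality, graphs = {}, {}
        for sex in SEXES:
            reps = list(reports[sex].values())
            if not reps:
                continue
            ci = centrality_index(reps)
            centrality[sex] = ci
            try:
                graphs[sex] = select_representative_graph(
                    link_tables[sex], ci, n_bins=self.ci_bins, min_freq=self.min_freq
                )
            except ValueError as err:
                warnings.warn(f"graph selection skipped for sex {sex}: {err}", stacklevel=2)
        union = sorted(
            set(link_tables["M"].links) | set(link_tables["F"].links)
        )
        return FDConnectivityResults(
            model=self,
            subject_weights=subject_w,
            subject_correlations=subject_fpos,
            subject_thresholded=subject_fs,
            group_matrices=group_matrices,
            threshold_reports=reports,
            link_tables=link_tables,
            union_links=union,
            centrality=centrality,
            graphs=graphs,
            empty_groups=empty_groups,
            truth=getattr(self, "_truth", None),
        )


@dataclass
class FDConnectivityResults:
    """Fitted pipeline state: weights, group matrices, links, graphs."""

    model: FDConnectivity
    subject_weights: dict[str, FDWeightMatrix]
    subject_correlations: dict[str, np.ndarray]
    subject_thresholded: dict[str, np.ndarray]
    group_matrices: dict[str, dict[str, GroupMatrix]]
    threshold_reports: dict[str, dict[str, SecondThresholdReport]]
    link_tables: dict[str, LinkTable]
    union_links: list[tuple[int, int]]
    centrality: dict[str, pd.Series]
    graphs: dict[str, GraphSpec]
    empty_groups: list[tuple[str, str]] = field(default_factory=list)
    truth: dict | None = None

    @property
    def q(self) -> int:
        """Cardinality of the union link set L used by the statistics."""
        return len(self.union_links)

    def stat_dataset(self, link_values: str = "fd_weight") -> StatDataset:
        """Per-merged-group samples of subject link values on L.

        ``link_values`` selects what is compared: "fd_weight" (default, the
        normalized FD weights, as in the reference analysis) or
        "correlation" (the first-threshold correlations; immune to the
        ceiling the per-subject weight normalization imposes on the
        strongest link).
        """
        if link_values == "fd_weight":
            mats = self.subject_weights
        elif link_values == "correlation":
            mats = self.subject_thresholded
        else:
            raise ValueError(f"unknown link_values {link_values!r}")
        return build_stat_dataset(self.model.subjects, mats, self.union_links)

    def test_sex_differences(
        self,
        n_perm: int = DEFAULT_N_PERM,
        seed: int | None = None,
        alpha: float = 0.05,
        weak_alpha: float = 0.10,
        local: str = "significant",
        link_values: str = "fd_weight",
    ) -> "SexDifferenceResults":
        """Global (per merged group) then local (per link) permutation tests.

        ``local`` controls which groups get the per-link follow-up:
        "significant" (default: globally flagged groups only), "all", or
        "none".
        """
        if self.q == 0:
            raise ValueError("no emerging links; nothing to test")
        dataset = self.stat_dataset(link_values=link_values)
        rng = np.random.default_rng(seed)
        global_table = run_global_analysis(
            dataset, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)), alpha=alpha
        )
        local_tables: dict[str, pd.DataFrame] = {}
        if local not in ("significant", "all", "none"):
            raise ValueError(f"unknown local policy {local!r}")
        if local != "none":
            targets = (
                global_table.loc[global_table["significant"], "group"]
                if local == "significant"
                else global_table["group"]
            )
            for lab in targets:
                local_tables[lab] = run_local_analysis(
                    dataset,
                    lab,
                    n_perm=n_perm,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    alpha=alpha,
                    weak_alpha=weak_alpha,
                )
        return SexDifferenceResults(global_table, local_tables, n_perm, seed)

    def compare_with_correlations(
        self,
        threshold_mode: str = "histogram_gap",
        threshold: float | None = None,
        with_atlas_names: bool = True,
    ) -> compare_mod.ComparisonResult:
        """Average FD weights vs average correlations over the whole cohort."""
        ids = [s.subject_id for s in self.model.subjects]
        W_list = [self.subject_weights[i].W for i in ids]
        F_list = [self.subject_correlations[i] for i in ids]
        Wrep, Frep = compare_mod.representative_matrices(W_list, F_list)
        at = None
        if with_atlas_names and Wrep.shape[0] == atlas_mod.N_NODES:
            at = atlas_mod.load_atlas()
        return compare_mod.select_discrepant_links(
            Wrep, Frep, threshold_mode=threshold_mode, threshold=threshold, atlas=at
        )

    def graph_report(self) -> dict:
        return {sex: graph_properties(g) for sex, g in self.graphs.items()}

    def summary(self) -> str:
        """Human-readable account of the fitted pipeline."""
        lines = []
        n = len(self.model.subjects)
        n_m = sum(1 for s in self.model.subjects if s.sex == "M")
        lines.append("FD connectivity analysis")
        lines.append("=" * 48)
        lines.append(f"subjects:            {n} ({n_m} M, {n - n_m} F)")
        lines.append(f"nodes:               {self.model.distance.shape[0]}")
        lines.append(f"first threshold:     > {self.model.first_cut}")
        lines.append(f"second threshold:    {self.model.second_mode} (lam = m/2)")
        lines.append(f"emerging links |L|:  {self.q}")
        for sex in SEXES:
            lt = self.link_tables.get(sex)
            if lt is None or len(lt.table) == 0:
                continue
            lines.append(f"-- sex {sex}: {len(lt.table)} links")
            g = self.graphs.get(sex)
            if g is not None:
                props = graph_properties(g)
                lines.append(
                    f"   V' = {sorted(g.vprime)}\n   V'' = {sorted(g.vsecond)}"
                )
                lines.append(
                    f"   graph: {props['n_nodes']} nodes, {props['n_edges']} edges, "
                    f"{props['n_components']} components, planar={props['planar']}"
                )
        if self.empty_groups:
            lines.append(f"empty groups: {self.empty_groups}")
        return "\n".join(lines)


@dataclass
class SexDifferenceResults:
    """Permutation-test outcome: global table and per-group local tables."""

    global_table: pd.DataFrame
    local_tables: dict[str, pd.DataFrame]
    n_perm: int
    seed: int | None

    @property
    def significant_groups(self) -> list[str]:
        t = self.global_table
        return list(t.loc[t["significant"], "group"])

    def summary(self) -> str:
        lines = ["Global male/female permutation tests (Holm-adjusted)"]
        lines.append(self.global_table.to_string(index=False))
        for lab, tab in self.local_tables.items():
            lines.append(f"\nLocal analysis, group {lab} (top links)")
            lines.append(tab.head(10).to_string(index=False))
        return "\n".join(lines)
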