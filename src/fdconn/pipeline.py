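"""End-to-end pipeline driver with a structured configuration.

One YAML (or dataclass) config names every analysis choice — thresholds,
modes, frequency floor, permutation count, seed, significance levels — and
``run_pipeline`` executes the stages in order, writing all intermediate
artifacts (per-subject weights, group matrices, link tables, graph edge
lists/GraphML, test tables, comparison report) plus a JSON run report that
records config, seed and library versions so a run can be reproduced
bit-identically.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .cohort import SEXES, write_matrix
from .model import FDConnectivity
from .simulate import CohortConfig, Effect

log = logging.getLogger("fdconn")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults match the reference analysis."""

    manifest: str | None = None
    centroids: str | None = None
    distance: str | None = None
    out_dir: str = "fdconn_out"
    synthetic: bool = False  # generate the default synthetic cohort instead
    first_cut: float = 0.2
    second_mode: str = "top_decile_midpoint"
    ci_bins: int = 10
    min_freq: int = 7
    eta: float = 1.0
    mask_zero_correlation: bool = False
    n_perm: int = 9999
    seed: int = 0
    alpha: float = 0.05
    weak_alpha: float = 0.10
    comparison_mode: str = "histogram_gap"
    comparison_threshold: float | None = None
    effects: list[dict] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _build_model(cfg: PipelineConfig) -> FDConnectivity:
    kw = dict(
        first_cut=cfg.first_cut,
        second_mode=cfg.second_mode,
        ci_bins=cfg.ci_bins,
        min_freq=cfg.min_freq,
        eta=cfg.eta,
        mask_zero_correlation=cfg.mask_zero_correlation,
    )
    if cfg.synthetic or cfg.manifest is None:
        effects = tuple(
            Effect(tuple(e["link"]), e["group"], e["sex"], float(e["delta"]))
            for e in cfg.effects
        )
        sim = CohortConfig(seed=cfg.seed, effects=effects)
        return FDConnectivity.from_synthetic(sim, **kw)
    return FDConnectivity.from_manifest(
        cfg.manifest, centroids_path=cfg.centroids, distance_path=cfg.distance, **kw
    )


def _write_graph(gspec, out_dir: Path, sex: str) -> None:
    rows = [
        {
            "node_i": i,
            "node_j": j,
            "class": d.get("cls"),
            "frequency": d.get("frequency"),
        }
        for i, j, d in gspec.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_i", "node_j", "class", "frequency"]).to_csv(
        out_dir / f"graph_{sex}.csv", index=False
    )
    G = gspec.graph.copy()
    for _, _, d in G.edges(data=True):  # GraphML cannot hold None
        if d.get("frequency") is None:
            d["frequency"] = -1
    nx.write_graphml(G, out_dir / f"graph_{sex}.graphml")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage, write artifacts under cfg.out_dir, return report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "build"
    try:
        model = _build_model(cfg)
        stage = "fit"
        res = model.fit()
        log.info("fit: %d subjects, Q=%d emerging links", len(model.subjects), res.q)
        wdir = out / "subject_weights"
        wdir.mkdir(exist_ok=True)
        for sid, fw in res.subject_weights.items():
            write_matrix(wdir / f"{sid}.csv", fw.W)
        for sex in SEXES:
            for lab, gm in res.group_matrices.get(sex, {}).items():
                write_matrix(out / f"group_{sex}_{lab}.csv", gm.Wbar)
            lt = res.link_tables.get(sex)
            if lt is not None:
                lt.table.to_csv(out / f"links_{sex}.csv", index=False)
            ci = res.centrality.get(sex)
            if ci is not None:
                ci.rename_axis("node").to_csv(out / f"centrality_{sex}.csv")
        stage = "graph"
        for sex, g in res.graphs.items():
            _write_graph(g, out, sex)
        graph_report = res.graph_report()
        stage = "stats"
        stats_report = {}
        have_both_sexes = {s.sex for s in model.subjects} == set(SEXES)
        if have_both_sexes and res.q > 0:
            sexdiff = res.test_sex_differences(
                n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.alpha,
                weak_alpha=cfg.weak_alpha,
            )
            sexdiff.global_table.to_csv(out / "global_tests.csv", index=False)
            for lab, tab in sexdiff.local_tables.items():
                tab.to_csv(out / f"local_tests_{lab}.csv", index=False)
            stats_report = {
                "significant_groups": sexdiff.significant_groups,
                "n_perm": cfg.n_perm,
            }
        else:
            warnings.warn("statistics stage skipped (one sex absent or no links)")
            stats_report = {"skipped": True}
        stage = "compare"
        comp = res.compare_with_correlations(
            threshold_mode=cfg.comparison_mode, threshold=cfg.comparison_threshold
        )
        write_matrix(out / "difference_matrix.csv", comp.M)
        comp.to_frame().to_csv(out / "discrepant_links.csv", index=False)
        report = {
            "config": asdict(cfg),
            "seed": cfg.seed,
            "versions": {
                "fdconn": _version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "networkx": nx.__version__,
            },
            "n_subjects": len(model.subjects),
            "q_links": res.q,
            "thresholds": {
                "first_cut": cfg.first_cut,
                "second": {
                    sex: {lab: rep.lam for lab, rep in res.threshold_reports[sex].items()}
                    for sex in SEXES
                },
                "comparison": comp.threshold,
            },
            "graphs": graph_report,
            "stats": stats_report,
            "comparison_links": [list(l) for l in comp.selected_links],
        }
    except Exception as err:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def run_fixture_analysis(out_dir=None) -> dict:
    """Graph selection on the packaged published tables (no scan data).

    Runs the principal/secondary selection on the published link-frequency
    and centrality tables per sex and reports the vertex sets, the union,
    the cardinality Q of the union link set, and graph properties.
    """
    from .datasets import link_set, load_fixture
    from .graph import graph_properties, select_representative_graph
    from .grouping import LinkTable

    report: dict = {}
    union_links = set()
    for sex in ("male", "female"):
        lt = LinkTable(load_fixture(f"table3_{sex}"), [])
        t6 = load_fixture(f"table6_{sex}")
        ci = pd.Series(t6["ci"].values, index=t6["node"].values, name="ci")
        g = select_representative_graph(lt, ci)
        union_links |= link_set(lt.table)
        report[sex] = {
            "v_principal": sorted(g.vprime),
            "v_secondary": sorted(g.vsecond),
            "vertices": sorted(g.vertices),
            "properties": graph_properties(g),
        }
        if out_dir is not None:
            _write_graph(g, Path(out_dir), sex)
    report["q_links"] = len(union_links)
    report["union_identical"] = (
        report["male"]["vertices"] == report["female"]["vertices"]
    )
    if out_dir is not None:
        with open(Path(out_dir) / "fixture_analysis.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("fdconn")
    except PackageNotFoundError:
        return "unknown"
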