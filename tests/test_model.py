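import json

import numpy as np
import pytest

from fdconn import CohortConfig, FDConnectivity, load_fixture
from fdconn.cohort import write_cohort


class TestFit:
    def test_deterministic_end_to_end(self, small_cohort_config, fitted_small):
        res2 = FDConnectivity.from_synthetic(small_cohort_config).fit()
        sid = next(iter(fitted_small.subject_weights))
        assert np.array_equal(
            fitted_small.subject_weights[sid].W, res2.subject_weights[sid].W
        )
        assert fitted_small.union_links == res2.union_links

    def test_weight_matrices_normalized(self, fitted_small):
        for fw in fitted_small.subject_weights.values():
            assert fw.W.max() == pytest.approx(1.0)
            assert fw.W.min() >= 0
            assert np.allclose(np.diag(fw.W), 0.0)

    def test_link_tables_sorted_and_consistent(self, fitted_small):
        for sex, lt in fitted_small.link_tables.items():
            freqs = list(lt.table.frequency)
            assert freqs == sorted(freqs, reverse=True)
            labs = lt.group_labels
            for _, row in lt.table.iterrows():
                assert row.frequency == sum(row[lab] != 0 for lab in labs)

    def test_union_links_cover_both_sexes(self, fitted_small):
        lm = set(fitted_small.link_tables["M"].links)
        lf = set(fitted_small.link_tables["F"].links)
        assert set(fitted_small.union_links) == lm | lf

    def test_summary_mentions_key_quantities(self, fitted_small):
        text = fitted_small.summary()
        assert "emerging links" in text
        assert str(fitted_small.q) in text


class TestStatInterface:
    def test_stat_dataset_shapes(self, fitted_small):
        ds = fitted_small.stat_dataset()
        assert ds.q == fitted_small.q
        for lab, (Y, X) in ds.groups.items():
            assert Y.shape[1] == X.shape[1] == ds.q
        # small cohort: 2 M and 2 F per 14-band -> 4 per merged band
        assert all(Y.shape[0] == 4 and X.shape[0] == 4 for Y, X in ds.groups.values())

    def test_correlation_route_values(self, fitted_small):
        ds = fitted_small.stat_dataset(link_values="correlation")
        # correlation values at emerging links exceed the first cut
        for Y, X in ds.groups.values():
            vals = np.concatenate([Y.ravel(), X.ravel()])
            assert ((vals == 0) | (vals > 0.2)).all()

    def test_unknown_route_rejected(self, fitted_small):
        with pytest.raises(ValueError, match="link_values"):
            fitted_small.stat_dataset(link_values="banana")

    def test_sexdiff_runs_and_adjusts(self, fitted_small):
        out = fitted_small.test_sex_differences(n_perm=99, seed=5, local="all")
        t = out.global_table
        assert len(t) == 7
        assert (t.adj_p >= t.raw_p - 1e-15).all()
        assert set(out.local_tables) == set(t.group)
        for tab in out.local_tables.values():
            assert len(tab) == fitted_small.q

    def test_sexdiff_deterministic_in_seed(self, fitted_small):
        a = fitted_small.test_sex_differences(n_perm=99, seed=5, local="none")
        b = fitted_small.test_sex_differences(n_perm=99, seed=5, local="none")
        assert a.global_table.raw_p.tolist() == b.global_table.raw_p.tolist()


class TestComparison:
    def test_compare_runs(self, fitted_small):
        res = fitted_small.compare_with_correlations()
        assert res.M.shape == (94, 94)
        assert res.threshold > 0
        frame = res.to_frame()
        if len(frame):
            assert "region_i" in frame.columns


class TestPipeline:
    def test_run_pipeline_writes_artifacts(self, tmp_path, small_cohort_config):
        from fdconn.pipeline import PipelineConfig, run_pipeline

        cohort_cfg = small_cohort_config
        cfg = PipelineConfig(
            synthetic=True, out_dir=str(tmp_path / "run"), n_perm=49, seed=3
        )
        # shrink the synthetic cohort for speed by reusing its sizes
        import fdconn.pipeline as pl

        orig = pl.CohortConfig
        pl.CohortConfig = lambda **kw: orig(group_sizes=cohort_cfg.group_sizes, **kw)
        try:
            report = run_pipeline(cfg)
        finally:
            pl.CohortConfig = orig
        out = tmp_path / "run"
        assert (out / "run_report.json").exists()
        assert (out / "links_M.csv").exists()
        assert (out / "global_tests.csv").exists()
        assert (out / "difference_matrix.csv").exists()
        on_disk = json.loads((out / "run_report.json").read_text())
        assert on_disk["seed"] == 3
        assert on_disk["q_links"] == report["q_links"]

    def test_one_sex_absent_skips_all_groups(self):
        sizes = load_fixture("table1")
        sizes["n_male"] = 1
        sizes["n_female"] = 0
        res = FDConnectivity.from_synthetic(
            CohortConfig(group_sizes=sizes, seed=1)
        ).fit()
        with pytest.warns(UserWarning, match="skipped"):
            out = res.test_sex_differences(n_perm=19, seed=0, local="none")
        assert out.global_table.empty
        assert out.significant_groups == []

    def test_fixture_only_mode_reproduces_published_graph(self, tmp_path):
        from fdconn.pipeline import run_fixture_analysis

        report = run_fixture_analysis(tmp_path)
        assert report["q_links"] == 29
        assert report["union_identical"]
        assert report["male"]["properties"]["n_components"] == 2
        assert (tmp_path / "fixture_analysis.json").exists()
        assert (tmp_path / "graph_male.graphml").exists()

    def test_unknown_config_key_rejected(self, tmp_path):
        from fdconn.pipeline import PipelineConfig

        p = tmp_path / "cfg.yaml"
        p.write_text("bogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            PipelineConfig.from_yaml(p)


class TestCLI:
    def test_fixtures_list_and_dump(self):
        from click.testing import CliRunner

        from fdconn.cli import main

        runner = CliRunner()
        listed = runner.invoke(main, ["fixtures"])
        assert listed.exit_code == 0 and "table3_male" in listed.output
        dumped = runner.invoke(main, ["fixtures", "table1"])
        assert dumped.exit_code == 0 and "n_male" in dumped.output
        missing = runner.invoke(main, ["fixtures", "nosuch"])
        assert missing.exit_code != 0
        assert "available" in missing.output

    def test_simulate_and_weights_roundtrip(self, tmp_path, small_cohort_config):
        from click.testing import CliRunner

        from fdconn.cli import main
        from fdconn.simulate import generate_cohort

        cohort = generate_cohort(small_cohort_config)
        out = tmp_path / "cohort"
        write_cohort(cohort.subjects, out)
        cohort.centroids.to_csv(out / "centroids.csv", index=False)
        runner = CliRunner()
        result = runner.invoke(
            main,
            [
                "weights",
                "--manifest", str(out / "manifest.csv"),
                "--centroids", str(out / "centroids.csv"),
                "--out", str(tmp_path / "w"),
            ],
        )
        assert result.exit_code == 0, result.output
        written = list((tmp_path / "w").glob("*.csv"))
        assert len(written) == len(cohort.subjects)


class TestFixtureAccess:
    def test_published_table_row_counts(self):
        assert len(load_fixture("table3_male")) == 27
        assert len(load_fixture("table1")) == 14
        assert len(load_fixture("table11")) == 58

    def test_unknown_fixture_lists_names(self):
        with pytest.raises(KeyError, match="table9"):
            load_fixture("nosuch")
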