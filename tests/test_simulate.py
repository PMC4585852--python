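import numpy as np
import pandas as pd
import pytest

from conftest import small_sim_config
from riborestore import prognosis
from riborestore.simulate import (GroundTruth, SimulationConfig,
                                  simulate_all, simulate_annotation,
                                  simulate_cna, simulate_cohort,
                                  simulate_expression)


class TestAnnotationGenerator:
    def test_non_overlapping_tiling(self):
        cat = simulate_annotation(small_sim_config())
        for _, grp in cat.groupby("chrom"):
            grp = grp.sort_values("start")
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()

    def test_determinism(self):
        a = simulate_annotation(small_sim_config())
        b = simulate_annotation(small_sim_config())
        pd.testing.assert_frame_equal(a, b)

    def test_class_counts_exceeding_genes_error(self):
        cfg = small_sim_config(n_restore_up=500)
        with pytest.raises(ValueError, match="exceed"):
            simulate_annotation(cfg)


class TestCNAGenerator:
    def test_zero_probe_noise_equals_segment_means(self):
        cfg = small_sim_config(sigma_probe=0.0)
        cat = simulate_annotation(cfg)
        tracks, states, _, _ = simulate_cna(cat, cfg)
        from riborestore.simulate import STATE_MEANS
        wide = tracks.pivot_table(index="position", columns="sample",
                                  values="log_ratio")
        expected = states.to_numpy()
        mean_map = np.vectorize(STATE_MEANS.get)(expected)
        got = tracks.set_index(["chrom", "position", "sample"])["log_ratio"]
        # spot-check every gene of one line
        line = states.columns[0]
        mid = (cat["start"] + cat["end"]) // 2
        for g in states.index[:50]:
            v = got.loc[(cat.loc[g, "chrom"], mid[g], line)]
            assert v == STATE_MEANS[states.loc[g, line]]

    def test_planted_loss_region_genes_have_loss_state(self):
        cfg = small_sim_config()
        cat = simulate_annotation(cfg)
        _, states, gene_class, regions = simulate_cna(cat, cfg)
        for g, cls in gene_class.items():
            signs = set(states.loc[g][states.loc[g] != 0])
            if cls in ("RESTORE_UP", "ENHANCE_DOWN"):
                assert signs == {-1}
            else:
                assert signs <= {1, 2} and signs

    def test_determinism(self):
        cfg = small_sim_config()
        cat = simulate_annotation(cfg)
        t1, s1, c1, _ = simulate_cna(cat, cfg)
        t2, s2, c2, _ = simulate_cna(cat, cfg)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(s1, s2)
        assert c1 == c2


class TestExpressionGenerator:
    def test_full_compensation_zero_noise_restores_baseline(self):
        # gamma=1, sigma -> 0: a RESTORE gene's translatome equals the
        # baseline while its transcriptome carries the full dosage shift
        cfg = small_sim_config(noise_sd=0.0, sigma_probe=0.0, compensation=1.0)
        cat = simulate_annotation(cfg)
        _, states, gene_class, _ = simulate_cna(cat, cfg)
        tc, tl, _, truth = simulate_expression(cat, states, gene_class, cfg)
        beta = cfg.dosage_effect
        for g, cls in gene_class.items():
            if not cls.startswith("RESTORE"):
                continue
            # full compensation: the translatome is flat at the baseline
            # while the transcriptome carries the full dosage shift
            row_tl = tl.loc[g]
            assert row_tl.std() == pytest.approx(0.0, abs=1e-12)
            expected_tc = row_tl + beta * states.loc[g]
            assert np.allclose(tc.loc[g], expected_tc)

    def test_no_compensation_translatome_equals_transcriptome(self):
        cfg = small_sim_config(noise_sd=0.0, compensation=0.0)
        cat = simulate_annotation(cfg)
        _, states, gene_class, _ = simulate_cna(cat, cfg)
        tc, tl, _, _ = simulate_expression(cat, states, gene_class, cfg)
        non_hist = cat.index[cat["family"].isna()]
        assert np.allclose(tc.loc[non_hist], tl.loc[non_hist])

    def test_histone_family_sums_match_target_tc_disperses(self):
        cfg = small_sim_config(stoich_noise_sd=0.005)
        cat = simulate_annotation(cfg)
        _, states, gene_class, _ = simulate_cna(cat, cfg)
        tc, tl, _, truth = simulate_expression(cat, states, gene_class, cfg)
        ctrl = truth.control_line
        for family, target in truth.family_targets.items():
            members = cat.index[cat["family"] == family]
            tl_sums = (2.0 ** tl.loc[members]).sum(axis=0)
            tc_sums = (2.0 ** tc.loc[members]).sum(axis=0)
            non_ctrl = [c for c in tl.columns if c != ctrl]
            assert np.all(np.abs(tl_sums[non_ctrl] / target - 1) < 0.05)
            assert tc_sums.max() / tc_sums.min() >= 2.0

    def test_missing_call_errors(self):
        cfg = small_sim_config()
        cat = simulate_annotation(cfg)
        _, states, gene_class, _ = simulate_cna(cat, cfg)
        with pytest.raises(ValueError, match="cover"):
            simulate_expression(cat, states.iloc[:-1], gene_class, cfg)

    def test_ground_truth_round_trip(self, tmp_path):
        cfg = small_sim_config()
        ds = simulate_all(cfg)
        p = tmp_path / "truth.json"
        ds.truth.save(p)
        back = GroundTruth.load(p)
        assert back.gene_class == ds.truth.gene_class
        pd.testing.assert_frame_equal(back.copy_state, ds.truth.copy_state)
        assert back.family_targets == pytest.approx(ds.truth.family_targets)


class TestCohortGenerator:
    def test_null_effect_logrank_p_uniform(self):
        # with no prognostic effect the two expression groups of any gene
        # are exchangeable; log-rank p over repeated seeds is ~ uniform
        pvals = []
        for seed in range(200):
            cfg = small_sim_config(seed=seed, prognostic_effect=0.0,
                                   cohort_size=60, censoring_rate=0.1)
            truth = GroundTruth(
                gene_class={"gA": "RESTORE_DOWN"},
                copy_state=pd.DataFrame(), family_targets={},
                control_line="x")
            cohort, prog = simulate_cohort(truth, cfg)
            g = "gA"
            expr = cohort[g].to_numpy()
            high = expr > np.median(expr)
            res = prognosis.logrank_test(
                cohort["time"][high], cohort["event"][high],
                cohort["time"][~high], cohort["event"][~high])
            pvals.append(res.p)
        from scipy import stats
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_large_effect_power(self):
        # hazard ratio 5 with n=200: the planted prognostic gene separates
        # outcomes at log-rank p < 0.01 in nearly every replicate
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            cfg = small_sim_config(seed=seed, prognostic_effect=np.log(5.0),
                                   cohort_size=200, prognostic_fraction=1.0,
                                   censoring_rate=0.1)
            truth = GroundTruth(gene_class={"gA": "RESTORE_DOWN"},
                                copy_state=pd.DataFrame(), family_targets={},
                                control_line="x")
            cohort, prog = simulate_cohort(truth, cfg)
            expr = cohort["gA"].to_numpy()
            high = expr > np.median(expr)
            res = prognosis.logrank_test(
                cohort["time"][high], cohort["event"][high],
                cohort["time"][~high], cohort["event"][~high])
            hits += res.p < 0.01
        assert hits / n_rep >= 0.95

    def test_full_censoring_no_events(self):
        cfg = small_sim_config(censoring_rate=1.0)
        truth = GroundTruth(gene_class={"gA": "RESTORE_UP"},
                            copy_state=pd.DataFrame(), family_targets={},
                            control_line="x")
        cohort, _ = simulate_cohort(truth, cfg)
        assert (cohort["event"] == 0).all()
        with pytest.warns(UserWarning, match="no events"):
            res = prognosis.logrank_test(
                cohort["time"][:30], cohort["event"][:30],
                cohort["time"][30:], cohort["event"][30:])
        assert np.isnan(res.p)


class TestCatalogGenerator:
    def test_full_concordance_gives_frequency_one(self):
        cfg = small_sim_config(pan_cancer_concordance=1.0)
        ds = simulate_all(cfg)
        down = [g for g, c in ds.truth.gene_class.items() if c == "RESTORE_DOWN"]
        gain_cols = [c for c in ds.pan_cancer.columns if c.endswith(":gain")]
        assert np.allclose(ds.pan_cancer.loc[down, gain_cols], 1.0)

    def test_determinism_of_whole_study(self):
        a = simulate_all(small_sim_config())
        b = simulate_all(small_sim_config())
        pd.testing.assert_frame_equal(a.transcriptome, b.transcriptome)
        pd.testing.assert_frame_equal(a.pan_cancer, b.pan_cancer)
        assert a.complexes == b.complexes
        pd.testing.assert_frame_equal(a.cohort, b.cohort)

    def test_emitted_files_readable_by_core_io(self, tmp_path):
        from riborestore import io as rio
        simulate_all(small_sim_config(), outdir=tmp_path)
        cat = rio.read_annotation(tmp_path / "annotation.bed")
        tc = rio.read_expression_matrix(tmp_path / "transcriptome.tsv")
        assert len(cat) == len(tc)
        tracks = rio.read_probe_tracks(tmp_path / "probes.tsv")
        assert set(tracks["sample"]) == set(tc.columns)
        complexes = rio.read_complex_catalog(tmp_path / "complexes.tsv")
        assert all(len(m) >= 2 for m in complexes.values())
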