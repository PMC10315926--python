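"""Table I/O, replicate filtering, normalization and z-scoring."""

import numpy as np
import pandas as pd
import pytest

import tmtpanel as tp
from tmtpanel import quantio, synthgen


@pytest.fixture(scope="module")
def written_dataset(tmp_path_factory):
    cfg = tp.SimConfig(n_proteins=150, seed=4, dep_plan={("hik8",): 10})
    catalog = tp.make_proteome(cfg)
    truth = tp.plan_truth(catalog, cfg)
    exp = tp.simulate_tmt(truth, cfg, catalog)
    outdir = tmp_path_factory.mktemp("tables")
    paths = synthgen.write_experiment(exp, outdir)
    return exp, paths[:-1], paths[-1]


class TestReadProteinGroups:
    def test_round_trip_with_generator(self, written_dataset):
        exp, tables, design_path = written_dataset
        design = quantio.read_design(design_path)
        loaded = quantio.read_protein_groups(tables, design)
        assert loaded.n_replicates == 3
        assert loaded.intensities.shape == exp.intensities.shape
        np.testing.assert_allclose(loaded.intensities, exp.intensities, rtol=1e-9)
        assert loaded.design == {r: dict(m) for r, m in exp.design.items()}

    def test_missing_column_is_format_error(self, written_dataset, tmp_path):
        _, tables, design_path = written_dataset
        df = pd.read_csv(tables[0], sep="\t")
        bad = tmp_path / "bad.tsv"
        df.drop(columns=["Reporter intensity corrected 3"]).to_csv(
            bad, sep="\t", index=False
        )
        design = quantio.read_design(design_path)
        with pytest.raises(quantio.FormatError, match="Reporter intensity corrected 3"):
            quantio.read_protein_groups([bad, tables[1], tables[2]], design)

    def test_reverse_rows_excluded_downstream(self, written_dataset, tmp_path):
        exp, tables, design_path = written_dataset
        frames = [pd.read_csv(p, sep="\t") for p in tables]
        flagged = frames[0].loc[0, "Protein IDs"]
        paths = []
        for i, df in enumerate(frames):
            df["Reverse"] = df["Reverse"].astype("string")
            df.loc[df["Protein IDs"] == flagged, "Reverse"] = "+"
            p = tmp_path / f"rep{i}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths.append(p)
        design = quantio.read_design(design_path)
        loaded = quantio.read_protein_groups(paths, design)
        retained = quantio.filter_min_replicates(loaded, k=2)
        assert flagged not in retained

    def test_write_read_write_lossless(self, written_dataset, tmp_path):
        _, tables, design_path = written_dataset
        design = quantio.read_design(design_path)
        loaded = quantio.read_protein_groups(tables, design)
        paths2 = synthgen.write_experiment(loaded, tmp_path)
        assert paths2[0].read_text() == tables[0].read_text()


class TestFilterMinReplicates:
    def _exp_with_coverage(self, present_reps):
        cfg = tp.SimConfig(n_proteins=20, seed=3, dep_plan={})
        catalog = tp.make_proteome(cfg)
        truth = tp.plan_truth(catalog, cfg)
        exp = tp.simulate_tmt(truth, cfg, catalog)
        for rep in range(exp.n_replicates):
            if rep not in present_reps:
                exp.intensities[0, rep, :] = 0.0
        return exp

    def test_quantified_in_two_of_three_retained(self):
        exp = self._exp_with_coverage({0, 2})
        assert exp.proteins[0] in quantio.filter_min_replicates(exp, k=2)

    def test_single_replicate_dropped(self):
        exp = self._exp_with_coverage({1})
        assert exp.proteins[0] not in quantio.filter_min_replicates(exp, k=2)

    def test_monotone_in_k(self, default_dataset):
        _, _, _, exp = default_dataset
        k1 = set(quantio.filter_min_replicates(exp, k=1))
        k2 = set(quantio.filter_min_replicates(exp, k=2))
        k3 = set(quantio.filter_min_replicates(exp, k=3))
        assert k3 <= k2 <= k1

    def test_invalid_k_rejected(self, default_dataset):
        _, _, _, exp = default_dataset
        with pytest.raises(ValueError):
            quantio.filter_min_replicates(exp, k=0)
        with pytest.raises(ValueError):
            quantio.filter_min_replicates(exp, k=4)


class TestNormalizedRatios:
    def test_mean_scaling_hand_case(self):
        # raw ratios {1, 2, 3} in one slice -> normalized {0.5, 1.0, 1.5}
        rm = tp.RatioMatrix(
            proteins=("a", "b", "c"),
            mutants=("m",),
            ratios=np.array([[[1.0]], [[2.0]], [[3.0]]]),
        )
        normalized = rm.ratios[:, 0, 0] / np.nanmean(rm.ratios[:, 0, 0])
        np.testing.assert_allclose(normalized, [0.5, 1.0, 1.5])

    def test_slice_means_are_one(self, default_ratios):
        _, rm = default_ratios
        means = np.nanmean(rm.ratios, axis=0)
        np.testing.assert_allclose(means, 1.0, atol=1e-9)

    def test_null_noiseless_data_gives_all_ones(self):
        cfg = tp.SimConfig(n_proteins=30, dep_plan={}, noise_sigma=0.0, seed=6)
        catalog = tp.make_proteome(cfg)
        exp = tp.simulate_tmt(tp.plan_truth(catalog, cfg), cfg, catalog)
        rm = tp.compute_normalized_ratios(exp, exp.proteins)
        np.testing.assert_allclose(rm.ratios, 1.0, atol=1e-9)

    def test_normalization_idempotent(self, default_ratios):
        _, rm = default_ratios
        renorm = rm.ratios / np.nanmean(rm.ratios, axis=0, keepdims=True)
        np.testing.assert_allclose(renorm, rm.ratios, rtol=1e-12)

    def test_zero_wt_becomes_missing(self, default_dataset):
        _, _, _, exp = default_dataset
        import copy

        exp2 = copy.deepcopy(exp)
        wt_ch = exp2.channel_of(0, exp2.wt_strain())
        exp2.intensities[5, 0, wt_ch] = 0.0
        retained = quantio.filter_min_replicates(exp2, k=2)
        rm = tp.compute_normalized_ratios(exp2, retained)
        i = rm.proteins.index(exp2.proteins[5])
        assert np.isnan(rm.ratios[i, :, 0]).all()


class TestReplicateCorrelation:
    def test_duplicated_replicate_gives_r2_one(self, default_dataset):
        _, _, _, exp = default_dataset
        import copy

        exp2 = copy.deepcopy(exp)
        # make replicate 1 a relabeled copy of replicate 0
        for ch in range(synthgen.N_CHANNELS):
            strain = exp2.design[1][ch]
            src = exp2.channel_of(0, strain)
            exp2.intensities[:, 1, ch] = exp2.intensities[:, 0, src]
        corr = tp.replicate_correlation(exp2)
        pair01 = corr[(corr.rep_a == 0) & (corr.rep_b == 1)]
        np.testing.assert_allclose(pair01["r2"], 1.0, atol=1e-12)

    def test_low_noise_regime_exceeds_study_floor(self):
        cfg = tp.SimConfig(n_proteins=500, noise_sigma=0.1, seed=8)
        catalog = tp.make_proteome(cfg)
        exp = tp.simulate_tmt(tp.plan_truth(catalog, cfg), cfg, catalog)
        corr = tp.replicate_correlation(exp, quantio.filter_min_replicates(exp))
        assert (corr["r2"] > 0.9).all()

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(0)
        cfg = tp.SimConfig(n_proteins=2000, dep_plan={}, seed=9,
                           base_intensity_law=(20.0, 0.0), noise_sigma=1.0)
        catalog = tp.make_proteome(cfg)
        exp = tp.simulate_tmt(tp.plan_truth(catalog, cfg), cfg, catalog)
        corr = tp.replicate_correlation(exp)
        # flat base abundance: columns share nothing but noise
        assert (corr["r2"] < 0.05).all()


class TestFoldChangesAndZscores:
    def _rm(self, values):
        arr = np.asarray(values, dtype=float)[None, None, :]
        return tp.RatioMatrix(proteins=("p",), mutants=("m",), ratios=arr)

    def test_constant_ratios(self):
        fcm = tp.fold_changes_and_zscores(self._rm([2.0, 2.0, 2.0]))
        assert fcm.log2fc.loc["p", "m"] == pytest.approx(1.0)

    def test_log_symmetry(self):
        fcm = tp.fold_changes_and_zscores(self._rm([2.0, 0.5]))
        assert fcm.log2fc.loc["p", "m"] == pytest.approx(0.0)

    def test_zscored_rows_standardized(self, default_ratios):
        _, rm = default_ratios
        fcm = tp.fold_changes_and_zscores(rm)
        z = fcm.zscores.dropna(axis=0).to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_median_aggregation_option(self):
        fcm = tp.fold_changes_and_zscores(self._rm([1.0, 2.0, 8.0]), aggregate="median")
        assert fcm.log2fc.loc["p", "m"] == pytest.approx(1.0)


class TestSampleProfiles:
    def test_shape_and_standardization(self, default_dataset, default_ratios):
        _, _, _, exp = default_dataset
        retained, _ = default_ratios
        prof = tp.sample_profiles(exp, retained)
        assert prof.shape[1] == 18
        np.testing.assert_allclose(prof.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(prof.std(axis=1, ddof=0), 1.0, atol=1e-9)
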