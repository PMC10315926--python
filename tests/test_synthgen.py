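"""Generator: determinism, planted-truth exactness, interference model."""

import numpy as np
import pytest

import tmtpanel as tp

from conftest import brute_force_regions


class TestMakeProteome:
    def test_deterministic_under_fixed_seed(self):
        cfg = tp.SimConfig(n_proteins=100, n_categories=5, seed=1, dep_plan={})
        a = tp.make_proteome(cfg)
        b = tp.make_proteome(cfg)
        assert a.proteins == b.proteins
        assert a.categories == b.categories
        assert a.terms == b.terms
        assert len(a) == 100

    def test_rejects_empty_proteome(self):
        with pytest.raises(ValueError):
            tp.SimConfig(n_proteins=0)

    def test_categories_partition_proteome(self, default_dataset):
        _, catalog, _, _ = default_dataset
        assert set(catalog.categories) == set(catalog.proteins)
        sizes = {}
        for cat in catalog.categories.values():
            sizes[cat] = sizes.get(cat, 0) + 1
        assert sum(sizes.values()) == len(catalog)
        assert all(v > 0 for v in sizes.values())
        assert all(len(catalog.terms[p]) >= 1 for p in catalog.proteins)


class TestPlanTruth:
    def test_default_plan_matches_overlap_skeleton(self, default_dataset):
        _, _, truth, _ = default_dataset
        regions = brute_force_regions(truth.dep_sets())
        all_five = tuple(sorted(tp.DEFAULT_STRAINS[1:]))
        assert regions[all_five] == 4
        assert regions[("hik31",)] == 11
        assert regions[("hik8",)] == 60
        assert regions[("rre37",)] == 14
        assert regions[("sigE",)] == 25
        assert regions[("slr6041",)] == 97

    def test_null_plan_plants_nothing(self):
        cfg = tp.SimConfig(n_proteins=50, dep_plan={}, seed=2)
        truth = tp.plan_truth(tp.make_proteome(cfg), cfg)
        assert all(not d for d in truth.true_dep.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_arbitrary_plan_region_counts_exact(self, seed):
        rng = np.random.default_rng(seed)
        mutants = tp.DEFAULT_STRAINS[1:]
        plan = {}
        for _ in range(rng.integers(1, 8)):
            size = rng.integers(1, 6)
            region = tuple(sorted(rng.choice(mutants, size=size, replace=False)))
            plan[region] = plan.get(region, 0) + int(rng.integers(1, 10))
        cfg = tp.SimConfig(n_proteins=300, dep_plan=plan, seed=seed)
        truth = tp.plan_truth(tp.make_proteome(cfg), cfg)
        assert brute_force_regions(truth.dep_sets()) == plan

    def test_infeasible_plan_rejected(self):
        with pytest.raises(ValueError):
            tp.SimConfig(n_proteins=10, dep_plan={("hik8",): 11})

    def test_shared_regions_have_consistent_direction(self, default_dataset):
        _, _, truth, _ = default_dataset
        shared = [
            p for p in truth.true_dep["hik8"]
            if all(p in truth.true_dep[m] for m in tp.DEFAULT_STRAINS[1:])
        ]
        assert len(shared) == 4
        for p in shared:
            signs = {np.sign(truth.true_dep[m][p]) for m in tp.DEFAULT_STRAINS[1:]}
            assert len(signs) == 1

    def test_labeling_design_reshuffles_channels(self, default_dataset):
        _, _, truth, _ = default_dataset
        maps = list(truth.labeling_design.values())
        for chmap in maps:
            assert sorted(chmap.values()) == sorted(tp.DEFAULT_STRAINS)
        assert any(maps[0] != m for m in maps[1:])


class TestSimulateTmt:
    def _one_protein_ratio(self, f, fc, sigma=0.0):
        cfg = tp.SimConfig(
            n_proteins=10,
            noise_sigma=sigma,
            interference_f=f,
            dep_plan={("hik8",): 1},
            fc_law=tp.FoldChangeLaw(np.log2(fc), np.log2(fc), 1.0),
            seed=7,
        )
        catalog = tp.make_proteome(cfg)
        truth = tp.plan_truth(catalog, cfg)
        exp = tp.simulate_tmt(truth, cfg, catalog)
        protein = next(iter(truth.true_dep["hik8"]))
        i = catalog.proteins.index(protein)
        mut = exp.strain_intensity("hik8")[i]
        wt = exp.strain_intensity("WT")[i]
        return float((mut / wt)[0])

    def test_no_interference_identity(self):
        assert self._one_protein_ratio(f=0.0, fc=2.0) == pytest.approx(2.0, abs=1e-12)

    def test_full_mixing_limit(self):
        assert self._one_protein_ratio(f=0.999, fc=2.0) == pytest.approx(1.0, abs=1e-2)

    def test_closed_form_mixing_at_f03(self):
        # one channel at 26x among 6: signal = (26,1,1,1,1,1), mean = 31/6;
        # observed ratio = (0.7*26 + 0.3*31/6) / (0.7*1 + 0.3*31/6)
        expected = (0.7 * 26 + 0.3 * 31 / 6) / (0.7 * 1 + 0.3 * 31 / 6)
        got = self._one_protein_ratio(f=0.3, fc=26.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got < 10  # a "26-fold" signal reads below 10-fold

    def test_compression_monotone_in_f(self):
        ratios = [self._one_protein_ratio(f=f, fc=4.0) for f in np.arange(0, 1, 0.1)]
        assert all(a >= b - 1e-12 for a, b in zip(ratios, ratios[1:]))

    def test_mixing_conserves_total_signal_and_positivity(self, default_config):
        plan = {("hik8",): 10, ("hik31", "sigE"): 5}
        cfg = tp.SimConfig(seed=5, n_proteins=200, interference_f=0.4, dep_plan=plan)
        catalog = tp.make_proteome(cfg)
        truth = tp.plan_truth(catalog, cfg)
        exp = tp.simulate_tmt(truth, cfg, catalog)
        assert np.all(exp.intensities >= 0)
        cfg0 = tp.SimConfig(seed=5, n_proteins=200, interference_f=0.0, dep_plan=plan)
        exp0 = tp.simulate_tmt(tp.plan_truth(catalog, cfg0), cfg0, catalog)
        np.testing.assert_allclose(
            exp.intensities.sum(axis=2), exp0.intensities.sum(axis=2), rtol=1e-9
        )


class TestSimulatePrm:
    def test_full_occupancy_empties_counterparts(self):
        cfg = tp.SimConfig(occupancy_a=1.0, prm_cv=0.0, seed=1)
        truth = tp.plan_truth(tp.make_proteome(cfg), cfg)
        prm = tp.simulate_prm(truth, cfg)
        nonph_a = prm[(prm["condition"] == "A") & (~prm["phospho"])]
        assert (nonph_a["area"] == 0).all()

    def test_same_seed_identical_tables(self, default_config):
        truth = tp.plan_truth(tp.make_proteome(default_config), default_config)
        a = tp.simulate_prm(truth, default_config)
        b = tp.simulate_prm(truth, default_config)
        assert a.equals(b)

    def test_out_of_range_occupancy_rejected(self):
        with pytest.raises(ValueError):
            tp.SimConfig(occupancy_a=1.2)

    def test_noiseless_forward_model_inverts_exactly(self):
        cfg = tp.SimConfig(prm_cv=0.0, seed=9)
        truth = tp.plan_truth(tp.make_proteome(cfg), cfg)
        prm = tp.simulate_prm(truth, cfg)
        est = tp.estimate_occupancy(prm, cfg.protein_ratio)
        assert est.a == pytest.approx(0.70, abs=1e-12)
        assert est.b == pytest.approx(0.04, abs=1e-12)
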