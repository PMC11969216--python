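"""Generator of trees and trait tables with known ground truth."""

import json
from pathlib import Path

import numpy as np
import pytest

import mutclock as mc
from mutclock.phylo import leaf_names

from conftest import dataset_xy


class TestYule:
    def test_two_tips_is_a_cherry(self):
        tree = mc.simulate_yule_tree(2, 1.0, 0)
        C = mc.brownian_vcv(tree)
        assert C.n == 2
        assert C.matrix[0, 0] == pytest.approx(C.matrix[1, 1])

    @pytest.mark.parametrize("seed", range(4))
    def test_always_ultrametric(self, seed):
        tree = mc.simulate_yule_tree(30, 2.0, seed)
        assert mc.is_ultrametric(tree, 1e-9)

    def test_deterministic_under_seed(self):
        t1 = mc.simulate_yule_tree(12, 1.0, 99)
        t2 = mc.simulate_yule_tree(12, 1.0, 99)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_mean_height_matches_pure_birth_expectation(self):
        """Crown age of an n-tip pure-birth tree: waiting times between the
        k-th and (k+1)-th splits are Exp(k * birth_rate), so the expected
        height is sum_{k=2..n} 1/(k * birth_rate).  Checked over 500 trees
        against that independent closed form."""
        n, lam, reps = 10, 1.3, 500
        heights = []
        for seed in range(reps):
            tree = mc.simulate_yule_tree(n, lam, seed)
            heights.append(float(np.diag(mc.brownian_vcv(tree).matrix)[0]))
        expected = sum(1.0 / (k * lam) for k in range(2, n + 1))
        sd = np.std(heights, ddof=1)
        assert abs(np.mean(heights) - expected) < 3 * sd / np.sqrt(reps)


class TestTraits:
    def test_noiseless_generator_recovers_slope_exactly(self):
        cfg = mc.GeneratorConfig(n_species=20, sigma2_bm=0.0, gt_error_sd=0.0, seed=5)
        ds = mc.generate_dataset(cfg)
        table, tree, _ = mc.match_to_tree(ds.rates_table(), ds.tree)
        y, x = dataset_xy(table)
        fit = mc.fit_pgls(y, x, mc.brownian_vcv(tree))
        assert fit.slope == pytest.approx(cfg.true_slope, abs=1e-10)
        assert fit.intercept == pytest.approx(cfg.true_intercept, abs=1e-9)

    def test_brownian_simulation_deterministic(self):
        tree = mc.simulate_yule_tree(10, 1.0, 3)
        v1 = mc.synthetic.simulate_brownian(tree, 0.2, np.random.default_rng(1))
        v2 = mc.synthetic.simulate_brownian(tree, 0.2, np.random.default_rng(1))
        assert v1 == v2

    def test_brownian_tip_covariance_matches_vcv(self):
        """Empirical covariance of simulated tip values over 2000 replicates
        matches rate * C entrywise within 3 standard errors."""
        tree = mc.simulate_yule_tree(10, 1.0, 17)
        C = mc.brownian_vcv(tree)
        rate, reps = 0.5, 2000
        names = list(C.species_order)
        draws = np.empty((reps, len(names)))
        rng = np.random.default_rng(2024)
        for r in range(reps):
            vals = mc.synthetic.simulate_brownian(tree, rate, rng)
            draws[r] = [vals[nm] for nm in names]
        emp = np.cov(draws, rowvar=False)
        target = rate * C.matrix
        # SE of a sample covariance of bivariate normals
        d = np.sqrt(np.diag(target))
        se = np.sqrt((target**2 + np.outer(d**2, d**2)) / reps)
        assert np.all(np.abs(emp - target) <= 3 * se)

    def test_group_sizes_sum_and_pipeline_closure(self):
        ds = mc.generate_dataset(mc.GeneratorConfig(n_species=133, n_groups=9, seed=0))
        assert ds.table["group"].value_counts().sum() == 133
        assert ds.table["group"].nunique() == 9
        table, tree, dropped = mc.match_to_tree(ds.rates_table(), ds.tree)
        assert dropped == [] and table.n == 133
        assert table.species == leaf_names(tree)

    def test_gt_error_induces_attenuation(self):
        """Injected generation-time error pushes the fitted slope below the
        generating value (errors-in-variables artifact, as designed)."""
        slopes = {}
        for sd in (0.0, 1.0):
            fits = []
            for seed in range(30):
                cfg = mc.GeneratorConfig(
                    n_species=60, gt_error_sd=sd, true_slope=0.0, seed=seed
                )
                ds = mc.generate_dataset(cfg)
                table, tree, _ = mc.match_to_tree(ds.rates_table(), ds.tree)
                y, x = dataset_xy(table)
                fits.append(mc.fit_pgls(y, x, mc.brownian_vcv(tree), lam=0.0).slope)
            slopes[sd] = np.mean(fits)
        assert slopes[0.0] > -0.1
        assert slopes[1.0] < slopes[0.0] - 0.2


class TestFixture:
    def test_write_read_round_trip(self, tmp_path):
        ds = mc.generate_dataset(mc.GeneratorConfig(n_species=25, n_groups=3, seed=13))
        paths = mc.write_fixture(ds, tmp_path / "fx")
        table = mc.read_species_table(paths["table"])
        np.testing.assert_allclose(
            table.data["mu_g"], ds.table["mu_g"], rtol=1e-12
        )
        tree = mc.phylo.read_newick(paths["tree"])
        np.testing.assert_allclose(
            mc.brownian_vcv(tree).matrix, mc.brownian_vcv(ds.tree).matrix, rtol=1e-9
        )
        truth = json.loads(paths["truth"].read_text())
        assert truth["seed"] == 13 and truth["n_species"] == 25

    def test_shipped_example_fixture_regenerates_byte_identically(self, tmp_path):
        """The fixture under examples/fixture is exactly what the generator
        produces from the config recorded in its truth.json."""
        shipped = Path(__file__).resolve().parent.parent / "examples" / "fixture"
        cfg = mc.GeneratorConfig(**json.loads((shipped / "truth.json").read_text()))
        regen = mc.write_fixture(mc.generate_dataset(cfg), tmp_path / "regen")
        for key, fname in (("table", "table.tsv"), ("tree", "tree.nwk"), ("truth", "truth.json")):
            assert regen[key].read_bytes() == (shipped / fname).read_bytes()

    def test_fixture_regenerates_byte_identically(self, tmp_path):
        cfg = mc.GeneratorConfig(n_species=15, n_groups=3, seed=4)
        p1 = mc.write_fixture(mc.generate_dataset(cfg), tmp_path / "a")
        p2 = mc.write_fixture(mc.generate_dataset(cfg), tmp_path / "b")
        for key in ("table", "tree", "truth"):
            assert p1[key].read_bytes() == p2[key].read_bytes()
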