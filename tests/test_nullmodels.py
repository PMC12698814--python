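"""Wood-volume weighting, community assembly, null models and SES."""

import numpy as np
import pandas as pd
import pytest

from leafvar import (
    VarianceModel,
    build_community_dataset,
    convergence_check,
    fit_pca,
    generate_design,
    null_shuffle,
    observed_indices,
    population_weights,
    richness_trend,
    run_null_models,
    simulate_allometry,
    simulate_traits,
    wood_volume,
)
from leafvar.nullmodels import _Assembler


class TestWoodVolume:
    def test_intercept(self):
        raw, clamped = wood_volume(0.0, 0.0)
        assert raw == pytest.approx(0.5412)
        assert clamped == pytest.approx(0.5412)

    def test_unit_product(self):
        raw, _ = wood_volume(1.0, 1.0)
        assert raw == pytest.approx(0.3427)

    def test_large_tree_clamped(self):
        raw, clamped = wood_volume(1.0, 10.0)
        assert raw < 0
        assert clamped == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            wood_volume(-0.1, 5.0)


class TestPopulationWeights:
    @staticmethod
    def _tables(species_sizes):
        """One plot; species -> list of basal_area*height products."""
        central, allom = [], []
        for sp, products in species_sizes.items():
            for i, prod in enumerate(products):
                tid = f"P1:{sp}:C{i}"
                central.append({"plot_id": "P1", "species_id": sp, "tree_id": tid})
                allom.append(
                    {"tree_id": tid, "basal_area": prod, "height": 1.0}
                )
        return pd.DataFrame(central), pd.DataFrame(allom)

    def test_monoculture_weight_is_one(self):
        w = population_weights(*self._tables({"A": [0.5, 0.7]}))
        assert w["weight"].tolist() == [1.0]

    def test_identical_species_split_evenly(self):
        w = population_weights(*self._tables({"A": [0.5, 0.5], "B": [0.5, 0.5]}))
        assert np.allclose(w["weight"], 0.5)

    def test_two_to_one_volume_ratio(self):
        # products chosen so summed clamped WV is exactly 2:1
        # WV(0,1) = 0.5412 per tree
        tabs = self._tables({"A": [0.0, 0.0], "B": [0.0]})
        w = population_weights(*tabs).set_index("species_id")["weight"]
        assert w["A"] == pytest.approx(2.0 / 3.0)
        assert w["B"] == pytest.approx(1.0 / 3.0)

    def test_all_clamped_falls_back_to_equal(self):
        tabs = self._tables({"A": [10.0], "B": [12.0]})  # raw WV negative
        with pytest.warns(UserWarning):
            w = population_weights(*tabs)
        assert np.allclose(w["weight"], 0.5)

    def test_form_factor_mode(self):
        tabs = self._tables({"A": [2.0], "B": [1.0]})
        w = population_weights(*tabs, form_factor=0.5).set_index("species_id")["weight"]
        assert w["A"] == pytest.approx(2.0 / 3.0)


@pytest.fixture(scope="module")
def small_dataset():
    design = generate_design(
        seed=0,
        n_species=4,
        richness_levels=(1, 2),
        plots_per_species_per_level=2,
        trees_per_population=4,
        mortality=None,
        central_trees_per_plot=8,
    )
    vm = VarianceModel(gamma_intra=0.0, gamma_ind=0.0)
    traits = simulate_traits(design, vm, seed=1)
    scores = fit_pca(traits, run_pa=False).scores
    allom = simulate_allometry(design, seed=2)
    weights = population_weights(design.central_trees, allom)
    return build_community_dataset(scores, weights, cells_per_dim=25, min_leaves=5)


class TestAssembly:
    def test_community_tpds_sum_to_one(self, small_dataset):
        asm = _Assembler(small_dataset)
        comm = asm.community_probs(asm.pop_probs())
        assert np.allclose(comm.sum(axis=1), 1.0, atol=1e-9)
        assert (comm >= 0).all()

    def test_monoculture_community_equals_population(self, small_dataset):
        asm = _Assembler(small_dataset)
        pop = asm.pop_probs()
        comm = asm.community_probs(pop)
        mono_plots = [
            (i, p)
            for i, p in enumerate(asm.plot_ids)
            if (asm.pops["plot_id"] == p).sum() == 1
        ]
        assert mono_plots
        for i, p in mono_plots:
            j = asm.pops.index[asm.pops["plot_id"] == p][0]
            assert np.allclose(comm[i], pop[j])

    def test_identical_populations_any_weights(self):
        # two species with identical trees: community TPD equals either population
        leaves = []
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((6, 2))
        for sp in ("A", "B"):
            for t in range(2):
                for leaf in range(6):
                    leaves.append(
                        {
                            "leaf_id": f"{sp}{t}{leaf}",
                            "tree_id": f"{sp}:T{t}",
                            "population_id": f"P1:{sp}",
                            "plot_id": "P1",
                            "species_id": sp,
                            "PC1": pts[leaf, 0],
                            "PC2": pts[leaf, 1],
                        }
                    )
        weights = pd.DataFrame(
            {"plot_id": ["P1", "P1"], "species_id": ["A", "B"], "weight": [0.8, 0.2]}
        )
        ds = build_community_dataset(
            pd.DataFrame(leaves), weights, cells_per_dim=20, min_leaves=5
        )
        asm = _Assembler(ds)
        pop = asm.pop_probs()
        comm = asm.community_probs(pop)
        assert np.allclose(comm[0], pop[0], atol=1e-12)

    def test_observed_indices_table(self, small_dataset):
        obs = observed_indices(small_dataset)
        assert set(obs.columns) == {"plot_id", "FRic", "FDiv"}
        assert (obs["FRic"] > 0).all()
        assert obs["FDiv"].between(0, 1).all()


class TestNullShuffle:
    @pytest.mark.parametrize(
        "scheme",
        [
            "random_population",
            "random_tree",
            "random_leaf",
            "population_restricted_random_leaf",
        ],
    )
    def test_composition_and_counts_preserved(self, small_dataset, scheme):
        shuffled = null_shuffle(small_dataset, scheme, seed=11)
        before = small_dataset.trees.groupby(["plot_id", "species_id"]).size()
        after = shuffled.trees.groupby(["plot_id", "species_id"]).size()
        pd.testing.assert_series_equal(before, after)

    def test_leaf_multiset_preserved_per_species(self, small_dataset):
        shuffled = null_shuffle(small_dataset, "random_leaf", seed=3)
        for sp in small_dataset.leaves["species_id"].unique():
            a = np.sort(
                small_dataset.leaves.loc[
                    small_dataset.leaves["species_id"] == sp, "PC1"
                ].to_numpy()
            )
            b = np.sort(
                shuffled.leaves.loc[shuffled.leaves["species_id"] == sp, "PC1"].to_numpy()
            )
            assert np.array_equal(a, b)

    def test_population_restriction_preserves_population_multisets(self, small_dataset):
        shuffled = null_shuffle(small_dataset, "population_restricted_random_leaf", seed=5)
        for pop in small_dataset.leaves["population_id"].unique():
            a = np.sort(
                small_dataset.leaves.loc[
                    small_dataset.leaves["population_id"] == pop, "PC2"
                ].to_numpy()
            )
            b = np.sort(
                shuffled.leaves.loc[shuffled.leaves["population_id"] == pop, "PC2"].to_numpy()
            )
            assert np.array_equal(a, b)

    def test_species_in_single_plot_identity_under_random_population(self):
        design = generate_design(
            seed=0,
            n_species=2,
            richness_levels=(1,),
            plots_per_species_per_level=1,
            trees_per_population=4,
            mortality=None,
            central_trees_per_plot=4,
        )
        traits = simulate_traits(design, VarianceModel(), seed=0)
        scores = fit_pca(traits, run_pa=False).scores
        weights = population_weights(
            design.central_trees, simulate_allometry(design, seed=1)
        )
        ds = build_community_dataset(scores, weights, cells_per_dim=15, min_leaves=5)
        shuffled = null_shuffle(ds, "random_population", seed=9)
        pd.testing.assert_frame_equal(
            shuffled.trees[["tree_id", "plot_id"]], ds.trees[["tree_id", "plot_id"]]
        )

    def test_unknown_scheme_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            null_shuffle(small_dataset, "bogus")


class TestRunNullModels:
    def test_ses_table_structure_and_reproducibility(self, small_dataset):
        ses, draws = run_null_models(
            small_dataset, n_sim=30, schemes=("random_tree",), seed=1, indices=("FRic",)
        )
        assert len(ses) == len(small_dataset.trees["plot_id"].unique())
        assert draws[("random_tree", "FRic")].shape == (30, len(ses))
        ses2, _ = run_null_models(
            small_dataset, n_sim=30, schemes=("random_tree",), seed=1, indices=("FRic",)
        )
        pd.testing.assert_frame_equal(ses, ses2)

    def test_ses_formula(self, small_dataset):
        ses, draws = run_null_models(
            small_dataset, n_sim=40, schemes=("random_tree",), seed=2, indices=("FRic",)
        )
        sim = draws[("random_tree", "FRic")]
        row = ses.iloc[0]
        i = list(ses["plot_id"]).index(row["plot_id"])
        expected = (row["observed"] - sim[:, i].mean()) / sim[:, i].std(ddof=1)
        assert row["ses"] == pytest.approx(expected)

    def test_degenerate_null_flagged_undefined(self):
        # a single monoculture plot: permutation changes nothing
        design = generate_design(
            seed=0,
            n_species=1,
            richness_levels=(1,),
            plots_per_species_per_level=1,
            trees_per_population=4,
            mortality=None,
            central_trees_per_plot=4,
        )
        traits = simulate_traits(design, VarianceModel(), seed=0)
        scores = fit_pca(traits, run_pa=False).scores
        weights = population_weights(
            design.central_trees, simulate_allometry(design, seed=1)
        )
        ds = build_community_dataset(scores, weights, cells_per_dim=15, min_leaves=5)
        ses, _ = run_null_models(
            ds, n_sim=20, schemes=("random_population",), seed=0, indices=("FRic",)
        )
        assert ses["undefined"].all()
        assert ses["ses"].isna().all()

    def test_leaf_scheme_runs_and_conserves_mass(self, small_dataset):
        ses, draws = run_null_models(
            small_dataset,
            n_sim=3,
            schemes=("population_restricted_random_leaf",),
            seed=4,
            indices=("FRic", "FDiv"),
        )
        assert np.isfinite(draws[("population_restricted_random_leaf", "FRic")]).all()
        assert (ses["null_sd"] >= 0).all()


class TestConvergence:
    def test_constant_draws(self):
        table, flags = convergence_check(np.full(50, 2.0))
        assert flags["sd_zero"]
        assert flags["mean_drift"] == 0.0
        assert not flags["flagged"]
        assert len(table) == 50

    def test_iid_draws_rarely_flagged(self):
        flagged = 0
        for s in range(20):
            x = np.random.default_rng(s).standard_normal(500)
            _, flags = convergence_check(x)
            flagged += flags["flagged"]
        assert flagged <= 1

    def test_minimum_draws(self):
        with pytest.raises(ValueError):
            convergence_check(np.arange(5))


class TestRichnessTrend:
    @staticmethod
    def _table(values_by_richness, species=("A", "B")):
        rows = []
        for sp in species:
            for r, vals in values_by_richness.items():
                for v in vals:
                    rows.append({"species_id": sp, "richness": r, "FRic": v})
        return pd.DataFrame(rows)

    def test_constant_index_zero_slope(self):
        t = self._table({1: [2.0, 2.0], 2: [2.0], 4: [2.0]})
        assert richness_trend(t, "FRic")["slope"] == pytest.approx(0.0)

    def test_exact_linear_slope(self):
        t = self._table({1: [0.0], 2: [-0.3], 4: [-0.6], 8: [-0.9]})
        assert richness_trend(t, "FRic")["slope"] == pytest.approx(-0.3)

    def test_single_level_rejected(self):
        t = self._table({2: [1.0, 2.0]})
        with pytest.raises(ValueError):
            richness_trend(t, "FRic")
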