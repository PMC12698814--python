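"""Simulation studies validating the pipeline end to end.

Each study generates synthetic data under stated conditions, runs the real
pipeline, and summarizes a recovery or calibration statistic:

* design replication counts (plots / trees / leaves of the default design);
* SES calibration -- under structureless data (no population-level effects,
  no richness dependence) standardized effect sizes should be centered on 0
  with unit spread;
* slope recovery -- a negative tree-level richness sensitivity
  (``gamma_intra < 0``) should surface as a negative intraspecific-FRic
  versus log2(richness) slope, and a zero sensitivity as a coin-flip sign;
* spectral segmentation recovery of planted independent wavelength blocks;
* calibration accuracy of the latent-variable regressor on the linear
  spectral forward model.

The problem sizes used here are the package's test-scale defaults; they are
documented in docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .axes import fit_pca
from .calibration import evaluate_model, fit_calibration, split_calibration
from .nullmodels import (
    build_community_dataset,
    population_weights,
    richness_trend,
    run_null_models,
)
from .preprocess import augment_features, trim_range
from .segmentation import segment_spectra
from .synthetic import (
    TRAITS,
    SpectraMatrix,
    SpectralForwardModel,
    VarianceModel,
    generate_design,
    simulate_allometry,
    simulate_spectra,
    simulate_traits,
)
from .tpd import bootstrap_tree_means, make_grid, population_tpd, fric


# ---------------------------------------------------------------------------
# Intraspecific FRic pipeline
# ---------------------------------------------------------------------------


def intraspecific_fric_table(
    traits: pd.DataFrame,
    seed: int = 0,
    bootstrap_B: int = 100,
    cells_per_dim: int = 50,
    min_trees: int = 3,
) -> pd.DataFrame:
    """Population-level FRic from a complete leaf trait table.

    Pipeline: trait PCA (PC1/PC2 leaf scores) -> bootstrap tree mean scores
    -> shared grid over all tree means -> one TPD per population with at
    least ``min_trees`` trees -> FRic.
    """
    scores = fit_pca(traits, run_pa=False).scores
    rng = np.random.default_rng(seed)
    rows = []
    for tree_id, sub in scores.groupby("tree_id", sort=True):
        m = bootstrap_tree_means(
            sub[["PC1", "PC2"]].to_numpy(float),
            B=bootstrap_B,
            seed=int(rng.integers(2**31)),
        )
        first = sub.iloc[0]
        rows.append(
            {
                "tree_id": tree_id,
                "population_id": first["population_id"],
                "plot_id": first["plot_id"],
                "species_id": first["species_id"],
                "richness": first["richness"],
                "PC1": m[0],
                "PC2": m[1],
            }
        )
    tree_means = pd.DataFrame(rows)
    grid = make_grid(tree_means[["PC1", "PC2"]].to_numpy(float), cells_per_dim)
    out = []
    for pop, sub in tree_means.groupby("population_id", sort=True):
        if len(sub) < min_trees:
            continue
        t = population_tpd(sub[["PC1", "PC2"]].to_numpy(float), grid, min_trees=min_trees)
        out.append(
            {
                "population_id": pop,
                "plot_id": sub.iloc[0]["plot_id"],
                "species_id": sub.iloc[0]["species_id"],
                "richness": sub.iloc[0]["richness"],
                "FRic": fric(t),
            }
        )
    return pd.DataFrame(out)


def slope_recovery_study(
    gamma_intra: float,
    n_seeds: int = 50,
    base_seed: int = 0,
    bootstrap_B: int = 100,
) -> dict:
    """Fraction of simulation seeds recovering a negative intraspecific-FRic
    slope against log2(richness).

    ``gamma_ind`` is held at 0 so the tree-level effect is isolated; with
    ``gamma_intra = 0`` the slope sign is a fair coin.
    """
    negatives = 0
    slopes = []
    for k in range(n_seeds):
        seed = base_seed + 1000 * k
        design = generate_design(seed=seed)
        vm = VarianceModel(gamma_intra=gamma_intra, gamma_ind=0.0)
        traits = simulate_traits(design, vm, seed=seed + 1)
        table = intraspecific_fric_table(traits, seed=seed + 2, bootstrap_B=bootstrap_B)
        res = richness_trend(table, "FRic")
        slopes.append(res["slope"])
        if res["slope"] < 0:
            negatives += 1
    return {
        "fraction_negative": negatives / n_seeds,
        "n_seeds": n_seeds,
        "mean_slope": float(np.mean(slopes)),
    }


# ---------------------------------------------------------------------------
# SES calibration
# ---------------------------------------------------------------------------


def structureless_variance_model() -> VarianceModel:
    """Trait model with no population effects and no richness dependence.

    Trees are then exchangeable within species across populations, so tree-
    permuting null models hold exactly and SES should be calibrated.
    """
    vm = VarianceModel(gamma_intra=0.0, gamma_ind=0.0)
    vm.sigma_pop = {t: 0.0 for t in TRAITS}
    return vm


def ses_calibration_study(
    seed: int = 0,
    n_designs: int = 7,
    n_sim: int = 500,
    scheme: str = "random_tree",
    cells_per_dim: int = 50,
) -> dict:
    """Distribution of community-FRic SES under exchangeable data.

    Generates ``n_designs`` full default designs with structureless traits,
    runs the null model on every plot, and pools the per-plot SES values
    (about 30 per design).
    """
    ses_vals = []
    vm = structureless_variance_model()
    for k in range(n_designs):
        s = seed + 1000 * k
        design = generate_design(seed=s)
        traits = simulate_traits(design, vm, seed=s + 1)
        scores = fit_pca(traits, run_pa=False).scores
        allom = simulate_allometry(design, seed=s + 2)
        weights = population_weights(design.central_trees, allom)
        ds = build_community_dataset(scores, weights, cells_per_dim=cells_per_dim)
        ses, _ = run_null_models(
            ds, n_sim=n_sim, schemes=(scheme,), seed=s + 3, indices=("FRic",)
        )
        ok = ses[~ses["undefined"]]
        ses_vals.extend(ok["ses"].tolist())
    arr = np.asarray(ses_vals)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)),
        "n_replicates": len(arr),
        "n_sim": n_sim,
    }


# ---------------------------------------------------------------------------
# Segmentation recovery
# ---------------------------------------------------------------------------


def planted_block_spectra(
    n_blocks: int,
    block_width: int = 50,
    n_leaves: int = 160,
    noise_sd: float = 0.05,
    seed: int = 0,
    wl_start: int = 400,
) -> tuple[SpectraMatrix, list[int]]:
    """Spectra driven by independent latent factors on contiguous blocks.

    Each block's wavelengths share one latent factor with a smooth loading
    profile plus independent noise.  Returns the spectra and the planted
    internal boundary positions (first wavelength of each block after the
    first).
    """
    rng = np.random.default_rng(seed)
    p = n_blocks * block_width
    wl = np.arange(wl_start, wl_start + p)
    values = np.zeros((n_leaves, p))
    boundaries = []
    for b in range(n_blocks):
        lo = b * block_width
        factor = rng.standard_normal(n_leaves)
        profile = 1.0 + 0.3 * np.sin(np.linspace(0, np.pi, block_width))
        values[:, lo : lo + block_width] = np.outer(factor, profile)
        if b > 0:
            boundaries.append(int(wl[lo]))
    values += noise_sd * rng.standard_normal(values.shape)
    leaf_ids = [f"L{i}" for i in range(n_leaves)]
    return SpectraMatrix(leaf_ids, wl, values), boundaries


def segmentation_recovery_study(
    n_blocks: int,
    n_seeds: int = 20,
    base_seed: int = 0,
    tol_nm: int = 3,
) -> dict:
    """Fraction of seeds where HSC-PA recovers the planted segmentation."""
    successes = 0
    for k in range(n_seeds):
        seed = base_seed + 100 * k
        spectra, planted = planted_block_spectra(n_blocks, seed=seed)
        tree = segment_spectra(spectra, n_iter=30, seed=seed + 1)
        segs = tree.segments
        if len(segs) != n_blocks:
            continue
        found = sorted(s.low for s in segs[1:])
        if all(
            abs(f - p) <= tol_nm for f, p in zip(found, sorted(planted))
        ):
            successes += 1
    return {"fraction_recovered": successes / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# Calibration accuracy
# ---------------------------------------------------------------------------


def calibration_study(
    seed: int = 0,
    n_leaves: int = 700,
    n_components: int = 12,
) -> dict:
    """Held-out R^2 of the latent-variable calibrator on clean forward data.

    Simulates leaves under the default design, generates low-noise spectra
    without sensor artifacts, trims to 400-2500 nm, augments features, fits
    PLS on a species-stratified 75% split and scores the 25% test set.
    """
    design = generate_design(seed=seed)
    traits = simulate_traits(design, VarianceModel(), seed=seed + 1).head(n_leaves)
    fm = SpectralForwardModel(noise_sd=0.0005, splice_sd=(0.0, 0.0), outlier_rate=0.0)
    spectra = simulate_spectra(traits, fm, seed=seed + 2, splice_artifacts=False)
    spectra = trim_range(spectra, 400, 2500)
    X = augment_features(spectra.values)
    samples = traits.reset_index(drop=True)
    train, test = split_calibration(samples, seed=seed + 3)
    model = fit_calibration(
        X[train.index.to_numpy()],
        train[TRAITS].to_numpy(float),
        family="pls",
        n_components=n_components,
    )
    ev = evaluate_model(model, X[test.index.to_numpy()], test[TRAITS].to_numpy(float))
    return {
        "r2": {t: float(ev.loc[t, "r2"]) for t in TRAITS},
        "min_r2": float(ev["r2"].min()),
        "n_train": len(train),
        "n_test": len(test),
    }


# ---------------------------------------------------------------------------
# Design counts
# ---------------------------------------------------------------------------


def design_counts(seed: int = 0) -> dict:
    """Plot/tree/leaf counts of the default design, before and after mortality."""
    full = generate_design(seed=seed, mortality=None)
    realized = generate_design(seed=seed)
    return {
        "n_plots": realized.n_plots,
        "n_trees_planned": full.n_trees_planned,
        "n_trees_realized": realized.n_trees_realized,
        "n_leaves": realized.n_leaves,
    }
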