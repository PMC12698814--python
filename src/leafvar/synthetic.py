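"""Synthetic tree-diversity-experiment designs, traits, spectra and allometry.

Emulates the sampling structure of a broken-stick biodiversity experiment:
a pool of ``n_species`` tree species planted in plots at richness levels
1, 2, 4 and 8, with each species sampled in a fixed number of plots per
level, a fixed number of trees per population (species x plot) and a fixed
number of leaves per tree (3 crown heights x 4 orientations).  On top of the
design, a hierarchical variance model generates per-leaf trait values with
population-, tree- and leaf-level random effects whose standard deviations
may shrink (or grow) with the log2 of plot species richness, and a linear
spectral forward model turns leaf traits into 1-nm reflectance spectra with
realistic sensor artifacts (splice steps between the three sensors of a
field spectroradiometer, smooth noise, occasional whole-spectrum outliers).

Every generator is deterministic given its seed, so each downstream stage of
the analysis can be tested against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRAITS = ["SLA", "LDMC", "C", "N", "P"]
TRAIT_UNITS = {"SLA": "mm2/mg", "LDMC": "mg/g", "C": "%", "N": "%", "P": "ug/g"}

CROWN_HEIGHTS = ("low", "mid", "high")
ORIENTATIONS = ("N", "E", "S", "W")


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


@dataclass
class DesignSpec:
    """Plots, populations, trees and sampled leaves of a diversity experiment.

    ``trees`` holds the sampled trees (``alive`` marks mortality losses;
    leaves exist only for living trees).  ``central_trees`` holds the
    designated central-area trees of every plot, used only for wood-volume
    weighting of community trait probability densities.
    """

    plots: pd.DataFrame
    populations: pd.DataFrame
    trees: pd.DataFrame
    leaves: pd.DataFrame
    central_trees: pd.DataFrame

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def n_trees_planned(self) -> int:
        return len(self.trees)

    @property
    def n_trees_realized(self) -> int:
        return int(self.trees["alive"].sum())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def validate(self) -> None:
        plots = self.plots
        for _, row in plots.iterrows():
            if len(row["species_set"]) != row["richness"]:
                raise ValueError(
                    f"plot {row['plot_id']}: species_set size != richness"
                )
        living = self.trees[self.trees["alive"]]
        counts = living.groupby("tree_id").size()
        if (counts != 1).any():
            raise ValueError("duplicate tree ids")
        per_tree = self.leaves.groupby("tree_id").size()
        if set(per_tree.index) != set(living["tree_id"]):
            raise ValueError("leaves must cover exactly the living trees")

    def write_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        plots = self.plots.copy()
        plots["species_set"] = plots["species_set"].map(lambda s: "|".join(s))
        plots.to_csv(outdir / "plots.csv", index=False)
        self.populations.to_csv(outdir / "populations.csv", index=False)
        self.trees.to_csv(outdir / "trees.csv", index=False)
        self.leaves.to_csv(outdir / "leaves.csv", index=False)
        self.central_trees.to_csv(outdir / "central_trees.csv", index=False)


def _broken_stick_sets(species: list[str], levels: tuple[int, ...]) -> dict[int, list[tuple[str, ...]]]:
    """Species compositions per richness level by recursive halving.

    The ordered pool is split in two equal halves for each subordinate
    richness level; the compositions at level R are the contiguous blocks of
    size R, so every species occurs in exactly one composition per level.
    """
    n = len(species)
    out: dict[int, list[tuple[str, ...]]] = {}
    for level in sorted(levels):
        if level > n:
            raise ValueError(f"richness level {level} exceeds pool size {n}")
        if n % level != 0:
            raise ValueError(f"pool size {n} not divisible by level {level}")
        out[level] = [tuple(species[i : i + level]) for i in range(0, n, level)]
    return out


def generate_design(
    seed: int = 0,
    n_species: int = 8,
    richness_levels: tuple[int, ...] = (1, 2, 4, 8),
    plots_per_species_per_level: int = 2,
    trees_per_population: int = 6,
    mortality: str | list[tuple[str, str, int]] | None = "default",
    central_trees_per_plot: int = 36,
) -> DesignSpec:
    """Generate a broken-stick diversity-experiment sampling design.

    With the defaults (8 species, levels {1,2,4,8}, 2 plots per species and
    level, 6 trees per population, 12 leaves per tree) the design has
    30 plots, 64 populations and 384 planned trees; the default mortality
    event reduces one monoculture population of the last species to 3 found
    trees, leaving 381 realized trees and 4572 leaves.

    ``mortality`` is a list of ``(plot_id, species_id, n_found)`` tuples,
    ``"default"`` for the built-in single-population event, or None.
    """
    if plots_per_species_per_level < 1:
        raise ValueError("plots_per_species_per_level must be >= 1")
    rng = np.random.default_rng(seed)
    species = [f"S{i + 1}" for i in range(n_species)]
    comps = _broken_stick_sets(species, tuple(richness_levels))

    plot_rows = []
    pid = 0
    for level in sorted(richness_levels):
        for comp in comps[level]:
            for _ in range(plots_per_species_per_level):
                pid += 1
                plot_rows.append(
                    {"plot_id": f"P{pid:02d}", "richness": level, "species_set": comp}
                )
    plots = pd.DataFrame(plot_rows)

    if mortality == "default":
        # one monoculture population of the last species is reduced to 3
        # found trees (a single-species high-mortality event)
        target = plots[
            (plots["richness"] == min(richness_levels))
            & (plots["species_set"].map(lambda s: s == (species[-1],)))
        ]
        mortality_list = (
            [(target.iloc[0]["plot_id"], species[-1], 3)] if len(target) else []
        )
    elif mortality is None:
        mortality_list = []
    else:
        mortality_list = list(mortality)
    dead_lookup = {(p, s): n for p, s, n in mortality_list}

    pop_rows, tree_rows, leaf_rows = [], [], []
    for _, plot in plots.iterrows():
        for sp in plot["species_set"]:
            n_found = dead_lookup.get((plot["plot_id"], sp), trees_per_population)
            pop_rows.append(
                {
                    "plot_id": plot["plot_id"],
                    "species_id": sp,
                    "population_id": f"{plot['plot_id']}:{sp}",
                    "n_trees": n_found,
                }
            )
            for t in range(trees_per_population):
                tree_id = f"{plot['plot_id']}:{sp}:T{t + 1}"
                alive = t < n_found
                tree_rows.append(
                    {
                        "tree_id": tree_id,
                        "plot_id": plot["plot_id"],
                        "species_id": sp,
                        "population_id": f"{plot['plot_id']}:{sp}",
                        "alive": alive,
                    }
                )
                if alive:
                    for h in CROWN_HEIGHTS:
                        for o in ORIENTATIONS:
                            leaf_rows.append(
                                {
                                    "leaf_id": f"{tree_id}:{h}:{o}",
                                    "tree_id": tree_id,
                                    "crown_height": h,
                                    "orientation": o,
                                }
                            )

    # central-area trees: a fixed-size block per plot for wood-volume
    # weighting, species allocated round-robin over the composition
    central_rows = []
    for _, plot in plots.iterrows():
        comp = plot["species_set"]
        order = list(comp)
        rng.shuffle(order)
        for i in range(central_trees_per_plot):
            sp = order[i % len(order)]
            central_rows.append(
                {
                    "plot_id": plot["plot_id"],
                    "species_id": sp,
                    "tree_id": f"{plot['plot_id']}:{sp}:C{i + 1}",
                }
            )

    design = DesignSpec(
        plots=plots,
        populations=pd.DataFrame(pop_rows),
        trees=pd.DataFrame(tree_rows),
        leaves=pd.DataFrame(leaf_rows),
        central_trees=pd.DataFrame(central_rows),
    )
    design.validate()
    return design


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

# Species mean trait values (leaf-economics-like gradient over 8 subtropical
# broadleaf species): SLA mm2/mg, LDMC mg/g, C %, N %, P ug/g.
DEFAULT_SPECIES_MEANS = pd.DataFrame(
    {
        "SLA": [10.5, 12.0, 14.0, 15.5, 17.0, 19.0, 21.5, 24.0],
        "LDMC": [460.0, 430.0, 400.0, 375.0, 350.0, 325.0, 295.0, 265.0],
        "C": [49.5, 48.8, 48.0, 47.3, 46.6, 45.9, 45.0, 44.2],
        "N": [1.45, 1.62, 1.80, 1.98, 2.17, 2.38, 2.60, 2.85],
        "P": [950.0, 1090.0, 1230.0, 1380.0, 1530.0, 1700.0, 1880.0, 2080.0],
    },
    index=[f"S{i + 1}" for i in range(8)],
)

# Leaf-economics-style correlation between the random effects of the five
# traits (shared by the population, tree and leaf levels).
DEFAULT_TRAIT_CORR = np.array(
    [
        #  SLA   LDMC    C     N     P
        [1.00, -0.60, -0.40, 0.50, 0.40],
        [-0.60, 1.00, 0.45, -0.40, -0.30],
        [-0.40, 0.45, 1.00, -0.25, -0.20],
        [0.50, -0.40, -0.25, 1.00, 0.50],
        [0.40, -0.30, -0.20, 0.50, 1.00],
    ]
)


@dataclass
class VarianceModel:
    """Hierarchical variance structure of leaf traits.

    Leaf value = species mean + population effect + tree effect + leaf
    effect.  Tree- and leaf-level SDs are multiplied by
    ``exp(gamma * log2(richness))``; negative gammas make within-population
    (``gamma_intra``) and within-tree (``gamma_ind``) variability shrink as
    plot richness grows, which is the structure the analysis is meant to
    recover.
    """

    species_means: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_SPECIES_MEANS.copy()
    )
    trait_corr: np.ndarray = field(default_factory=lambda: DEFAULT_TRAIT_CORR.copy())
    sigma_pop: dict[str, float] = field(
        default_factory=lambda: {"SLA": 0.8, "LDMC": 12.0, "C": 0.40, "N": 0.08, "P": 60.0}
    )
    sigma_tree0: dict[str, float] = field(
        default_factory=lambda: {"SLA": 1.5, "LDMC": 22.0, "C": 0.70, "N": 0.15, "P": 110.0}
    )
    sigma_leaf0: dict[str, float] = field(
        default_factory=lambda: {"SLA": 2.0, "LDMC": 28.0, "C": 0.90, "N": 0.20, "P": 140.0}
    )
    gamma_intra: float = -0.3
    gamma_ind: float = -0.1

    def validate(self) -> None:
        for d in (self.sigma_pop, self.sigma_tree0, self.sigma_leaf0):
            if any(v < 0 for v in d.values()):
                raise ValueError("variance components must be non-negative")
        w = np.linalg.eigvalsh(np.asarray(self.trait_corr))
        if w.min() < -1e-10:
            raise ValueError("trait correlation matrix is not positive semidefinite")

    def _cov(self, sigmas: dict[str, float], mult: float = 1.0) -> np.ndarray:
        s = np.array([sigmas[t] * mult for t in TRAITS])
        return np.asarray(self.trait_corr) * np.outer(s, s)



def _draw_mvn(rng: np.random.Generator, cov: np.ndarray, size: int | None = None) -> np.ndarray:
    """PSD-safe multivariate normal draw (handles zero/singular covariance)."""
    w, v = np.linalg.eigh(np.asarray(cov, float))
    a = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((size or 1, cov.shape[0]))
    out = z @ a.T
    return out[0] if size is None else out


def simulate_traits(
    design: DesignSpec, model: VarianceModel | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw per-leaf trait values under the hierarchical variance model.

    Returns a table with leaf/tree/population/plot/species keys, the plot
    richness and one column per trait.
    """
    model = model or VarianceModel()
    model.validate()
    rng = np.random.default_rng(seed)

    trees = design.trees[design.trees["alive"]].reset_index(drop=True)
    richness = design.plots.set_index("plot_id")["richness"]
    k = len(TRAITS)

    pop_cov = model._cov(model.sigma_pop)
    pops = design.populations.reset_index(drop=True)
    b_pop = {
        row["population_id"]: _draw_mvn(rng, pop_cov)
        for _, row in pops.iterrows()
    }

    b_tree = {}
    for _, row in trees.iterrows():
        r = richness[row["plot_id"]]
        cov = model._cov(model.sigma_tree0, np.exp(model.gamma_intra * np.log2(r)))
        b_tree[row["tree_id"]] = _draw_mvn(rng, cov)

    leaves = design.leaves.merge(
        trees[["tree_id", "plot_id", "species_id", "population_id"]], on="tree_id"
    )
    leaves["richness"] = leaves["plot_id"].map(richness)

    mu = model.species_means
    rows = np.stack([mu.loc[s, TRAITS].to_numpy(float) for s in leaves["species_id"]])
    rows += np.stack([b_pop[p] for p in leaves["population_id"]])
    rows += np.stack([b_tree[t] for t in leaves["tree_id"]])
    # leaf effects drawn in one batch per richness level (independent per leaf)
    for r in sorted(leaves["richness"].unique()):
        idx = np.where(leaves["richness"].to_numpy() == r)[0]
        cov = model._cov(model.sigma_leaf0, np.exp(model.gamma_ind * np.log2(r)))
        rows[idx] += _draw_mvn(rng, cov, size=len(idx))
    out = leaves[
        ["leaf_id", "tree_id", "population_id", "plot_id", "species_id", "richness"]
    ].copy()
    for j, t in enumerate(TRAITS):
        out[t] = rows[:, j]
    return out


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


def _vegetation_baseline(wl: np.ndarray) -> np.ndarray:
    """Smooth leaf-reflectance-like baseline over 350-2500 nm."""
    wl = wl.astype(float)
    r = np.full(wl.shape, 0.05)
    r += 0.06 * np.exp(-0.5 * ((wl - 550) / 40.0) ** 2)  # green peak
    r += 0.40 / (1.0 + np.exp(-(wl - 715) / 18.0))  # red edge to NIR plateau
    r -= 0.18 / (1.0 + np.exp(-(wl - 1350) / 60.0))  # SWIR decline
    r -= 0.16 * np.exp(-0.5 * ((wl - 1450) / 50.0) ** 2)  # water band
    r -= 0.20 * np.exp(-0.5 * ((wl - 1940) / 60.0) ** 2)  # water band
    r -= 0.05 * np.exp(-0.5 * ((wl - 2500) / 150.0) ** 2)
    return np.clip(r, 0.0, 1.0)


@dataclass
class SpectralForwardModel:
    """Linear trait-to-reflectance forward model with sensor artifacts.

    Each trait perturbs the baseline through one Gaussian absorption-like
    band; the perturbation is ``gain * (trait - ref) * band`` so the gain is
    expressed in reflectance units per trait unit around a reference value.
    Optional artifacts: smooth correlated noise, additive per-sensor splice
    steps at the 1000/1800 nm junctions, and rare whole-spectrum outliers.
    """

    wl_min: int = 350
    wl_max: int = 2500
    bands: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            # trait: (center nm, width nm, gain per trait unit)
            "SLA": (1210.0, 70.0, -0.0030),
            "LDMC": (1660.0, 60.0, 0.00035),
            "C": (1730.0, 55.0, 0.0120),
            "N": (2110.0, 70.0, -0.0400),
            "P": (2300.0, 55.0, -0.000035),
        }
    )
    trait_ref: dict[str, float] = field(
        default_factory=lambda: {"SLA": 17.0, "LDMC": 360.0, "C": 46.9, "N": 2.1, "P": 1480.0}
    )
    noise_sd: float = 0.002
    noise_corr_nm: float = 30.0
    splice_sd: tuple[float, float] = (0.015, 0.010)
    outlier_rate: float = 0.0
    outlier_magnitude: float = 0.25

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wl_min, self.wl_max + 1)

    def validate(self) -> None:
        for t, (c, w, _) in self.bands.items():
            if not (self.wl_min <= c <= self.wl_max):
                raise ValueError(f"band for {t} centered outside wavelength grid")
            if w <= 0:
                raise ValueError("band width must be positive")


@dataclass
class SpectraMatrix:
    """Leaves x wavelengths reflectance with row/column metadata."""

    leaf_ids: list[str]
    wavelengths: np.ndarray  # integer nm, strictly increasing, step 1
    values: np.ndarray  # (n_leaves, n_wavelengths)
    spliced: bool = False
    trimmed: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.leaf_ids), len(self.wavelengths)):
            raise ValueError("values shape inconsistent with leaf_ids/wavelengths")

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(
            list(self.leaf_ids),
            self.wavelengths.copy(),
            self.values.copy(),
            self.spliced,
            self.trimmed,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.wavelengths.astype(str))
        df.insert(0, "leaf_id", self.leaf_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectraMatrix":
        wl = np.array([int(c) for c in df.columns if c != "leaf_id"])
        return cls(list(df["leaf_id"]), wl, df.drop(columns="leaf_id").to_numpy(float))

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SpectraMatrix":
        return cls.from_frame(pd.read_csv(path))


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float, corr_nm: float) -> np.ndarray:
    """White noise smoothed by a Gaussian kernel along wavelengths."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    half = int(3 * corr_nm)
    x = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (x / corr_nm) ** 2)
    kern /= np.sqrt((kern**2).sum())  # preserve marginal SD
    out = np.apply_along_axis(lambda r: np.convolve(r, kern, mode="same"), 1, white)
    return sd * out


def simulate_spectra(
    leaf_traits: pd.DataFrame,
    model: SpectralForwardModel | None = None,
    seed: int = 0,
    splice_artifacts: bool = True,
) -> SpectraMatrix:
    """Generate reflectance spectra from a complete leaf trait table."""
    model = model or SpectralForwardModel()
    model.validate()
    if leaf_traits[TRAITS].isna().any().any():
        raise ValueError("trait table must be complete")
    rng = np.random.default_rng(seed)
    wl = model.wavelengths.astype(float)
    n = len(leaf_traits)

    base = _vegetation_baseline(wl)
    spectra = np.tile(base, (n, 1))
    for t, (c, w, g) in model.bands.items():
        band = np.exp(-0.5 * ((wl - c) / w) ** 2)
        dev = leaf_traits[t].to_numpy(float) - model.trait_ref[t]
        spectra += np.outer(g * dev, band)

    spectra += _smooth_noise(rng, spectra.shape, model.noise_sd, model.noise_corr_nm)

    if splice_artifacts and (model.splice_sd[0] > 0 or model.splice_sd[1] > 0):
        # additive per-leaf sensor offsets: VNIR (<=1000 nm), SWIR2 (>=1801 nm)
        d1 = rng.normal(0.0, model.splice_sd[0], n)
        d2 = rng.normal(0.0, model.splice_sd[1], n)
        spectra[:, wl <= 1000] += d1[:, None]
        spectra[:, wl >= 1801] += d2[:, None]

    if model.outlier_rate > 0:
        is_out = rng.random(n) < model.outlier_rate
        for i in np.where(is_out)[0]:
            center = rng.uniform(500, 2300)
            width = rng.uniform(150, 400)
            spectra[i] += model.outlier_magnitude * np.exp(
                -0.5 * ((wl - center) / width) ** 2
            ) * rng.choice([-1.0, 1.0])

    return SpectraMatrix(
        list(leaf_traits["leaf_id"]), model.wavelengths, np.clip(spectra, 0.0, 1.0)
    )


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------

DEFAULT_BA_MEAN = {f"S{i + 1}": v for i, v in enumerate([0.012, 0.010, 0.016, 0.014, 0.009, 0.011, 0.013, 0.008])}
DEFAULT_HEIGHT_MEAN = {f"S{i + 1}": v for i, v in enumerate([7.5, 6.8, 9.0, 8.2, 6.0, 7.0, 7.8, 5.5])}


def simulate_allometry(
    design: DesignSpec,
    seed: int = 0,
    ba_mean: dict[str, float] | None = None,
    height_mean: dict[str, float] | None = None,
    log_sd: float = 0.25,
) -> pd.DataFrame:
    """Log-normal basal area (m2) and height (m) for sampled + central trees."""
    rng = np.random.default_rng(seed)
    ba_mean = ba_mean or DEFAULT_BA_MEAN
    height_mean = height_mean or DEFAULT_HEIGHT_MEAN
    trees = pd.concat(
        [
            design.trees.loc[design.trees["alive"], ["tree_id", "plot_id", "species_id"]],
            design.central_trees[["tree_id", "plot_id", "species_id"]],
        ],
        ignore_index=True,
    )
    ba = np.array(
        [
            ba_mean[s] * np.exp(rng.normal(-0.5 * log_sd**2, log_sd))
            for s in trees["species_id"]
        ]
    )
    h = np.array(
        [
            height_mean[s] * np.exp(rng.normal(-0.5 * log_sd**2, log_sd))
            for s in trees["species_id"]
        ]
    )
    out = trees.copy()
    out["basal_area"] = ba
    out["height"] = h
    return out


# ---------------------------------------------------------------------------
# Config plumbing
# ---------------------------------------------------------------------------


def generator_config_from_json(path: str | Path) -> dict:
    """Read a JSON config holding keyword arguments for the generators."""
    with open(path) as fh:
        return json.load(fh)
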