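"""Community functional diversity from hierarchical TPDs, and null models.

Community trait probability densities are assembled bottom-up: leaf scores
-> one TPD per tree -> population TPDs (equal-weight mean of member tree
TPDs) -> community TPD (populations weighted by the summed wood volume of
each species' central-area trees).  Four permutation null models randomize
different organizational levels while preserving plot species composition
and abundances exactly:

* ``random_population`` -- within each species, permute its population TPDs
  across the plots containing that species.
* ``random_tree`` -- within each species, permute trees across its
  populations, preserving per-population tree counts.
* ``random_leaf`` -- within each species, permute leaf records across its
  trees, preserving per-tree leaf counts.
* ``population_restricted_random_leaf`` -- within each population, permute
  leaf records across its trees.

Observed functional diversity is compared with the null distribution
through standardized effect sizes, SES = (FD_obs - mean(FD_sim)) / SD(FD_sim).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tpd import TPD, TraitGrid, fdiv, fric, make_grid, tree_tpd

NULL_SCHEMES = (
    "random_population",
    "random_tree",
    "random_leaf",
    "population_restricted_random_leaf",
)

WOOD_VOLUME_COEFFS = (0.5412, -0.1985)


# ---------------------------------------------------------------------------
# Wood volume and species weights
# ---------------------------------------------------------------------------


def wood_volume(
    basal_area: np.ndarray | float,
    height: np.ndarray | float,
    coeffs: tuple[float, float] = WOOD_VOLUME_COEFFS,
) -> tuple[np.ndarray, np.ndarray]:
    """Tree wood volume (m3) from basal area (m2) and height (m).

    ``WV = a + b * basal_area * height`` with the default site-calibrated
    coefficients.  Returns ``(raw, clamped)``: the formula can go negative
    for large trees, so weighting uses the value clamped at zero while the
    raw value is also reported.
    """
    ba = np.asarray(basal_area, float)
    h = np.asarray(height, float)
    if np.any(ba < 0) or np.any(h < 0):
        raise ValueError("basal area and height must be non-negative")
    a, b = coeffs
    raw = a + b * ba * h
    return raw, np.clip(raw, 0.0, None)


def population_weights(
    central_trees: pd.DataFrame,
    allometry: pd.DataFrame,
    coeffs: tuple[float, float] = WOOD_VOLUME_COEFFS,
    form_factor: float | None = None,
) -> pd.DataFrame:
    """Species weights per plot from central-area wood volume.

    For every plot, each member species' weight is proportional to the sum
    of (clamped) wood volumes of that species' central-area trees,
    normalized to sum to 1.  ``form_factor`` switches to the alternative
    ``WV = f * basal_area * height`` form.  A plot whose weights all clamp
    to zero falls back to equal weights with a warning.
    """
    merged = central_trees.merge(
        allometry[["tree_id", "basal_area", "height"]], on="tree_id"
    )
    if form_factor is not None:
        wv = form_factor * merged["basal_area"] * merged["height"]
        merged["wv"] = np.clip(wv, 0.0, None)
    else:
        _, clamped = wood_volume(merged["basal_area"], merged["height"], coeffs)
        merged["wv"] = clamped
    rows = []
    for plot, sub in merged.groupby("plot_id"):
        sums = sub.groupby("species_id")["wv"].sum()
        total = sums.sum()
        if total == 0:
            warnings.warn(f"plot {plot}: all wood volumes clamp to 0; equal weights")
            w = pd.Series(1.0 / len(sums), index=sums.index)
        else:
            w = sums / total
        for sp, val in w.items():
            rows.append({"plot_id": plot, "species_id": sp, "weight": float(val)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass
class CommunityDataset:
    """Leaf scores with hierarchy keys plus everything needed for assembly.

    ``tree_probs`` rows are the (thresholded, renormalized) TPD vectors of
    the retained trees on the shared grid.
    """

    leaves: pd.DataFrame  # leaf_id, tree_id, population_id, plot_id, species_id + scores
    grid: TraitGrid
    weights: pd.DataFrame  # plot_id, species_id, weight
    score_cols: tuple[str, ...] = ("PC1", "PC2")
    alpha: float = 0.95
    min_leaves: int = 5
    trees: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    tree_probs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.trees is None:
            self.trees, self.tree_probs = _tree_probs_from_leaves(
                self.leaves, list(self.score_cols), self.grid, self.alpha, self.min_leaves
            )


def _tree_probs_from_leaves(
    leaves: pd.DataFrame, score_cols, grid: TraitGrid, alpha: float, min_leaves: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """One TPD row per tree with enough leaves; short trees are dropped."""
    rows, probs = [], []
    for tree_id, sub in leaves.groupby("tree_id", sort=True):
        if len(sub) < min_leaves:
            continue
        t = tree_tpd(sub[score_cols].to_numpy(float), grid, alpha, min_leaves)
        first = sub.iloc[0]
        rows.append(
            {
                "tree_id": tree_id,
                "population_id": first["population_id"],
                "plot_id": first["plot_id"],
                "species_id": first["species_id"],
            }
        )
        probs.append(t.prob)
    return pd.DataFrame(rows), np.asarray(probs)


def build_community_dataset(
    leaf_scores: pd.DataFrame,
    weights: pd.DataFrame,
    grid: TraitGrid | None = None,
    score_cols: tuple[str, ...] = ("PC1", "PC2"),
    cells_per_dim: int = 50,
    alpha: float = 0.95,
    min_leaves: int = 5,
) -> CommunityDataset:
    """Assemble the shared grid and per-tree TPDs for null-model analyses."""
    if grid is None:
        grid = make_grid(leaf_scores[list(score_cols)].to_numpy(float), cells_per_dim)
    return CommunityDataset(
        leaves=leaf_scores,
        grid=grid,
        weights=weights,
        score_cols=tuple(score_cols),
        alpha=alpha,
        min_leaves=min_leaves,
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _fd_indices(prob: np.ndarray, grid: TraitGrid) -> tuple[float, float]:
    t = TPD(grid=grid, prob=prob, bandwidth=np.eye(grid.ndim), alpha=1.0, n_points=0)
    try:
        fd = fdiv(t)
    except ValueError:  # single occupied cell
        fd = np.nan
    return fric(t), fd


class _Assembler:
    """Precomputed index structures for fast repeated community assembly."""

    def __init__(self, ds: CommunityDataset):
        self.ds = ds
        trees = ds.trees.reset_index(drop=True)
        self.trees = trees
        pops = (
            trees.groupby("population_id", sort=True)
            .agg(plot_id=("plot_id", "first"), species_id=("species_id", "first"), n=("tree_id", "size"))
            .reset_index()
        )
        self.pops = pops
        # slot ordering: tree rows sorted by population, with reduceat bounds
        order = np.argsort(trees["population_id"].to_numpy(), kind="stable")
        self.slot_order = order
        pop_of_slot = trees["population_id"].to_numpy()[order]
        self.starts = np.concatenate(
            ([0], np.where(pop_of_slot[1:] != pop_of_slot[:-1])[0] + 1)
        )
        self.pop_ids_in_slot_order = pop_of_slot[self.starts]
        counts = np.diff(np.concatenate((self.starts, [len(order)])))
        self.counts = counts
        # align pops frame to reduceat output order
        self.pops = pops.set_index("population_id").loc[self.pop_ids_in_slot_order].reset_index()
        # plot x population weight matrix
        wkey = ds.weights.set_index(["plot_id", "species_id"])["weight"]
        self.plot_ids = sorted(self.pops["plot_id"].unique())
        W = np.zeros((len(self.plot_ids), len(self.pops)))
        for j, row in self.pops.iterrows():
            i = self.plot_ids.index(row["plot_id"])
            W[i, j] = wkey.get((row["plot_id"], row["species_id"]), 0.0)
        self.W = W / W.sum(axis=1, keepdims=True)
        # species -> tree row indices and population row indices
        self.species_tree_rows = {
            s: np.where(trees["species_id"].to_numpy() == s)[0]
            for s in trees["species_id"].unique()
        }
        self.species_pop_rows = {
            s: np.where(self.pops["species_id"].to_numpy() == s)[0]
            for s in self.pops["species_id"].unique()
        }

    def pop_probs(self, tree_assignment: np.ndarray | None = None) -> np.ndarray:
        """Population TPDs as equal-weight means of member tree TPDs.

        ``tree_assignment[i]`` is the tree-row occupying original slot i
        (identity when None).
        """
        T = self.ds.tree_probs
        assign = (
            np.arange(len(T)) if tree_assignment is None else tree_assignment
        )
        rows = T[assign[self.slot_order]]
        sums = np.add.reduceat(rows, self.starts, axis=0)
        return sums / self.counts[:, None]

    def community_probs(self, pop_probs: np.ndarray, pop_permutation: np.ndarray | None = None) -> np.ndarray:
        """Weighted sum of population TPDs per plot, renormalized."""
        P = pop_probs if pop_permutation is None else pop_probs[pop_permutation]
        comm = self.W @ P
        s = comm.sum(axis=1, keepdims=True)
        return comm / s

    def indices(self, comm: np.ndarray) -> pd.DataFrame:
        rows = []
        for i, plot in enumerate(self.plot_ids):
            fr, fd = _fd_indices(comm[i], self.ds.grid)
            rows.append({"plot_id": plot, "FRic": fr, "FDiv": fd})
        return pd.DataFrame(rows)


def community_tpd(dataset: CommunityDataset) -> pd.DataFrame:
    """Observed community TPD per plot, as a long frame of cell masses."""
    asm = _Assembler(dataset)
    comm = asm.community_probs(asm.pop_probs())
    frames = []
    centers = dataset.grid.centers
    for i, plot in enumerate(asm.plot_ids):
        df = pd.DataFrame(
            {f"axis{d + 1}_center": centers[:, d] for d in range(dataset.grid.ndim)}
        )
        df["probability"] = comm[i]
        df.insert(0, "plot_id", plot)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def observed_indices(dataset: CommunityDataset) -> pd.DataFrame:
    """Observed community FRic and FDiv per plot."""
    asm = _Assembler(dataset)
    return asm.indices(asm.community_probs(asm.pop_probs()))


# ---------------------------------------------------------------------------
# Null models
# ---------------------------------------------------------------------------


def null_shuffle(dataset: CommunityDataset, scheme: str, seed: int = 0) -> CommunityDataset:
    """One permuted copy of the dataset under a null-model scheme.

    Plot species compositions and per-species tree counts are preserved
    exactly; only the level the scheme targets is randomized.  Leaf-level
    schemes trigger a full recomputation of tree TPDs in the returned
    dataset.
    """
    if scheme not in NULL_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    leaves = dataset.leaves

    if scheme in ("random_population", "random_tree"):
        asm = _Assembler(dataset)
        trees = dataset.trees.copy().reset_index(drop=True)
        if scheme == "random_tree":
            assign = np.arange(len(trees))
            for s, rows in asm.species_tree_rows.items():
                assign[rows] = rng.permutation(rows)
            # slot i keeps its population; the tree occupying it is permuted
            new = trees.copy()
            new["tree_id"] = trees["tree_id"].to_numpy()[assign]
            probs = dataset.tree_probs[assign]
        else:  # random_population: permute whole populations across plots
            pop_map = {}
            for s, rows in asm.species_pop_rows.items():
                perm = rng.permutation(rows)
                for src, dst in zip(rows, perm):
                    pop_map[asm.pops.loc[src, "population_id"]] = asm.pops.loc[
                        dst, "plot_id"
                    ]
            new = trees.copy()
            new["plot_id"] = new["population_id"].map(pop_map)
            probs = dataset.tree_probs
        out = CommunityDataset(
            leaves=leaves,
            grid=dataset.grid,
            weights=dataset.weights,
            score_cols=dataset.score_cols,
            alpha=dataset.alpha,
            min_leaves=dataset.min_leaves,
            trees=new,
            tree_probs=probs,
        )
        return out

    # leaf-level schemes: permute score rows among leaf slots, recompute
    new_leaves = leaves.copy().reset_index(drop=True)
    strata = "species_id" if scheme == "random_leaf" else "population_id"
    score_cols = list(dataset.score_cols)
    vals = new_leaves[score_cols].to_numpy(float).copy()
    for _, sub in new_leaves.groupby(strata):
        idx = sub.index.to_numpy()
        vals[idx] = vals[rng.permutation(idx)]
    new_leaves[score_cols] = vals
    return CommunityDataset(
        leaves=new_leaves,
        grid=dataset.grid,
        weights=dataset.weights,
        score_cols=dataset.score_cols,
        alpha=dataset.alpha,
        min_leaves=dataset.min_leaves,
    )


def run_null_models(
    dataset: CommunityDataset,
    n_sim: int = 500,
    schemes=NULL_SCHEMES,
    seed: int = 0,
    indices=("FRic", "FDiv"),
) -> tuple[pd.DataFrame, dict]:
    """Null distributions and standardized effect sizes per plot and scheme.

    Returns ``(ses_table, draws)`` where ``draws[(scheme, index)]`` is an
    ``(n_sim, n_plots)`` array of simulated index values.  Population- and
    tree-level schemes reuse the precomputed TPDs they merely permute (the
    draws equal full recomputation because those TPDs depend only on the
    unit's own points); leaf-level schemes recompute tree TPDs per draw.
    SES is flagged undefined (NaN, ``undefined=True``) when the null SD is 0.
    """
    asm = _Assembler(dataset)
    obs = asm.indices(asm.community_probs(asm.pop_probs()))
    rng = np.random.default_rng(seed)
    draws: dict = {}
    n_plots = len(asm.plot_ids)

    for scheme in schemes:
        if scheme not in NULL_SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}")
        arr = {ix: np.empty((n_sim, n_plots)) for ix in indices}
        for b in range(n_sim):
            if scheme == "random_population":
                perm = np.arange(len(asm.pops))
                for s, rows in asm.species_pop_rows.items():
                    perm[rows] = rng.permutation(rows)
                comm = asm.community_probs(asm.pop_probs(), pop_permutation=perm)
            elif scheme == "random_tree":
                assign = np.arange(len(asm.trees))
                for s, rows in asm.species_tree_rows.items():
                    assign[rows] = rng.permutation(rows)
                comm = asm.community_probs(asm.pop_probs(assign))
            else:
                shuffled = null_shuffle(
                    dataset, scheme, seed=int(rng.integers(2**31))
                )
                sub_asm = _Assembler(shuffled)
                comm = sub_asm.community_probs(sub_asm.pop_probs())
            if "FRic" in arr:
                arr["FRic"][b] = (comm > 0).sum(axis=1) * dataset.grid.cell_volume
            if "FDiv" in arr:
                for i in range(n_plots):
                    _, fd = _fd_indices(comm[i], dataset.grid)
                    arr["FDiv"][b, i] = fd
        for ix in indices:
            draws[(scheme, ix)] = arr[ix]

    rows = []
    for scheme in schemes:
        for ix in indices:
            sim = draws[(scheme, ix)]
            mean = sim.mean(axis=0)
            sd = sim.std(axis=0, ddof=1)
            for i, plot in enumerate(asm.plot_ids):
                obs_val = float(obs.loc[obs["plot_id"] == plot, ix].iloc[0])
                undefined = sd[i] == 0
                rows.append(
                    {
                        "plot_id": plot,
                        "scheme": scheme,
                        "index": ix,
                        "observed": obs_val,
                        "null_mean": mean[i],
                        "null_sd": sd[i],
                        "ses": np.nan if undefined else (obs_val - mean[i]) / sd[i],
                        "undefined": bool(undefined),
                        "n_sim": n_sim,
                    }
                )
    return pd.DataFrame(rows), draws


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def convergence_check(null_draws: np.ndarray, drift_frac: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Running mean/SD of a null distribution versus number of draws.

    Flags instability when the mean drifts by more than
    ``drift_frac * SD(all draws)`` over the last decile of draws; an SD of
    zero is flagged separately.
    """
    x = np.asarray(null_draws, float).ravel()
    if len(x) < 10:
        raise ValueError("need at least 10 draws")
    n = np.arange(1, len(x) + 1)
    cmean = np.cumsum(x) / n
    csq = np.cumsum(x**2) / n
    var = np.clip(csq - cmean**2, 0.0, None)
    csd = np.sqrt(var * n / np.maximum(n - 1, 1))
    table = pd.DataFrame({"n": n, "running_mean": cmean, "running_sd": csd})
    sd_final = csd[-1]
    i90 = int(0.9 * len(x)) - 1
    drift = abs(cmean[-1] - cmean[i90])
    flags = {
        "sd_zero": bool(sd_final == 0),
        "mean_drift": float(drift),
        "flagged": bool(sd_final > 0 and drift > drift_frac * sd_final),
    }
    return table, flags


def richness_trend(
    index_table: pd.DataFrame,
    value_col: str,
    richness_col: str = "richness",
    species_col: str = "species_id",
) -> dict:
    """Species-demeaned OLS slope of an index on log2(richness).

    A recovery diagnostic for synthetic data: with tree-level variability
    shrinking in richer plots, intraspecific FRic should decline, giving a
    negative slope.
    """
    df = index_table.dropna(subset=[value_col]).reset_index(drop=True)
    if df[richness_col].nunique() < 2:
        raise ValueError("need at least 2 richness levels")
    x = np.log2(df[richness_col].to_numpy(float))
    y = df[value_col].to_numpy(float)
    for s, sub in df.groupby(species_col):
        idx = df.index.get_indexer(sub.index)
        y[idx] -= y[idx].mean()
        x[idx] -= x[idx].mean()
    if np.allclose(x.var(), 0):
        raise ValueError("no within-species richness contrast")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "pvalue": float(res.pvalue), "n": len(df)}
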