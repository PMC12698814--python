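"""Trait probability densities (TPDs) and the functional indices built on
them: functional richness (FRic), functional divergence (FDiv) and overlap.

A TPD is a Gaussian kernel density over trait space (here the 1- or 2-axis
PCA score space), discretized on a shared regular grid, truncated by
removing the lowest-density cells until at most ``1 - alpha`` of the mass is
dropped, and renormalized to sum to 1.  Kernel bandwidths come from a
two-stage plug-in estimate of the full (unconstrained) bandwidth matrix,
with a scaled-covariance fallback for tiny or degenerate samples.

Units are compiled at two organizational levels: one TPD per tree from its
leaf scores (intraindividual variability) and one TPD per population from
bootstrap tree mean scores (intraspecific variability).  All TPDs entering
a comparison must share one grid object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitGrid:
    """Regular rectangular grid over trait space (1 or 2 dimensions)."""

    edges: tuple[np.ndarray, ...]

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(e) - 1 for e in self.edges)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def cell_volume(self) -> float:
        return float(np.prod([e[1] - e[0] for e in self.edges]))

    @property
    def centers(self) -> np.ndarray:
        """(n_cells, ndim) cell centers, C-order over the dimensions."""
        axes = [0.5 * (e[:-1] + e[1:]) for e in self.edges]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def same_as(self, other: "TraitGrid") -> bool:
        return self is other or (
            self.ndim == other.ndim
            and all(np.array_equal(a, b) for a, b in zip(self.edges, other.edges))
        )


def make_grid(points: np.ndarray, cells_per_dim: int = 50, pad_frac: float = 0.05) -> TraitGrid:
    """Build one grid over the pooled range of all points to be compared.

    The range in each dimension is expanded by ``pad_frac`` on each side so
    kernel tails near the data boundary are not cut off abruptly.  Every TPD
    entering any comparison (overlap, null models) must use the same grid.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points to span a grid")
    edges = []
    for d in range(pts.shape[1]):
        lo, hi = pts[:, d].min(), pts[:, d].max()
        if hi == lo:
            raise ValueError(f"zero range in dimension {d}")
        pad = pad_frac * (hi - lo)
        edges.append(np.linspace(lo - pad, hi + pad, cells_per_dim + 1))
    return TraitGrid(edges=tuple(edges))


# ---------------------------------------------------------------------------
# Bandwidth selection
# ---------------------------------------------------------------------------


@dataclass
class BandwidthResult:
    H: np.ndarray  # (d, d) symmetric positive definite, squared-units scale
    fallback: bool = False


def _silverman_H(points: np.ndarray) -> np.ndarray:
    """Scaled-covariance (normal reference) bandwidth matrix."""
    n, d = points.shape
    cov = (
        np.atleast_2d(np.cov(points, rowvar=False)) if n > 1 else np.zeros((d, d))
    )
    cov = np.nan_to_num(cov)
    # floor degenerate directions so the kernel stays proper
    scale = max(np.abs(points).max(), 1.0)
    floor = (1e-3 * scale) ** 2
    w, v = np.linalg.eigh(cov)
    cov = (v * np.maximum(w, floor)) @ v.T
    factor = (4.0 / (d + 2.0)) ** (2.0 / (d + 4.0)) * n ** (-2.0 / (d + 4.0))
    return factor * cov


_HERMITE = {
    0: lambda t: np.ones_like(t),
    1: lambda t: t,
    2: lambda t: t**2 - 1.0,
    3: lambda t: t**3 - 3.0 * t,
    4: lambda t: t**4 - 6.0 * t**2 + 3.0,
}


def _psi_functionals(Z: np.ndarray, g: float, orders) -> dict[tuple[int, int], float]:
    """Kernel estimates of integrated density derivative functionals.

    ``psi_(a,b) = E[ d^(a+b) f / dx^a dy^b ]`` estimated with a scalar
    pilot bandwidth ``g`` on sphered data:
    ``psi_hat = n^-2 sum_ij D^(a,b) phi_g(Z_i - Z_j)``.  Derivatives of the
    product Gaussian use probabilists' Hermite polynomials.
    """
    n, d = Z.shape
    out = {r: 0.0 for r in orders}
    chunk = 256
    norm = (2.0 * np.pi * g * g) ** (-d / 2.0)
    for start in range(0, n, chunk):
        D = Z[start : start + chunk, None, :] - Z[None, :, :]  # (c, n, d)
        U = D / g
        phi = norm * np.exp(-0.5 * (U**2).sum(axis=-1))
        for (a, b) in orders:
            term = phi * _HERMITE[a](U[..., 0]) * (
                _HERMITE[b](U[..., 1]) if d == 2 else 1.0
            )
            # d^r phi_g(x) = (-1/g)^r He_r(x/g) phi_g(x); all orders used here
            # have |r| = 4, so the sign factor is +1
            out[(a, b)] += float(term.sum()) * g ** (-(a + b))
    return {r: v / (n * n) for r, v in out.items()}


def plugin_bandwidth(points: np.ndarray, min_n: int = 5) -> BandwidthResult:
    """Two-stage plug-in estimate of the unconstrained bandwidth matrix.

    The data are sphered with their sample covariance; fourth-order
    integrated density derivative functionals are estimated with a
    normal-scale scalar pilot; the asymptotic MISE, with those functionals
    in its bias term, is minimized over Cholesky-parametrized symmetric
    positive definite matrices; the optimum is mapped back to the original
    scale.  Samples smaller than ``min_n`` or with singular covariance fall
    back to the scaled-covariance rule (flagged).
    """
    X = np.atleast_2d(np.asarray(points, float))
    n, d = X.shape
    if d not in (1, 2):
        raise ValueError("plug-in bandwidth implemented for 1 or 2 dimensions")
    cov = np.atleast_2d(np.cov(X, rowvar=False)) if n > 1 else np.zeros((d, d))
    if n < min_n or np.linalg.matrix_rank(cov, tol=1e-12) < d or np.trace(cov) == 0:
        return BandwidthResult(_silverman_H(X if n > 1 else X + 0.0), fallback=True)

    w, v = np.linalg.eigh(cov)
    A = (v * np.sqrt(w)) @ v.T  # symmetric square root
    Ainv = (v * (1.0 / np.sqrt(w))) @ v.T
    Z = (X - X.mean(axis=0)) @ Ainv

    g = n ** (-1.0 / (d + 6.0))  # normal-scale-order pilot for 4th-order psi

    if d == 1:
        psi = _psi_functionals(Z[:, :1], g, [(4, 0)])
        psi4 = psi[(4, 0)]
        if psi4 <= 0:
            return BandwidthResult(_silverman_H(X), fallback=True)
        h2 = (1.0 / (2.0 * np.sqrt(np.pi) * psi4 * n)) ** (2.0 / 5.0)
        H = A @ np.array([[h2]]) @ A
        return BandwidthResult(H, fallback=False)

    orders = [(4, 0), (3, 1), (2, 2), (1, 3), (0, 4)]
    psi = _psi_functionals(Z, g, orders)

    def theta(H):
        h11, h12, h22 = H[0, 0], H[0, 1], H[1, 1]
        return (
            h11**2 * psi[(4, 0)]
            + 4.0 * h11 * h12 * psi[(3, 1)]
            + (2.0 * h11 * h22 + 4.0 * h12**2) * psi[(2, 2)]
            + 4.0 * h12 * h22 * psi[(1, 3)]
            + h22**2 * psi[(0, 4)]
        )

    RK = (4.0 * np.pi) ** (-d / 2.0)

    def amise(params):
        l11, l21, l22 = np.exp(params[0]), params[1], np.exp(params[2])
        L = np.array([[l11, 0.0], [l21, l22]])
        H = L @ L.T
        detH = l11**2 * l22**2
        th = theta(H)
        if th <= 0:
            th = 1e-12
        return RK / (n * np.sqrt(detH)) + 0.25 * th

    H0 = _silverman_H(Z)
    L0 = np.linalg.cholesky(H0)
    x0 = np.array([np.log(L0[0, 0]), L0[1, 0], np.log(L0[1, 1])])
    pre = minimize(amise, x0, method="BFGS", options={"gtol": 1e-10})
    res = minimize(
        amise,
        pre.x if np.isfinite(pre.fun) else x0,
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-14, "maxiter": 2000},
    )
    l11, l21, l22 = np.exp(res.x[0]), res.x[1], np.exp(res.x[2])
    L = np.array([[l11, 0.0], [l21, l22]])
    Hz = L @ L.T
    if theta(Hz) <= 0 or not np.isfinite(Hz).all():
        return BandwidthResult(_silverman_H(X), fallback=True)
    return BandwidthResult(A @ Hz @ A, fallback=False)


# ---------------------------------------------------------------------------
# TPD estimation
# ---------------------------------------------------------------------------


@dataclass
class TPD:
    """A discretized, thresholded, renormalized trait probability density."""

    grid: TraitGrid
    prob: np.ndarray  # (n_cells,), >= 0, sums to 1
    bandwidth: np.ndarray
    alpha: float
    n_points: int
    fallback_bandwidth: bool = False

    def to_frame(self) -> pd.DataFrame:
        centers = self.grid.centers
        cols = {f"axis{d + 1}_center": centers[:, d] for d in range(self.grid.ndim)}
        cols["probability"] = self.prob
        return pd.DataFrame(cols)


def _gaussian_density(points: np.ndarray, centers: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Mean Gaussian kernel density of ``points`` at ``centers``."""
    n, d = points.shape
    L = np.linalg.cholesky(H)
    norm = (2.0 * np.pi) ** (-d / 2.0) / np.prod(np.diag(L))
    out = np.empty(len(centers))
    chunk = max(1, 5_000_000 // max(n, 1))
    for start in range(0, len(centers), chunk):
        diff = centers[start : start + chunk, None, :] - points[None, :, :]
        sol = np.linalg.solve(L, diff.reshape(-1, d).T).T.reshape(diff.shape)
        q = (sol**2).sum(axis=-1)
        out[start : start + chunk] = norm * np.exp(-0.5 * q).mean(axis=1)
    return out


def _threshold(prob: np.ndarray, alpha: float) -> np.ndarray:
    """Zero lowest-density cells without dropping more than 1 - alpha mass."""
    if alpha >= 1.0:
        return prob / prob.sum()
    order = np.argsort(prob, kind="stable")
    cum = np.cumsum(prob[order])
    drop = order[cum <= (1.0 - alpha) + 1e-12]
    out = prob.copy()
    out[drop] = 0.0
    s = out.sum()
    if s == 0:  # pathological: keep the single densest cell
        out[np.argmax(prob)] = 1.0
        return out
    return out / s


def estimate_tpd(
    points: np.ndarray,
    grid: TraitGrid,
    H: np.ndarray | BandwidthResult | None = None,
    alpha: float = 0.95,
) -> TPD:
    """Kernel trait probability density on a shared grid.

    The Gaussian kernel density is evaluated at cell centers and multiplied
    by the cell volume; after renormalizing over the grid, the lowest-density
    cells are zeroed until at most ``1 - alpha`` of the mass has been
    removed (never overshooting past the cell that crosses the quantile),
    and the density is renormalized to sum to 1.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[1] != grid.ndim:
        raise ValueError("points dimensionality does not match grid")
    fallback = False
    if H is None:
        bw = plugin_bandwidth(pts)
        H, fallback = bw.H, bw.fallback
    elif isinstance(H, BandwidthResult):
        H, fallback = H.H, H.fallback
    H = np.atleast_2d(np.asarray(H, float))
    dens = _gaussian_density(pts, grid.centers, H)
    prob = dens * grid.cell_volume
    total = prob.sum()
    if total <= 0:
        inside = np.ones(len(pts), bool)
        for d in range(grid.ndim):
            inside &= (pts[:, d] >= grid.edges[d][0]) & (pts[:, d] <= grid.edges[d][-1])
        if not inside.any():
            raise ValueError("all probability mass falls outside the grid")
        # kernel far narrower than the grid resolution (degenerate sample):
        # place each point's mass in the cell containing it
        prob = np.zeros(grid.n_cells)
        centers = grid.centers
        for x in pts[inside]:
            prob[np.argmin(((centers - x) ** 2).sum(axis=1))] += 1.0
        total = prob.sum()
    prob = _threshold(prob / total, alpha)
    return TPD(
        grid=grid,
        prob=prob,
        bandwidth=H,
        alpha=alpha,
        n_points=len(pts),
        fallback_bandwidth=fallback,
    )


# ---------------------------------------------------------------------------
# Indices
# ---------------------------------------------------------------------------


def fric(tpd: TPD) -> float:
    """Functional richness: occupied trait-space volume after thresholding."""
    return float((tpd.prob > 0).sum() * tpd.grid.cell_volume)


def fdiv(tpd: TPD) -> float:
    """Functional divergence: mass displacement toward the volume's edge.

    With g the unweighted centroid of occupied cell centers, d_i the cell
    distances to g and d-bar their unweighted mean:
    ``FDiv = (sum_i p_i (d_i - dbar) + dbar) / (sum_i p_i |d_i - dbar| + dbar)``,
    bounded in [0, 1].
    """
    occ = tpd.prob > 0
    if occ.sum() < 2:
        raise ValueError("FDiv needs at least 2 occupied cells")
    centers = tpd.grid.centers[occ]
    p = tpd.prob[occ]
    g = centers.mean(axis=0)
    dist = np.sqrt(((centers - g) ** 2).sum(axis=1))
    dbar = dist.mean()
    dd = float((p * (dist - dbar)).sum())
    dabs = float((p * np.abs(dist - dbar)).sum())
    return float((dd + dbar) / (dabs + dbar))


def overlap(a: TPD, b: TPD) -> float:
    """Shared probability mass between two TPDs on the same grid."""
    if not a.grid.same_as(b.grid):
        raise ValueError("TPDs must share one grid")
    return float(np.minimum(a.prob, b.prob).sum())


# ---------------------------------------------------------------------------
# Organizational units
# ---------------------------------------------------------------------------


def tree_tpd(
    leaf_scores: np.ndarray, grid: TraitGrid, alpha: float = 0.95, min_leaves: int = 5
) -> TPD:
    """Intraindividual TPD of one tree from its leaf scores."""
    pts = np.atleast_2d(np.asarray(leaf_scores, float))
    if len(pts) < min_leaves:
        raise ValueError(f"tree has {len(pts)} leaves; needs >= {min_leaves}")
    return estimate_tpd(pts, grid, alpha=alpha)


def bootstrap_tree_means(
    leaf_scores: np.ndarray, B: int = 999, seed: int = 0
) -> np.ndarray:
    """Bootstrap estimate of a tree's mean scores.

    Mean of ``B`` bootstrap-resample means of the tree's leaf rows; converges
    to the arithmetic mean as B grows and is reproducible given the seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    pts = np.atleast_2d(np.asarray(leaf_scores, float))
    if len(pts) < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pts), size=(B, len(pts)))
    return pts[idx].mean(axis=1).mean(axis=0)


def population_tpd(
    tree_means: np.ndarray, grid: TraitGrid, alpha: float = 0.95, min_trees: int = 3
) -> TPD:
    """Intraspecific TPD of one population from its trees' mean scores."""
    pts = np.atleast_2d(np.asarray(tree_means, float))
    if len(pts) < min_trees:
        raise ValueError(f"population has {len(pts)} trees; needs >= {min_trees}")
    return estimate_tpd(pts, grid, alpha=alpha)


def intraspecific_overlap(tree_tpds: list[TPD]) -> float:
    """Mean pairwise overlap between conspecific trees of one population."""
    if len(tree_tpds) < 2:
        raise ValueError("need at least 2 tree TPDs")
    vals = [
        overlap(tree_tpds[i], tree_tpds[j])
        for i in range(len(tree_tpds))
        for j in range(i + 1, len(tree_tpds))
    ]
    return float(np.mean(vals))
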