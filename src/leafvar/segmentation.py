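"""Recursive segmentation of reflectance spectra (hierarchical spectral
clustering with parallel analysis).

The full wavelength range is tested with Horn's parallel analysis; while a
block of wavelengths retains more than one principal component, its
wavelengths are split into two groups by spectral clustering on a
squared-correlation affinity, each group is broken into maximal contiguous
runs, and the procedure recurses.  Terminal segments retain exactly one
component (or are flagged degenerate) and their first principal component
scores serve as per-leaf "spectral traits".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering

from .axes import horn_pa
from .synthetic import SpectraMatrix


@dataclass
class SegmentNode:
    """A contiguous wavelength block visited during recursion."""

    low: int  # nm, inclusive
    high: int  # nm, inclusive
    n_retained: int
    depth: int
    children: list = field(default_factory=list)

    @property
    def is_terminal(self) -> bool:
        return not self.children

    @property
    def width(self) -> int:
        return self.high - self.low + 1


@dataclass
class Segment:
    """A terminal segment with its leading principal component."""

    segment_id: int
    low: int
    high: int
    n_retained: int
    degenerate: bool
    loading: np.ndarray  # PC1 loading over the segment's wavelengths
    scores: np.ndarray  # per-leaf PC1 score


@dataclass
class SegmentTree:
    root: SegmentNode
    segments: list[Segment]
    wavelengths: np.ndarray

    @property
    def retained_segments(self) -> list[Segment]:
        return [s for s in self.segments if not s.degenerate]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "segment_id": s.segment_id,
                    "low_nm": s.low,
                    "high_nm": s.high,
                    "width_nm": s.high - s.low + 1,
                    "n_retained": s.n_retained,
                    "degenerate": s.degenerate,
                }
                for s in self.segments
            ]
        )

    def scores_frame(self, leaf_ids) -> pd.DataFrame:
        out = pd.DataFrame({"leaf_id": leaf_ids})
        for s in self.retained_segments:
            out[f"seg{s.segment_id}"] = s.scores
        return out


def _block_pc1(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PC1 loading and scores of a standardized wavelength block."""
    sd = block.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (block - block.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    v1 = vt[0]
    if v1[np.argmax(np.abs(v1))] < 0:
        v1 = -v1
    return v1, Z @ v1


def segment_scores(spectra: SpectraMatrix, low: int, high: int) -> np.ndarray:
    """PC1 scores of the wavelength block [low, high] (centered/scaled).

    The sign convention puts a positive loading on the wavelength with the
    largest absolute loading; scores have exactly zero mean.
    """
    wl = spectra.wavelengths
    sel = (wl >= low) & (wl <= high)
    if sel.sum() < 2:
        raise ValueError("segment narrower than 2 wavelengths")
    _, scores = _block_pc1(spectra.values[:, sel])
    return scores


def _contiguous_runs(indices: np.ndarray) -> list[np.ndarray]:
    """Split sorted integer indices into maximal contiguous runs."""
    if len(indices) == 0:
        return []
    breaks = np.where(np.diff(indices) > 1)[0] + 1
    return np.split(indices, breaks)


def _split_block(values: np.ndarray, idx: np.ndarray, seed: int) -> list[np.ndarray]:
    """2-way spectral clustering of wavelengths on squared correlation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr = np.corrcoef(values[:, idx], rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    affinity = corr**2
    np.fill_diagonal(affinity, 1.0)
    sc = SpectralClustering(
        n_clusters=2,
        affinity="precomputed",
        random_state=seed,
        assign_labels="kmeans",
        n_init=10,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = sc.fit_predict(affinity)
    parts = []
    for lab in (0, 1):
        parts.extend(_contiguous_runs(idx[labels == lab]))
    parts.sort(key=lambda a: a[0])
    return parts


def segment_spectra(
    spectra: SpectraMatrix,
    n_iter: int = 30,
    min_width: int = 5,
    max_depth: int = 12,
    seed: int = 0,
) -> SegmentTree:
    """Recursively segment the spectrum until each block keeps one component.

    Parallel-analysis randomness and clustering initialization are seeded;
    the terminal segments partition the wavelength range exactly.  Blocks
    narrower than ``min_width``, deeper than ``max_depth`` or retaining no
    component are terminal and flagged degenerate unless they retain exactly
    one component.
    """
    values = spectra.values
    if not np.isfinite(values).all():
        raise ValueError("non-finite reflectance values")
    wl = spectra.wavelengths
    rng = np.random.default_rng(seed)

    def recurse(idx: np.ndarray, depth: int) -> SegmentNode:
        if len(idx) == 1:  # single wavelength trivially carries one component
            return SegmentNode(int(wl[idx[0]]), int(wl[idx[0]]), 1, depth)
        block = values[:, idx]
        try:
            _, n_ret = horn_pa(block, n_iter=n_iter, seed=int(rng.integers(2**31)))
        except ValueError:  # constant column inside the block
            n_ret = 0
        node = SegmentNode(int(wl[idx[0]]), int(wl[idx[-1]]), n_ret, depth)
        if n_ret > 1 and len(idx) >= min_width and depth < max_depth:
            parts = _split_block(values, idx, int(rng.integers(2**31)))
            if len(parts) > 1:
                node.children = [recurse(p, depth + 1) for p in parts]
        return node

    root = recurse(np.arange(values.shape[1]), 0)

    segments: list[Segment] = []

    def collect(node: SegmentNode) -> None:
        if node.is_terminal:
            sel = (wl >= node.low) & (wl <= node.high)
            loading, scores = _block_pc1(values[:, sel])
            segments.append(
                Segment(
                    segment_id=len(segments) + 1,
                    low=node.low,
                    high=node.high,
                    n_retained=node.n_retained,
                    degenerate=node.n_retained != 1,
                    loading=loading,
                    scores=scores,
                )
            )
        else:
            for child in node.children:
                collect(child)

    collect(root)
    segments.sort(key=lambda s: s.low)
    for i, s in enumerate(segments):
        s.segment_id = i + 1
    return SegmentTree(root=root, segments=segments, wavelengths=wl)


def segment_trait_r2(
    spectral_traits: pd.DataFrame, functional_traits: pd.DataFrame, join_col: str = "leaf_id"
) -> pd.DataFrame:
    """Squared Pearson correlation (with sign) between every spectral trait
    and every functional trait, aligned by leaf id.

    Returns a long frame with columns segment, trait, r2, sign.
    """
    merged = spectral_traits.merge(functional_traits, on=join_col, suffixes=("_s", "_f"))
    seg_cols = [c for c in spectral_traits.columns if c != join_col]
    trait_cols = [c for c in functional_traits.columns if c != join_col]
    rows = []
    for sc in seg_cols:
        x = merged[sc if sc in merged else f"{sc}_s"].to_numpy(float)
        if x.std() == 0:
            raise ValueError(f"zero-variance spectral trait {sc}")
        for tc in trait_cols:
            y = merged[tc if tc in merged else f"{tc}_f"].to_numpy(float)
            if y.std() == 0:
                raise ValueError(f"zero-variance trait {tc}")
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append(
                {"segment": sc, "trait": tc, "r2": r**2, "sign": int(np.sign(r)) or 1}
            )
    return pd.DataFrame(rows)
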