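"""Color-coding of diet states and tabular exports.

A diet state's color is the additive mixture of the per-category colors
weighted by the state's utilization vector (channel-wise convex combination
sum_j p_j c_j).  Node/branch colors average over states with the marginal
ancestral state probabilities within a posterior sample, then across
samples.  The trophic network export is an edge list (species -> prey
category) weighted by posterior-mean utilization.
"""
from __future__ import annotations

import colorsys

import numpy as np
import pandas as pd

from .dmm import PosteriorSample, node_marginals
from .ecospace import expected_node_vectors
from .treedata import Phylogeny

__all__ = [
    "default_palette", "state_color", "branch_colors", "rgb_to_hex",
    "hex_to_rgb", "export_network",
]


def default_palette(J: int) -> np.ndarray:
    """J visually spread RGB colors (hue-rotated, alternating lightness)."""
    cols = []
    for j in range(J):
        h = (j * 0.61803398875) % 1.0  # golden-ratio hue steps
        s = 0.85 if j % 2 == 0 else 0.55
        v = 0.9 if j % 3 else 0.65
        cols.append(colorsys.hsv_to_rgb(h, s, v))
    return np.asarray(cols)


def state_color(state, palette: np.ndarray) -> np.ndarray:
    """Additive color mix of a utilization vector: channel-wise sum_j p_j c_j."""
    x = np.asarray(state, dtype=float)
    palette = np.asarray(palette, dtype=float)
    if palette.shape != (x.size, 3):
        raise ValueError("palette must have one RGB triple per category")
    return x @ palette


def branch_colors(tree: Phylogeny, samples: list[PosteriorSample],
                  palette: np.ndarray) -> np.ndarray:
    """Per-node RGB: state colors mixed by marginal probabilities, then averaged
    over posterior samples.  Branches are painted with their child node's color."""
    if not samples:
        raise ValueError("empty chain")
    acc = np.zeros((tree.n_nodes, 3))
    for sample in samples:
        marg = node_marginals(tree, sample)
        node_vecs = expected_node_vectors(
            marg, np.stack([sample.state_vectors[lab] for lab in marg.labels]
                           + ([sample.other_vector] if marg.has_other else [])))
        acc += node_vecs @ palette
    return acc / len(samples)


def rgb_to_hex(rgb) -> str:
    r, g, b = (int(round(np.clip(c, 0, 1) * 255)) for c in rgb)
    return f"#{r:02x}{g:02x}{b:02x}"


def hex_to_rgb(code: str) -> np.ndarray:
    code = code.lstrip("#")
    return np.array([int(code[i:i + 2], 16) / 255.0 for i in (0, 2, 4)])


def export_network(tree: Phylogeny, samples: list[PosteriorSample],
                   categories: list[str] | None = None,
                   min_weight: float = 0.0) -> pd.DataFrame:
    """Edge list (species, prey category, posterior-mean utilization weight).

    Per-species weights sum to 1; edges at or below ``min_weight`` can be
    dropped for readability.
    """
    if not samples:
        raise ValueError("empty chain")
    J = samples[0].other_vector.size
    acc = np.zeros((tree.n_tips, J))
    for s in samples:
        for i in range(tree.n_tips):
            acc[i] += s.state_vectors[int(s.assignment[i])]
    acc /= len(samples)
    if categories is None:
        categories = [f"cat{j}" for j in range(J)]
    rows = []
    for i, sp in enumerate(tree.tip_labels):
        for j, cat in enumerate(categories):
            if acc[i, j] > min_weight:
                rows.append((sp, cat, acc[i, j]))
    return pd.DataFrame(rows, columns=["species", "prey_category", "weight"])
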