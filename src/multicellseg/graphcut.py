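"""Pixel-level refinement by exact binary graph-cut.

The region-filtered patch labeling is patch-resolution; the final mask is
obtained by minimizing the standard binary segmentation energy

    E(x) = sum_p U_p(x_p) + sum_{p~q} w_pq [x_p != x_q]

over per-pixel labels x in {cellular, background}.  Unary costs are negative
log-probabilities from a logistic calibration of the bilinearly upsampled
confidence map; interiors of confidently labeled baseline regions are pinned
with sentinel costs ("hard seeds"); pairwise weights are contrast-sensitive
Potts, w = lambda * exp(-(Ii-Ij)^2 / (2 sigma^2)), on the 4-neighbor pixel
graph (8-neighbor optional).  Because all pairwise weights are non-negative
the energy is submodular, and max-flow/min-cut recovers its *global* minimum
exactly; the labeling is read off the residual-graph reachability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from skimage.transform import resize

from .image import CalibratedImage, InputError
from .patches import PatchGrid, labels_to_pixels

#: unary cost pinning a hard seed to its baseline label
SEED_COST = 1.0e4


@dataclass
class SegmentationEnergy:
    """Binary submodular pixel-labeling energy on a 4/8-connected grid."""

    unary_cellular: np.ndarray    # (H, W) cost of labeling a pixel cellular
    unary_background: np.ndarray  # (H, W) cost of labeling a pixel background
    pairwise_h: np.ndarray        # (H, W-1) weights between column neighbors
    pairwise_v: np.ndarray        # (H-1, W) weights between row neighbors
    pairwise_d1: np.ndarray | None = None  # (H-1, W-1) "\" diagonals (8-conn)
    pairwise_d2: np.ndarray | None = None  # (H-1, W-1) "/" diagonals (8-conn)

    def __post_init__(self) -> None:
        h, w = self.unary_cellular.shape
        if self.unary_background.shape != (h, w):
            raise InputError("unary cost shapes differ")
        if self.pairwise_h.shape != (h, w - 1) or self.pairwise_v.shape != (h - 1, w):
            raise InputError("pairwise weight shapes do not match the grid")
        for arr in (self.unary_cellular, self.unary_background,
                    self.pairwise_h, self.pairwise_v,
                    self.pairwise_d1, self.pairwise_d2):
            if arr is None:
                continue
            if not np.all(np.isfinite(arr)):
                raise InputError("energy terms must be finite")
            if np.any(arr < 0):
                raise InputError("energy terms must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.unary_cellular.shape

    def _pair_iter(self):
        yield self.pairwise_h, (0, 1)
        yield self.pairwise_v, (1, 0)
        if self.pairwise_d1 is not None:
            yield self.pairwise_d1, (1, 1)
        if self.pairwise_d2 is not None:
            yield self.pairwise_d2, (1, -1)

    def evaluate(self, labels: np.ndarray) -> float:
        """Total energy of a labeling (True = background)."""
        lab = np.asarray(labels, bool)
        if lab.shape != self.shape:
            raise InputError("labeling shape mismatch")
        e = float(np.where(lab, self.unary_background, self.unary_cellular).sum())
        for w, (dr, dc) in self._pair_iter():
            if dc >= 0:
                a = lab[: lab.shape[0] - dr, : lab.shape[1] - dc]
                b = lab[dr:, dc:]
            else:
                a = lab[: lab.shape[0] - dr, -dc:]
                b = lab[dr:, : lab.shape[1] + dc]
            e += float((w * (a != b)).sum())
        return e


def _sigma_squared(intensities: np.ndarray) -> float:
    """Mean squared 4-neighbor intensity difference, floored for constant
    images."""
    dh = np.diff(intensities, axis=1).ravel()
    dv = np.diff(intensities, axis=0).ravel()
    diffs = np.concatenate([dh, dv]) if dh.size + dv.size else np.zeros(1)
    return max(float(np.mean(diffs ** 2)), 1e-6)


def build_energy(image: CalibratedImage, confidence: np.ndarray,
                 baseline_labels: np.ndarray, grid: PatchGrid,
                 lam: float = 1.0, logistic_scale: float = 1.0,
                 seed_erosion_px: int | None = None,
                 eight_connected: bool = False) -> SegmentationEnergy:
    """Construct the refinement energy from confidence + baseline labels.

    The patch confidences are bilinearly upsampled to pixels and squashed
    through a logistic to p(background); unary costs are -log p and
    -log(1-p).  Pixels one patch deep inside a baseline region (erosion by a
    patch-sized square, i.e. radius ``seed_erosion_px`` = half a patch by
    default) become hard seeds for their baseline label, so the cut can only
    move boundaries, not flip whole regions the earlier stages settled.
    """
    from scipy.ndimage import binary_erosion

    h, w = image.shape
    conf = np.asarray(confidence, float)
    ph, pw = grid.padded_shape
    conf_px = resize(conf, (ph, pw), order=1, mode="edge",
                     anti_aliasing=False)[:h, :w]
    p_bg = 1.0 / (1.0 + np.exp(-conf_px / logistic_scale))
    p_bg = np.clip(p_bg, 1e-6, 1 - 1e-6)
    unary_bg = -np.log(p_bg)
    unary_cell = -np.log(1.0 - p_bg)

    base_px = labels_to_pixels(np.asarray(baseline_labels, bool), grid)
    radius = grid.patch_size // 2 if seed_erosion_px is None else seed_erosion_px
    if radius > 0:
        se = np.ones((2 * radius + 1, 2 * radius + 1), bool)
        bg_seed = binary_erosion(base_px, se)
        cell_seed = binary_erosion(~base_px, se)
    else:
        bg_seed = base_px
        cell_seed = ~base_px
    unary_cell[bg_seed] = SEED_COST
    unary_bg[cell_seed] = SEED_COST

    arr = image.intensities
    s2 = _sigma_squared(arr)
    wh = lam * np.exp(-np.diff(arr, axis=1) ** 2 / (2 * s2))
    wv = lam * np.exp(-np.diff(arr, axis=0) ** 2 / (2 * s2))
    wd1 = wd2 = None
    if eight_connected:
        d1 = arr[1:, 1:] - arr[:-1, :-1]
        d2 = arr[1:, :-1] - arr[:-1, 1:]
        inv_sqrt2 = 1.0 / np.sqrt(2.0)  # length-weighted diagonal edges
        wd1 = lam * inv_sqrt2 * np.exp(-d1 ** 2 / (2 * s2))
        wd2 = lam * inv_sqrt2 * np.exp(-d2 ** 2 / (2 * s2))
    return SegmentationEnergy(unary_cell, unary_bg, wh, wv, wd1, wd2)


def min_cut_segment(energy: SegmentationEnergy) -> np.ndarray:
    """Globally minimize the energy by max-flow; returns the optimal labeling
    (True = background).

    Construction: source-side pixels take the *cellular* label.  The t-link
    source->p carries the background cost (cut when p is on the sink side),
    p->sink carries the cellular cost, and each neighbor pair carries a
    symmetric n-link of its Potts weight, so every s-t cut's capacity equals
    the energy of the corresponding labeling.
    """
    h, w = energy.shape
    n = h * w
    source, sink = n, n + 1
    idx = np.arange(n).reshape(h, w)

    rows, cols, caps = [], [], []

    def add(u, v, c):
        rows.append(u)
        cols.append(v)
        caps.append(c)
        rows.append(v)  # reverse edge with zero capacity keeps the pattern
        cols.append(u)  # symmetric so the residual graph is easy to form
        caps.append(np.zeros_like(c))

    flat = idx.ravel()
    add(np.full(n, source), flat, energy.unary_background.ravel())
    add(flat, np.full(n, sink), energy.unary_cellular.ravel())
    for wts, (dr, dc) in energy._pair_iter():
        if dc >= 0:
            a = idx[: h - dr, : w - dc].ravel()
            b = idx[dr:, dc:].ravel()
        else:
            a = idx[: h - dr, -dc:].ravel()
            b = idx[dr:, : w + dc].ravel()
        wv = wts.ravel()
        add(a, b, wv)
        add(b, a, wv)

    # scipy's max-flow works on int32 capacities; quantize adaptively so the
    # largest capacity fills the int32 range (finest resolvable energy gap)
    caps_all = np.concatenate(caps)
    scale = (2 ** 31 - 2) / max(float(caps_all.max()), 1e-300)
    caps_int = np.rint(caps_all * scale).astype(np.int64)
    graph = coo_matrix((caps_int, (np.concatenate(rows), np.concatenate(cols))),
                       shape=(n + 2, n + 2)).tocsr()
    result = maximum_flow(graph, source, sink)
    residual = graph - result.flow
    residual.data = (residual.data > 0).astype(np.int8)
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual, source, directed=True,
                                    return_predecessors=False)
    labels = np.ones(n + 2, bool)  # unreachable from source -> background
    labels[reachable] = False
    return labels[:n].reshape(h, w)


def refine_segmentation(image: CalibratedImage, confidence: np.ndarray,
                        baseline_labels: np.ndarray, grid: PatchGrid,
                        **energy_kwargs) -> np.ndarray:
    """Convenience wrapper: build the energy and solve it."""
    energy = build_energy(image, confidence, baseline_labels, grid, **energy_kwargs)
    return min_cut_segment(energy)
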