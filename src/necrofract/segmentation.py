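"""Semi-supervised necrosis segmentation by harmonic label propagation.

Pixels inside the tumor mask form a graph (8-connected by default) with
Gaussian intensity affinities w_ij = exp(-(I_i - I_j)^2 / sigma^2). Seed
pixels are clamped to their labels (1 = necrosis, 0 = enhancing tumor) and
every unlabeled pixel takes the affinity-weighted average of its
neighbors — the harmonic solution of the clamped graph-Laplacian system

    f_u = -L_uu^{-1} L_ul f_l .

By the maximum principle the field lies in [0, 1]; thresholding at 0.5
(ties to background) yields the necrosis mask. The linear system is solved
with a sparse LU factorization and the residual is checked against 1e-8 so
the solution is interchangeable with a dense solve.

Coordinate convention throughout: row-major, 0-based pixel indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from necrofract.errors import ConvergenceError, GraphError, ParameterError

__all__ = [
    "AffinityGraph",
    "SeedLabels",
    "HarmonicField",
    "build_affinity_graph",
    "harmonic_label_propagation",
    "segment_necrosis",
    "auto_seed",
]

_RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class AffinityGraph:
    """Gaussian-affinity graph over the pixels of a tumor mask.

    ``node_pixels`` maps node id -> flat pixel index (row-major);
    ``weights`` is the symmetric sparse affinity matrix; ``sigma`` is the
    Gaussian bandwidth actually used.
    """

    node_pixels: np.ndarray
    weights: sparse.csr_matrix
    shape: tuple[int, int]
    sigma: float

    @property
    def n_nodes(self) -> int:
        return self.node_pixels.size


@dataclass(frozen=True)
class SeedLabels:
    """Clamped pixels: flat indices of necrosis (label 1) and tumor (label 0) seeds."""

    necrosis_seeds: np.ndarray
    tumor_seeds: np.ndarray

    def __post_init__(self) -> None:
        nec = np.unique(np.asarray(self.necrosis_seeds, dtype=np.intp))
        tum = np.unique(np.asarray(self.tumor_seeds, dtype=np.intp))
        if nec.size == 0 or tum.size == 0:
            raise ParameterError("both seed classes must be non-empty")
        if np.intersect1d(nec, tum).size:
            raise ParameterError("necrosis and tumor seeds must be disjoint")
        object.__setattr__(self, "necrosis_seeds", nec)
        object.__setattr__(self, "tumor_seeds", tum)


@dataclass(frozen=True)
class HarmonicField:
    """Per-node harmonic values in [0, 1] over an affinity graph."""

    values: np.ndarray
    node_pixels: np.ndarray
    shape: tuple[int, int]

    def to_image(self) -> np.ndarray:
        """Full-size field image; NaN outside the tumor mask."""
        img = np.full(self.shape, np.nan)
        img.flat[self.node_pixels] = self.values
        return img


_NEIGHBOR_STEPS = {
    4: ((0, 1), (1, 0)),
    8: ((0, 1), (1, 0), (1, 1), (1, -1)),
}


def build_affinity_graph(
    image: np.ndarray,
    tumor_mask: np.ndarray,
    sigma: float | None = None,
    connectivity: int = 8,
) -> AffinityGraph:
    """Build the Gaussian intensity-affinity graph over tumor-mask pixels.

    When ``sigma`` is None it defaults to the standard deviation of
    within-mask neighbor intensity differences (falling back to 1.0 on a
    constant image, where all weights are exp(0) = 1 regardless).
    """
    image = np.asarray(image, float)
    mask = np.asarray(tumor_mask, bool)
    if image.shape != mask.shape:
        raise ParameterError("image and tumor mask must share a shape")
    if connectivity not in _NEIGHBOR_STEPS:
        raise ParameterError("connectivity must be 4 or 8")
    if sigma is not None and sigma <= 0:
        raise ParameterError("sigma must be > 0")

    node_pixels = np.flatnonzero(mask)
    if node_pixels.size < 2:
        raise GraphError("tumor mask must contain at least 2 pixels")
    node_of = np.full(image.size, -1, dtype=np.intp)
    node_of[node_pixels] = np.arange(node_pixels.size)

    h, w = image.shape
    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    diffs: list[np.ndarray] = []
    for dr, dc in _NEIGHBOR_STEPS[connectivity]:
        a = mask[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
        b = mask[max(0, dr) : h + min(0, dr), max(0, dc) : w + min(0, dc)]
        both = a & b
        if not both.any():
            continue
        r, c = np.nonzero(both)
        r = r + max(0, -dr)
        c = c + max(0, -dc)
        pa = r * w + c
        pb = (r + dr) * w + (c + dc)
        rows_i.append(node_of[pa])
        rows_j.append(node_of[pb])
        diffs.append(image.flat[pa] - image.flat[pb])
    if not rows_i:
        raise GraphError("mask has no neighboring pixel pairs")

    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    d = np.concatenate(diffs)
    if sigma is None:
        sigma = float(np.std(d))
        if sigma == 0.0:
            sigma = 1.0
    wts = np.exp(-(d**2) / sigma**2)
    n = node_pixels.size
    weights = sparse.coo_matrix(
        (np.concatenate([wts, wts]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    ).tocsr()
    return AffinityGraph(node_pixels=node_pixels, weights=weights, shape=image.shape, sigma=sigma)


def _seed_nodes(graph: AffinityGraph, seeds: SeedLabels) -> tuple[np.ndarray, np.ndarray]:
    node_of = np.full(int(np.prod(graph.shape)), -1, dtype=np.intp)
    node_of[graph.node_pixels] = np.arange(graph.n_nodes)
    nec = node_of[seeds.necrosis_seeds]
    tum = node_of[seeds.tumor_seeds]
    if (nec < 0).any() or (tum < 0).any():
        raise ParameterError("all seeds must lie inside the tumor mask")
    return nec, tum


def harmonic_label_propagation(graph: AffinityGraph, seeds: SeedLabels) -> HarmonicField:
    """Solve the clamped Laplacian system for the harmonic label field.

    Every connected component of the graph must contain at least one seed;
    otherwise the field would be undetermined there and an error naming
    the component size is raised.
    """
    nec, tum = _seed_nodes(graph, seeds)
    n = graph.n_nodes
    labels = np.zeros(n)
    labels[nec] = 1.0
    labeled = np.zeros(n, dtype=bool)
    labeled[nec] = True
    labeled[tum] = True

    n_comp, comp = csgraph.connected_components(graph.weights, directed=False)
    if n_comp > 1:
        seeded = np.zeros(n_comp, dtype=bool)
        seeded[comp[labeled]] = True
        if not seeded.all():
            sizes = np.bincount(comp, minlength=n_comp)
            missing = np.flatnonzero(~seeded)
            raise GraphError(
                "connected component(s) without a seed, sizes: "
                + ", ".join(str(int(sizes[m])) for m in missing)
            )

    values = labels.copy()
    unlabeled = ~labeled
    if unlabeled.any():
        W = graph.weights.tocsc()
        degree = np.asarray(W.sum(axis=1)).ravel()
        L = sparse.diags(degree) - W
        L_uu = L[unlabeled][:, unlabeled].tocsc()
        W_ul = W[unlabeled][:, labeled]
        rhs = W_ul @ labels[labeled]
        try:
            f_u = splu(L_uu).solve(rhs)
        except RuntimeError as exc:  # singular factorization
            raise ConvergenceError(f"Laplacian solve failed: {exc}") from exc
        residual = np.linalg.norm(L_uu @ f_u - rhs)
        scale = max(np.linalg.norm(rhs), 1.0)
        if not np.isfinite(residual) or residual > _RESIDUAL_TOL * scale:
            raise ConvergenceError(f"harmonic solve residual {residual:.2e} above tolerance")
        values[unlabeled] = np.clip(f_u, 0.0, 1.0)
    return HarmonicField(values=values, node_pixels=graph.node_pixels, shape=graph.shape)


def segment_necrosis(
    image: np.ndarray,
    tumor_mask: np.ndarray,
    seeds: SeedLabels,
    threshold: float = 0.5,
    sigma: float | None = None,
    connectivity: int = 8,
) -> np.ndarray:
    """Necrosis mask = pixels whose harmonic value exceeds ``threshold``.

    The cut is strict, so a value exactly at the threshold goes to
    background; seeds keep their clamped labels in the output. The result
    is always a subset of the tumor mask.
    """
    graph = build_affinity_graph(image, tumor_mask, sigma=sigma, connectivity=connectivity)
    fld = harmonic_label_propagation(graph, seeds)
    out = np.zeros(np.asarray(tumor_mask).shape, dtype=bool)
    out.flat[graph.node_pixels[fld.values > threshold]] = True
    return out


def auto_seed(
    image: np.ndarray,
    tumor_mask: np.ndarray,
    low_q: float = 0.10,
    high_q: float = 0.90,
) -> SeedLabels:
    """Quantile seeding: darkest pixels -> necrosis, brightest -> tumor.

    Necrosis appears as decreased signal within the enhancing tumor on
    post-contrast T1, so the darkest ``low_q`` quantile of within-mask
    intensities seeds the necrosis class and pixels above the ``high_q``
    quantile seed the tumor class.
    """
    image = np.asarray(image, float)
    mask = np.asarray(tumor_mask, bool)
    if not 0.0 < low_q < high_q < 1.0:
        raise ParameterError("quantiles must satisfy 0 < low_q < high_q < 1")
    pix = np.flatnonzero(mask)
    if pix.size < 20:
        raise ParameterError("tumor mask must contain at least 20 pixels")
    vals = image.flat[pix]
    lo = np.quantile(vals, low_q)
    hi = np.quantile(vals, high_q)
    if lo >= hi:
        raise ParameterError("intensity quantiles are not separable (constant image?)")
    return SeedLabels(necrosis_seeds=pix[vals <= lo], tumor_seeds=pix[vals >= hi])
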