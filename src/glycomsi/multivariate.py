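"""Unsupervised spatial summaries: bisecting k-means and pLSA.

Both operate on the non-negative spot x m/z-bin matrix produced by
:func:`glycomsi.preprocess.bin_spectra` (usually TIC-normalised first)
and are written as scikit-learn estimators so they compose with
``sklearn`` pipelines and model selection.

**Bisecting k-means with correlation distance** builds a binary
segmentation tree: starting from all spots, the leaf with the highest
correlation-distance inertia is repeatedly split by 2-means until the
requested number of leaves is reached.  Correlation distance
``1 - r(u, v)`` ignores per-spot scale and offset, which suits TIC-level
differences between spectra.  Internally each 2-means runs Lloyd's
algorithm on row-standardised data (centred, unit norm), for which
squared Euclidean distance is an affine function of correlation distance,
so the usual k-means machinery applies unchanged.

**pLSA** (probabilistic latent semantic analysis) factorises the matrix
as a k-component multinomial mixture

    P(spot, bin) = sum_z P(z) P(spot | z) P(bin | z)

fit by EM from a random initialisation; the per-iteration log-likelihood
is recorded and is non-decreasing.  Spots with zero total intensity are
excluded from the fit and surface as NaN in component maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.cluster import KMeans

from .dipps import SpatialMap
from .io import ImagingDataset

__all__ = [
    "correlation_distance",
    "SegmentNode",
    "BisectingSegmentation",
    "PLSA",
    "component_map",
    "segment_map",
]


def correlation_distance(u, v) -> float:
    """1 - Pearson correlation of two vectors; in [0, 2].

    Affine-invariant: d(v, a*v + b) = 0 for a > 0.  Raises for
    zero-variance inputs, whose correlation is undefined.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise ValueError("correlation distance undefined for zero-variance vector")
    return float(1.0 - np.dot(uc, vc) / (nu * nv))


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Centre each row and scale to unit norm (zero-variance rows raise)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError(
            "zero-variance rows (constant spectra) cannot be clustered "
            "under correlation distance; drop them first"
        )
    return Xc / norms


@dataclass(eq=False)
class SegmentNode:
    """A node of the segmentation tree: a set of row indices and its inertia."""

    indices: np.ndarray
    inertia: float
    depth: int
    children: list["SegmentNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


def _corr_inertia(S: np.ndarray) -> float:
    """Sum of correlation distances of standardised rows to their mean profile."""
    if S.shape[0] < 2:
        return 0.0
    center = S.mean(axis=0)
    norm = np.linalg.norm(center - center.mean())
    if norm == 0:
        return float(S.shape[0])  # rows cancel out; maximally heterogeneous
    c = (center - center.mean()) / norm
    # rows of S are centred unit vectors: 1 - r = 1 - s.c
    return float(np.sum(1.0 - S @ c))


class BisectingSegmentation(BaseEstimator, ClusterMixin):
    """Bisecting k-means spatial segmentation under correlation distance.

    Parameters
    ----------
    n_leaves : int
        Number of segments to produce (the tree is cut when this many
        leaves exist).
    n_restarts : int
        k-means restarts per bisection; the split with the lowest
        within-cluster inertia wins.
    max_iter : int
        Lloyd iterations per restart.
    random_state : int or None
        Seed; the same seed yields an identical tree.

    Attributes
    ----------
    labels_ : ndarray of shape (n_spots,)
        Leaf index per spot, in leaf-creation order.
    tree_ : SegmentNode
        Root of the binary segmentation tree; cutting it at any depth
        yields a partition of the spots.
    leaves_ : list of SegmentNode
    """

    def __init__(
        self,
        n_leaves: int = 2,
        n_restarts: int = 5,
        max_iter: int = 100,
        random_state: int | None = None,
    ):
        self.n_leaves = n_leaves
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least two spots")
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.n_leaves > X.shape[0]:
            raise ValueError(
                f"cannot make {self.n_leaves} leaves from {X.shape[0]} spots"
            )
        S = _standardize_rows(X)
        rng = np.random.default_rng(self.random_state)

        root = SegmentNode(np.arange(X.shape[0]), _corr_inertia(S), depth=0)
        leaves = [root]
        while len(leaves) < self.n_leaves:
            # split the most heterogeneous splittable leaf
            candidates = [
                l for l in leaves if l.indices.size >= 2 and l.inertia > 0
            ]
            if not candidates:
                raise ValueError(
                    "no heterogeneous leaf left to split; "
                    f"cannot reach {self.n_leaves} leaves"
                )
            target = max(candidates, key=lambda l: l.inertia)
            left_idx, right_idx = self._bisect(S[target.indices], rng)
            for part in (left_idx, right_idx):
                sub = target.indices[part]
                target.children.append(
                    SegmentNode(sub, _corr_inertia(S[sub]), target.depth + 1)
                )
            leaves.remove(target)
            leaves.extend(target.children)

        self.tree_ = root
        self.leaves_ = leaves
        labels = np.empty(X.shape[0], dtype=int)
        for k, leaf in enumerate(leaves):
            labels[leaf.indices] = k
        self.labels_ = labels
        return self

    def _bisect(self, S: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
        """2-means on standardised rows; returns index arrays of both halves."""
        best = None
        for _ in range(max(1, self.n_restarts)):
            seed = int(rng.integers(0, 2**31 - 1))
            km = KMeans(
                n_clusters=2,
                n_init=1,
                max_iter=self.max_iter,
                random_state=seed,
            ).fit(S)
            if best is None or km.inertia_ < best.inertia_:
                best = km
        labels = best.labels_
        left = np.flatnonzero(labels == 0)
        right = np.flatnonzero(labels == 1)
        if left.size == 0 or right.size == 0:  # pragma: no cover - degenerate
            half = S.shape[0] // 2
            left, right = np.arange(half), np.arange(half, S.shape[0])
        return left, right

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class PLSA(BaseEstimator, TransformerMixin):
    """Probabilistic latent semantic analysis of a spot x bin count matrix.

    EM fit of the aspect model ``P(s, b) = sum_z P(z) P(s|z) P(b|z)`` with
    random initialisation.  ``transform`` returns per-spot component
    weights P(z|s) (rows on the simplex), obtained by folding-in with the
    bin profiles held fixed, so it applies to the training matrix and to
    new spots alike.

    Parameters
    ----------
    n_components : int
    max_iter : int
    tol : float
        Stop when the log-likelihood gain per iteration falls below
        ``tol * |loglik|``.
    random_state : int or None

    Attributes
    ----------
    weights_ : ndarray (k,) — P(z)
    spot_given_component_ : ndarray (n_spots, k) — P(s|z), columns sum to 1;
        NaN rows mark spots excluded for zero total intensity.
    bin_given_component_ : ndarray (n_bins, k) — P(b|z), columns sum to 1.
    components_ : ndarray (k, n_bins) — sklearn-style alias of P(b|z).T.
    loglik_trace_ : list of per-iteration log-likelihoods (non-decreasing).
    row_mask_ : boolean ndarray of rows included in the fit.
    """

    def __init__(
        self,
        n_components: int = 10,
        max_iter: int = 200,
        tol: float = 1e-8,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if (X < 0).any():
            raise ValueError("pLSA requires a non-negative matrix")
        total = X.sum()
        if total <= 0:
            raise ValueError("matrix total must be positive")
        k = self.n_components
        if k < 1 or k > min(X.shape):
            raise ValueError(
                f"n_components must be in [1, min(n_spots, n_bins)] = "
                f"[1, {min(X.shape)}], got {k}"
            )
        row_mask = X.sum(axis=1) > 0
        N = X[row_mask]
        self._fit_total = float(N.sum())
        n, m = N.shape
        rng = np.random.default_rng(self.random_state)

        pz = np.full(k, 1.0 / k)
        ps = rng.random((n, k)) + 0.1
        ps /= ps.sum(axis=0, keepdims=True)
        pb = rng.random((m, k)) + 0.1
        pb /= pb.sum(axis=0, keepdims=True)

        trace: list[float] = []
        prev = -np.inf
        eps = np.finfo(float).tiny
        for _ in range(self.max_iter):
            # P(s,b) mixture and log-likelihood
            joint = np.zeros((n, m))
            for z in range(k):
                joint += pz[z] * np.outer(ps[:, z], pb[:, z])
            ll = float(np.sum(N * np.log(joint + eps)))
            trace.append(ll)
            # M-step accumulators via per-component responsibilities
            new_pz = np.empty(k)
            new_ps = np.empty_like(ps)
            new_pb = np.empty_like(pb)
            R = N / (joint + eps)
            for z in range(k):
                # q_z * N = pz*ps*pb / joint * N, factorised to avoid a 3-D array
                weighted = (pz[z] * np.outer(ps[:, z], pb[:, z])) * R
                sz = weighted.sum()
                new_pz[z] = sz
                new_ps[:, z] = weighted.sum(axis=1)
                new_pb[:, z] = weighted.sum(axis=0)
            new_ps /= np.maximum(new_pz, eps)[None, :]
            new_pb /= np.maximum(new_pz, eps)[None, :]
            pz = new_pz / new_pz.sum()
            ps, pb = new_ps, new_pb
            if prev > -np.inf and ll - prev < self.tol * (abs(ll) + 1.0):
                break
            prev = ll

        self.weights_ = pz
        full_ps = np.full((X.shape[0], k), np.nan)
        full_ps[row_mask] = ps
        self.spot_given_component_ = full_ps
        self.bin_given_component_ = pb
        self.components_ = pb.T
        self.loglik_trace_ = trace
        self.n_iter_ = len(trace)
        self.row_mask_ = row_mask
        return self

    def transform(self, X, n_iter: int = 50) -> np.ndarray:
        """Per-spot component weights P(z|s) for the rows of ``X``.

        Folding-in: EM over the spot weights only, with P(b|z) fixed at
        the fitted values.  Zero-total rows give NaN.
        """
        X = np.asarray(X, dtype=float)
        pb = self.bin_given_component_  # (m, k)
        if X.shape[1] != pb.shape[0]:
            raise ValueError("bin dimension mismatch with the fitted model")
        k = self.n_components
        out = np.full((X.shape[0], k), np.nan)
        eps = np.finfo(float).tiny
        for i in range(X.shape[0]):
            x = X[i]
            if x.sum() <= 0:
                continue
            theta = np.full(k, 1.0 / k)
            for _ in range(n_iter):
                mix = pb @ theta  # (m,)
                theta = theta * ((x / (mix + eps)) @ pb)
                theta /= theta.sum()
            out[i] = theta
        return out

    def reconstruct(self) -> np.ndarray:
        """Rank-k non-negative reconstruction of the fitted (non-zero) rows,
        scaled back to the matrix total."""
        ps = self.spot_given_component_[self.row_mask_]
        joint = np.zeros((ps.shape[0], self.bin_given_component_.shape[0]))
        for z in range(self.n_components):
            joint += self.weights_[z] * np.outer(ps[:, z], self.bin_given_component_[:, z])
        return joint * self._fit_total

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.transform(X)


def component_map(
    model: PLSA,
    component: int,
    dataset: ImagingDataset,
    binned_intensities: np.ndarray,
    spot_ids: list[str] | None = None,
) -> SpatialMap:
    """Spatial map of one pLSA component's per-spot posterior weight.

    Weights over components sum to 1 per spot; excluded (zero-intensity)
    spots come out as NaN.
    """
    if not (0 <= component < model.n_components):
        raise ValueError(
            f"component index {component} out of range [0, {model.n_components})"
        )
    ids = spot_ids if spot_ids is not None else dataset.spot_ids
    theta = model.transform(np.asarray(binned_intensities, dtype=float))
    values = {sid: float(theta[i, component]) for i, sid in enumerate(ids)}
    return SpatialMap.from_spot_values(dataset, values)


def segment_map(
    labels: np.ndarray, dataset: ImagingDataset, spot_ids: list[str] | None = None
) -> SpatialMap:
    """Spatial map of segmentation labels."""
    ids = spot_ids if spot_ids is not None else dataset.spot_ids
    return SpatialMap.from_spot_values(
        dataset, {sid: float(l) for sid, l in zip(ids, labels)}
    )
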