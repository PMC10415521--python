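"""Fuzzy c-means intensity clustering and fibro-glandular segmentation.

Fibro-glandular tissue (FGT) is segmented per breast by clustering the
masked voxel intensities into K soft clusters (default K = 7) and labelling
a subset of clusters as fibro-glandular.  On non-fat-suppressed T2-weighted
images parenchyma is dark, so the default labelling takes the clusters with
the lowest centroids; on fat-suppressed pre-contrast T1-weighted images the
parenchyma is bright and the highest clusters are taken instead.

The clustering minimises the standard FCM objective

    J(u, c) = sum_i sum_k u_ik^m (x_i - c_k)^2,   sum_k u_ik = 1,

by alternating membership and centroid updates, which makes J monotonically
non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .masking import BreastMask
from .grids import VolumeGrid


class DegenerateDataError(ValueError):
    """Too few distinct intensities to support the requested cluster count."""


class FuzzyCMeans:
    """Fuzzy c-means clustering of scalar samples, sklearn-style.

    Parameters
    ----------
    n_clusters : int
        Number of clusters K (>= 2).
    m : float
        Fuzziness exponent (> 1); 2.0 is the conventional default.
    tol : float
        Convergence threshold on the relative change of the objective.
    max_iter : int
        Iteration cap; if reached, ``converged_`` is False.
    init : {"quantile", "spread"}
        Initial centroids at K evenly spaced quantiles of the data, or
        evenly spread across the data range.  The quantile rule follows the
        data mass; the spread rule follows the intensity range.
    jitter : float
        Optional fractional jitter of the initial centroids (times the data
        range), drawn from ``random_state``; 0 gives a fully deterministic
        fit.
    random_state : int or None
        Seed for the jitter draw.

    Attributes
    ----------
    cluster_centers_ : (K,) ndarray, ascending
    memberships_ : (n, K) ndarray, rows summing to 1
    objective_trace_ : list of J values, one per iteration, non-increasing
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_clusters: int = 7,
        m: float = 2.0,
        tol: float = 1e-6,
        max_iter: int = 300,
        init: str = "quantile",
        jitter: float = 0.0,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.jitter = jitter
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "m": self.m,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "init": self.init,
            "jitter": self.jitter,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "FuzzyCMeans":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    @staticmethod
    def _validate_x(x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("FuzzyCMeans expects a 1D sample (or (n, 1) array)")
        if not np.all(np.isfinite(x)):
            raise ValueError("samples must be finite")
        return x

    # -- core ----------------------------------------------------------------

    def _initial_centroids(self, x: np.ndarray) -> np.ndarray:
        k = self.n_clusters
        if self.init == "quantile":
            q = (np.arange(k) + 0.5) / k
            c = np.quantile(x, q)
        elif self.init == "spread":
            c = np.linspace(x.min(), x.max(), k)
        else:
            raise ValueError(f"unknown init {self.init!r}")
        if self.jitter:
            rng = np.random.default_rng(self.random_state)
            span = float(x.max() - x.min())
            c = c + rng.uniform(-1, 1, size=k) * self.jitter * span
        # strictly separate coincident initial centroids
        c = np.sort(c)
        eps = 1e-9 * max(float(np.ptp(x)), 1.0)
        for i in range(1, k):
            if c[i] <= c[i - 1]:
                c[i] = c[i - 1] + eps
        return c

    def _memberships(self, x: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d2 = (x[:, None] - centers[None, :]) ** 2
        exact = d2 == 0.0
        u = np.empty_like(d2)
        with np.errstate(divide="ignore"):
            inv = d2 ** (-1.0 / (self.m - 1.0))
        finite_rows = ~exact.any(axis=1)
        u[finite_rows] = inv[finite_rows] / inv[finite_rows].sum(axis=1, keepdims=True)
        # a sample exactly on >=1 centroid: all mass on (the first of) them
        hit_rows = ~finite_rows
        if np.any(hit_rows):
            u[hit_rows] = 0.0
            first_hit = np.argmax(exact[hit_rows], axis=1)
            u[np.nonzero(hit_rows)[0], first_hit] = 1.0
        return u

    def _objective(self, x: np.ndarray, u: np.ndarray, centers: np.ndarray) -> float:
        d2 = (x[:, None] - centers[None, :]) ** 2
        return float(np.sum(u**self.m * d2))

    def fit(self, X, y=None) -> "FuzzyCMeans":
        x = self._validate_x(X)
        k = self.n_clusters
        if k < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzziness m must be > 1")
        if x.size < k:
            raise DegenerateDataError(f"need at least {k} samples, got {x.size}")
        if np.unique(x).size < k:
            raise DegenerateDataError(
                f"only {np.unique(x).size} distinct values for {k} clusters"
            )

        centers = self._initial_centroids(x)
        trace: list[float] = []
        converged = False
        u = self._memberships(x, centers)
        for it in range(self.max_iter):
            u = self._memberships(x, centers)
            w = u**self.m
            centers = (w * x[:, None]).sum(axis=0) / w.sum(axis=0)
            j = self._objective(x, u, centers)
            trace.append(j)
            if it > 0:
                prev = trace[-2]
                if prev == 0 or abs(prev - j) / max(prev, 1e-300) < self.tol:
                    converged = True
                    break

        # final memberships consistent with final centroids
        u = self._memberships(x, centers)
        order = np.argsort(centers, kind="stable")
        self.cluster_centers_ = centers[order]
        self.memberships_ = u[:, order]
        self.objective_trace_ = trace
        self.n_iter_ = len(trace)
        self.converged_ = converged
        return self

    def soft_predict(self, X) -> np.ndarray:
        x = self._validate_x(X)
        return self._memberships(x, self.cluster_centers_)

    def predict(self, X) -> np.ndarray:
        """Hard labels by maximum membership; ties go to the lower index."""
        u = self.soft_predict(X)
        return np.argmax(u, axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


def fcm_objective(x, u, centers, m: float = 2.0) -> float:
    """Standalone FCM objective J = sum u^m (x - c)^2 (for external checks)."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    centers = np.asarray(centers, dtype=float)
    return float(np.sum(u**m * (x[:, None] - centers[None, :]) ** 2))


def fit_fcm(
    intensities,
    n_clusters: int = 7,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    rng_seed: int | None = None,
    init: str = "quantile",
    jitter: float = 0.0,
) -> FuzzyCMeans:
    """Fit fuzzy c-means on a 1D sample of masked voxel values."""
    return FuzzyCMeans(
        n_clusters=n_clusters,
        m=m,
        tol=tol,
        max_iter=max_iter,
        init=init,
        jitter=jitter,
        random_state=rng_seed,
    ).fit(intensities)


# ---------------------------------------------------------------------------
# Cluster -> tissue assignment


def select_clusters(rule, centers: np.ndarray) -> np.ndarray:
    """Resolve a cluster-selection rule to sorted cluster indices.

    Rules (centroids are indexed in ascending order):

    - ``"lowest:n"`` — the n lowest-centroid clusters (dark tissue on
      non-fat-suppressed T2w);
    - ``"highest:n"`` — the n highest (bright parenchyma on fat-suppressed
      pre-contrast images);
    - ``"gap"`` / ``"gap-high"`` — split the ascending centroids at the
      largest inter-centroid gap and take the low (resp. high) side; this is
      the automated analogue of per-case fine-tuning of the cluster count;
    - an explicit iterable of cluster indices.
    """
    k = len(centers)
    if isinstance(rule, str):
        if rule.startswith("lowest:"):
            n = int(rule.split(":", 1)[1])
            idx = np.arange(min(n, k))
        elif rule.startswith("highest:"):
            n = int(rule.split(":", 1)[1])
            idx = np.arange(max(k - n, 0), k)
        elif rule in ("gap", "gap-low", "gap-high"):
            gaps = np.diff(np.asarray(centers, dtype=float))
            split = int(np.argmax(gaps)) + 1
            idx = np.arange(split) if rule != "gap-high" else np.arange(split, k)
        else:
            raise ValueError(f"unknown cluster-selection rule {rule!r}")
    else:
        idx = np.unique(np.asarray(list(rule), dtype=int))
        if np.any(idx < 0) or np.any(idx >= k):
            raise ValueError("explicit cluster indices out of range")
    if idx.size == 0:
        raise ValueError("cluster selection resolved to an empty set")
    return idx


@dataclass
class TissueSegmentation:
    """A binary fibro-glandular (parenchyma) segmentation within one breast."""

    fgt_mask: np.ndarray
    selected_clusters: np.ndarray
    laterality: str
    model: FuzzyCMeans | None = None

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.fgt_mask))


@dataclass
class DensityMetrics:
    """Fibro-glandular volume and MRI breast density for one breast."""

    fgt_volume_cc: float
    mrbd_pct: float
    breast_volume_cc: float
    laterality: str


def segment_fgt(
    corrected: VolumeGrid,
    breast: BreastMask,
    n_clusters: int = 7,
    m: float = 2.0,
    assignment="lowest:3",
    tol: float = 1e-6,
    max_iter: int = 300,
    rng_seed: int | None = None,
    init: str = "quantile",
) -> TissueSegmentation:
    """Segment fibro-glandular tissue within one breast mask.

    FCM is fitted on that breast's masked intensities only; each voxel is
    hard-assigned to its maximum-membership cluster (ties to the lower
    index) and the fgt mask is the union of the selected clusters.
    """
    mask = np.asarray(breast.values, dtype=bool)
    if not mask.any():
        raise ValueError("breast mask is empty")
    x = np.asarray(corrected.values)[mask].astype(float)
    model = fit_fcm(
        x, n_clusters=n_clusters, m=m, tol=tol, max_iter=max_iter,
        rng_seed=rng_seed, init=init,
    )
    selected = select_clusters(assignment, model.cluster_centers_)
    labels = model.predict(x)
    fgt_flat = np.isin(labels, selected)
    fgt = np.zeros(mask.shape, dtype=bool)
    fgt[mask] = fgt_flat
    return TissueSegmentation(
        fgt_mask=fgt,
        selected_clusters=selected,
        laterality=breast.laterality,
        model=model,
    )


def compute_density(
    seg: TissueSegmentation,
    breast: BreastMask,
    voxel_volume_mm3: float,
) -> DensityMetrics:
    """Fibro-glandular volume (cc) and MRBD (%) from a segmentation.

    MRBD is the percentage of the breast volume occupied by fibro-glandular
    tissue; volumes are voxel counts times the voxel volume.
    """
    n_breast = int(np.count_nonzero(breast.values))
    if n_breast == 0:
        raise ZeroDivisionError("breast mask is empty; cannot compute density")
    n_fgt = int(np.count_nonzero(seg.fgt_mask & np.asarray(breast.values, bool)))
    cc = voxel_volume_mm3 / 1000.0
    return DensityMetrics(
        fgt_volume_cc=n_fgt * cc,
        mrbd_pct=100.0 * n_fgt / n_breast,
        breast_volume_cc=n_breast * cc,
        laterality=seg.laterality,
    )
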