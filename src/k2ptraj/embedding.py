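"""Dimensionality reduction: PCA on sin/cos features and sketch-map.

Sketch-map is a nonlinear multidimensional scaling method for rugged
conformational landscapes.  Pairwise distances in the high- and
low-dimensional spaces are passed through sigmoid switching functions

    s(r) = 1 - (1 + (2^(p/q) - 1) (r / sigma)^p)^(-q/p)

so that distances below the characteristic length ``sigma`` are
contracted and distances above it saturate; the embedding minimizes the
stress

    chi^2 = sum_{i<j} [F(R_ij) - f(r_ij)]^2

where ``F`` uses the high-dimensional exponents (A, B) and ``f`` the
low-dimensional ones (a, b).  Only a subset of landmark frames is
optimized directly; every other frame is projected out-of-sample by
minimizing its single-point stress against the fixed landmarks.

:class:`SketchMap` follows the scikit-learn estimator protocol
(``fit`` / ``transform`` / ``fit_transform``, constructor-only
hyper-parameters, trailing-underscore fitted attributes) and composes
with sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "sigmoid",
    "pairwise_distance",
    "select_landmarks",
    "sketchmap_stress",
    "minimize_landmark_embedding",
    "project_out_of_sample",
    "SketchMap",
    "pca",
]


class EmbeddingError(ValueError):
    """Raised for invalid embedding inputs or a diverging optimization."""


# ---------------------------------------------------------------------------
# Sigmoid switching functions and distances
# ---------------------------------------------------------------------------

def _ipow(x, e: float):
    """x**e, with repeated multiplication when e is a small integer.

    np.power with a float exponent dominates the runtime of large
    projections; the conventional sketch-map exponents (1, 2, 12) are
    all small integers.
    """
    if float(e).is_integer() and 1 <= e <= 64:
        n = int(e)
        result = None
        base = x
        while n:
            if n & 1:
                result = base.copy() if result is None else result * base
            n >>= 1
            if n:
                base = base * base
        return result
    return x ** e


def sigmoid(r, sigma: float, p: float, q: float):
    """Sketch-map switching function; monotone, s(0)=0, s(sigma)=1/2, s(inf)=1."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise EmbeddingError("distances must be >= 0")
    if sigma <= 0 or p <= 0 or q <= 0:
        raise EmbeddingError("sigma, p, q must be > 0")
    c = 2.0 ** (p / q) - 1.0
    u = c * _ipow(r / sigma, p)
    e = q / p
    if float(e).is_integer() and 1 <= e <= 64:
        base = 1.0 / _ipow(1.0 + u, e)
    else:
        base = (1.0 + u) ** (-e)
    out = 1.0 - base
    return float(out) if out.ndim == 0 else out


def _sigmoid_and_grad(r, sigma, p, q):
    """s(r) and ds/dr, vectorized; r must be > 0 for the gradient."""
    c = 2.0 ** (p / q) - 1.0
    u = c * _ipow(r / sigma, p)
    e = q / p
    if float(e).is_integer() and 1 <= e <= 64:
        base = 1.0 / _ipow(1.0 + u, e)
    else:
        base = (1.0 + u) ** (-e)
    s = 1.0 - base
    rp1 = 1.0 if p == 1 else _ipow(r, p - 1.0)
    ds = base / (1.0 + u) * (q / p) * c * p * rp1 / sigma ** p
    return s, ds


def _euclidean_to_landmarks(pos: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Point-to-landmark euclidean distances via the Gram expansion."""
    d2 = (
        (pos ** 2).sum(axis=1)[:, None]
        - 2.0 * pos @ Y.T
        + (Y ** 2).sum(axis=1)[None, :]
    )
    return np.sqrt(np.clip(d2, 0.0, None))


def pairwise_distance(features: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Symmetric pairwise distance matrix between rows.

    ``periodic`` treats every coordinate as an angle in degrees and uses
    the wrapped per-coordinate difference min(|d|, 360 - |d|) inside the
    euclidean norm — appropriate for raw dihedrals, where 179 and -179
    degrees are 2 degrees apart, not 358.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise EmbeddingError("features must be a 2-D matrix")
    if metric == "euclidean":
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(x))
    if metric == "periodic":
        return cross_distance(x, x, metric="periodic")
    raise EmbeddingError(f"unknown metric {metric!r}")


def cross_distance(a: np.ndarray, b: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Distances between rows of ``a`` and rows of ``b`` (shape (na, nb))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if metric == "euclidean":
        from scipy.spatial.distance import cdist

        return cdist(a, b)
    if metric == "periodic":
        out = np.empty((a.shape[0], b.shape[0]))
        # chunked to bound the (na, nb, d) temporary; wrap in place
        step = max(1, int(2e7) // max(1, b.shape[0] * b.shape[1]))
        for i in range(0, a.shape[0], step):
            d = a[i:i + step, None, :] - b[None, :, :]
            np.abs(d, out=d)
            np.subtract(360.0, d, out=d, where=d > 180.0)
            np.square(d, out=d)
            np.sqrt(d.sum(axis=2), out=out[i:i + step])
        return out
    raise EmbeddingError(f"unknown metric {metric!r}")


def select_landmarks(
    features: np.ndarray,
    n_landmarks: int,
    seed: int = 0,
    metric: str = "euclidean",
) -> np.ndarray:
    """Farthest-point-sampling landmark selection.

    The first landmark is a seeded uniform choice; each subsequent one
    maximizes its minimum distance to the landmarks already chosen, so
    the set covers the data's extent rather than its density peaks.
    """
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    if n_landmarks >= n:
        return np.arange(n)
    if n_landmarks < 1:
        raise EmbeddingError("n_landmarks must be >= 1")
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(n))]
    min_d = cross_distance(x, x[chosen], metric=metric)[:, 0]
    for _ in range(n_landmarks - 1):
        nxt = int(np.argmax(min_d))
        chosen.append(nxt)
        d = cross_distance(x, x[[nxt]], metric=metric)[:, 0]
        min_d = np.minimum(min_d, d)
    return np.array(chosen)


# ---------------------------------------------------------------------------
# Landmark stress minimization
# ---------------------------------------------------------------------------

def sketchmap_stress(
    high_d_distances: np.ndarray,
    low_d_coords: np.ndarray,
    sigma: float, A: float, B: float, a: float, b: float,
) -> float:
    """Sketch-map stress of a low-d configuration against high-d distances."""
    R = np.asarray(high_d_distances, dtype=float)
    y = np.asarray(low_d_coords, dtype=float)
    iu = np.triu_indices(R.shape[0], k=1)
    F = sigmoid(R[iu], sigma, A, B)
    r = np.sqrt(((y[iu[0]] - y[iu[1]]) ** 2).sum(axis=1))
    f = sigmoid(r, sigma, a, b)
    return float(((F - f) ** 2).sum())


def _stress_and_grad(flat, F, iu, n, low_d, sigma, a, b):
    y = flat.reshape(n, low_d)
    diff = y[iu[0]] - y[iu[1]]
    r = np.sqrt((diff ** 2).sum(axis=1))
    r = np.maximum(r, 1e-12)
    f, df = _sigmoid_and_grad(r, sigma, a, b)
    resid = f - F
    stress = float((resid ** 2).sum())
    coef = (2.0 * resid * df / r)[:, None] * diff
    grad = np.zeros_like(y)
    np.add.at(grad, iu[0], coef)
    np.add.at(grad, iu[1], -coef)
    return stress, grad.ravel()


def _classical_mds(dist: np.ndarray, low_d: int) -> np.ndarray:
    """Classical (Torgerson) MDS on a distance matrix."""
    n = dist.shape[0]
    d2 = dist ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1][:low_d]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def minimize_landmark_embedding(
    high_d_distances: np.ndarray,
    sigma: float = 2.5, A: float = 12.0, B: float = 12.0,
    a: float = 1.0, b: float = 2.0,
    low_d: int = 2,
    n_restarts: int = 4,
    seed: int = 0,
    max_iter: int = 10000,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """Optimize landmark low-d coordinates by stress minimization.

    Initialization is classical MDS on the F-transformed distance matrix
    (so the start already respects the sigmoid geometry); refinement is
    L-BFGS with analytic gradients.  Further restarts perturb the MDS
    start with seeded Gaussian noise and the best final stress wins —
    the stress surface is non-convex and restarts hedge local minima.
    """
    R = np.asarray(high_d_distances, dtype=float)
    n = R.shape[0]
    if R.shape != (n, n):
        raise EmbeddingError("high_d_distances must be square")
    if n < 2:
        raise EmbeddingError(f"need at least 2 landmarks, got {n}")
    iu = np.triu_indices(n, k=1)
    F = sigmoid(R[iu], sigma, A, B)
    base = _classical_mds(sigmoid(R, sigma, A, B), low_d)
    scale = max(np.abs(base).max(), 1e-3)
    rng = np.random.default_rng(seed)
    best_y, best_stress = None, np.inf
    for trial in range(max(1, n_restarts)):
        y0 = base if trial == 0 else base + rng.normal(0.0, 0.3 * scale, base.shape)
        res = minimize(
            _stress_and_grad, y0.ravel(), jac=True,
            args=(F, iu, n, low_d, sigma, a, b),
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12},
        )
        if not np.isfinite(res.fun):
            raise EmbeddingError("non-finite stress during optimization")
        if res.fun < best_stress:
            best_stress = float(res.fun)
            best_y = res.x.reshape(n, low_d)
    return best_y, best_stress


# ---------------------------------------------------------------------------
# Out-of-sample projection
# ---------------------------------------------------------------------------

def project_out_of_sample(
    point_features: np.ndarray,
    landmark_features: np.ndarray,
    landmark_coords: np.ndarray,
    sigma: float = 2.5, A: float = 12.0, B: float = 12.0,
    a: float = 1.0, b: float = 2.0,
    metric: str = "euclidean",
    grid_size: int = 20,
    refine_iter: int = 60,
) -> np.ndarray:
    """Project points onto a fixed landmark embedding.

    Each point's low-d position minimizes its single-point stress
    sum_j [F(R_pj) - f(r_pj)]^2.  The candidate set for the coarse stage
    is a ``grid_size x grid_size`` grid over the landmark bounding box
    plus the landmark positions themselves (so an exact duplicate of a
    landmark recovers that landmark's coordinates); the best candidate is
    then refined by vectorized backtracking gradient descent.  The whole
    procedure is deterministic.
    """
    X = np.atleast_2d(np.asarray(point_features, dtype=float))
    L = np.asarray(landmark_features, dtype=float)
    Y = np.asarray(landmark_coords, dtype=float)
    R = cross_distance(X, L, metric=metric)
    F = sigmoid(R, sigma, A, B)  # (n, L)

    lo = Y.min(axis=0)
    hi = Y.max(axis=0)
    pad = 0.05 * np.maximum(hi - lo, 1e-6)
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_size)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_size)
    mesh = np.stack(np.meshgrid(gx, gy), axis=-1).reshape(-1, 2)
    candidates = np.vstack([mesh, Y])

    from scipy.spatial.distance import cdist

    fC = sigmoid(cdist(candidates, Y), sigma, a, b)  # (C, L)
    # stress(p, c) = ||F_p||^2 - 2 F_p . fC_c + ||fC_c||^2
    stress = (
        (F ** 2).sum(axis=1)[:, None]
        - 2.0 * F @ fC.T
        + (fC ** 2).sum(axis=1)[None, :]
    )
    pos = candidates[np.argmin(stress, axis=1)].copy()

    def total_stress(p):
        d = _euclidean_to_landmarks(p, Y)
        f = sigmoid(d, sigma, a, b)
        return ((f - F) ** 2).sum(axis=1)

    cur = total_stress(pos)
    step = np.full(len(pos), 0.1 * max(np.max(hi - lo), 1e-3))
    for _ in range(refine_iter):
        d = np.maximum(_euclidean_to_landmarks(pos, Y), 1e-12)
        f, df = _sigmoid_and_grad(d, sigma, a, b)
        coef = 2.0 * (f - F) * df / d  # (n, L)
        # grad_p = sum_j coef_pj (pos_p - Y_j), expanded into two GEMMs
        grad = coef.sum(axis=1)[:, None] * pos - coef @ Y
        gnorm = np.sqrt((grad ** 2).sum(axis=1))
        if not (gnorm > 1e-12).any():
            break
        trial = pos - (step / np.maximum(gnorm, 1e-12))[:, None] * grad
        new = total_stress(trial)
        improved = new < cur
        pos[improved] = trial[improved]
        cur[improved] = new[improved]
        step[~improved] *= 0.5
        step[improved] *= 1.1
        if not improved.any() and np.all(step < 1e-10):
            break
    return pos


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class SketchMap(TransformerMixin, BaseEstimator):
    """Sketch-map embedding with landmark optimization and projection.

    Parameters
    ----------
    sigma : characteristic switching length in high-d distance units.
    A, B : high-dimensional sigmoid exponents.
    a, b : low-dimensional sigmoid exponents.
    n_landmarks : landmark count (capped at the number of frames).
    metric : "periodic" (wrapped degrees, default for dihedral data) or
        "euclidean".
    n_restarts : optimization restarts for the landmark embedding.
    random_state : seed for landmark selection and restarts.

    Attributes
    ----------
    landmark_indices_ : indices of the landmark frames in the fit data.
    landmark_features_ : high-d features of the landmarks.
    embedding_ : low-d coordinates of the landmarks.
    stress_ : final landmark stress value.
    """

    def __init__(self, sigma=2.5, A=12.0, B=12.0, a=1.0, b=2.0,
                 n_landmarks=1000, metric="periodic", n_restarts=4,
                 low_d=2, grid_size=20, random_state=0):
        self.sigma = sigma
        self.A = A
        self.B = B
        self.a = a
        self.b = b
        self.n_landmarks = n_landmarks
        self.metric = metric
        self.n_restarts = n_restarts
        self.low_d = low_d
        self.grid_size = grid_size
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < self.low_d + 1:
            raise EmbeddingError("need a 2-D matrix with at least low_d + 1 rows")
        idx = select_landmarks(
            X, min(self.n_landmarks, X.shape[0]),
            seed=self.random_state, metric=self.metric,
        )
        lm = X[idx]
        R = pairwise_distance(lm, metric=self.metric)
        coords, stress = minimize_landmark_embedding(
            R, sigma=self.sigma, A=self.A, B=self.B, a=self.a, b=self.b,
            low_d=self.low_d, n_restarts=self.n_restarts, seed=self.random_state,
        )
        self.landmark_indices_ = idx
        self.landmark_features_ = lm
        self.embedding_ = coords
        self.stress_ = stress
        return self

    def transform(self, X):
        check_is_fitted(self, "embedding_")
        X = np.asarray(X, dtype=float)
        return project_out_of_sample(
            X, self.landmark_features_, self.embedding_,
            sigma=self.sigma, A=self.A, B=self.B, a=self.a, b=self.b,
            metric=self.metric, grid_size=self.grid_size,
        )

    def fit_transform(self, X, y=None):
        self.fit(X)
        out = self.transform(X)
        # landmarks keep their optimized coordinates exactly
        out[self.landmark_indices_] = self.embedding_
        return out


def pca(features: np.ndarray, n_components: int | None = None):
    """Column-centered PCA via SVD.

    Returns ``(scores, loadings, explained_variance)``; the explained
    variances sum to the total variance of the input and the score
    columns are mutually orthogonal.
    """
    x = np.asarray(features, dtype=float)
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    return scores, model.components_, model.explained_variance_
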