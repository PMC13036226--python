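"""Parameter-vector ("text") feature pipeline.

The 80 fluorescence parameters span about five orders of magnitude (Fm is
~1e4 a.u. while QY_max is dimensionless in [0, 1]), so the pipeline
z-scores each parameter before PCA.  A deterministic sign convention makes
the reduced features reproducible across runs and platforms.  The reducer
is an sklearn-style transformer fitted on the training split only.

Also here: the small additive jitter used to multiply parameter rows to
match image augmentation, and Calinski-Harabasz cluster-count selection
(the criterion that motivates the five-level labeling).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .data import ParameterRecord
from .errors import SchemaError

#: finite stand-in returned when within-cluster scatter collapses to zero
CH_SENTINEL = 1e12


# ------------------------------------------------------------------- jitter

def jitter_parameters(rec: ParameterRecord, lo: float = 0.001, hi: float = 0.009,
                      seed: int = 0) -> ParameterRecord:
    """Perturb each parameter by ``s * m``, ``m ~ U[lo, hi]``, ``s = +-1``.

    Signs and magnitudes are independent per parameter and deterministic
    under ``seed``.  The magnitude range follows the augmentation recipe
    (0.001..0.009); it is negligible for large-scale parameters such as Fm
    and is applied as-is, not rescaled.
    """
    if lo < 0 or lo > hi:
        raise ValueError(f"need 0 <= lo <= hi, got lo={lo}, hi={hi}")
    rng = np.random.default_rng(seed)
    names = list(rec.values)
    mags = rng.uniform(lo, hi, size=len(names))
    signs = rng.choice([-1.0, 1.0], size=len(names))
    new_values = {n: rec.values[n] + s * m
                  for n, s, m in zip(names, signs, mags)}
    return ParameterRecord(sample_id=rec.sample_id, variety_id=rec.variety_id,
                           treatment=rec.treatment, values=new_values)


# ---------------------------------------------------------------- reduction

@dataclass
class ReducedFeatures:
    sample_id: str
    values: np.ndarray  # length k


@dataclass
class ReductionModel:
    """Frozen standardize+PCA transform: z = C @ ((x - mu) / sigma)."""

    means: np.ndarray           # (p,)
    scales: np.ndarray          # (p,) all > 0
    components: np.ndarray      # (k, p), orthonormal rows
    explained_variance: np.ndarray  # (k,), non-increasing
    k: int
    param_names: list[str]

    def to_json(self, path) -> None:
        payload = {
            "k": int(self.k),
            "param_names": list(self.param_names),
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ReductionModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(means=np.array(d["means"]), scales=np.array(d["scales"]),
                   components=np.array(d["components"]),
                   explained_variance=np.array(d["explained_variance"]),
                   k=int(d["k"]), param_names=list(d["param_names"]))


class ParameterReducer(TransformerMixin, BaseEstimator):
    """Z-score standardization followed by rank-k PCA with fixed signs.

    Parameters
    ----------
    k : int, default 6
        Number of principal components retained.

    Attributes (after ``fit``)
    --------------------------
    mean_, scale_ : per-feature standardization; zero-variance features get
        scale 1 with a warning.
    components_ : (k, p) orthonormal rows; the largest-magnitude loading of
        each component is made positive.
    explained_variance_ : non-increasing.
    """

    def __init__(self, k: int = 6):
        self.k = k

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if self.k > p:
            raise ValueError(f"k={self.k} exceeds feature count {p}")
        if self.k > n - 1:
            raise ValueError(f"k={self.k} needs at least k+1={self.k + 1} samples, got {n}")
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        zero = std <= 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} zero-variance parameter(s); "
                          "scale set to 1", stacklevel=2)
            std = np.where(zero, 1.0, std)
        self.scale_ = std
        Z = (X - self.mean_) / self.scale_
        pca = PCA(n_components=self.k, svd_solver="full")
        pca.fit(Z)
        comps = pca.components_.copy()
        for i in range(comps.shape[0]):
            j = np.argmax(np.abs(comps[i]))
            if comps[i, j] < 0:
                comps[i] = -comps[i]
        self.components_ = comps
        self.explained_variance_ = pca.explained_variance_.copy()
        self.explained_variance_ratio_ = pca.explained_variance_ratio_.copy()
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.components_.T

    def inverse_transform(self, Y):
        check_is_fitted(self, "components_")
        Z = np.asarray(Y, dtype=float) @ self.components_
        return Z * self.scale_ + self.mean_


def fit_reduction(records: list[ParameterRecord], k: int = 6) -> ReductionModel:
    """Fit the standardize+PCA reduction on (training-split) records."""
    if not records:
        raise ValueError("cannot fit a reduction on an empty record list")
    names = list(records[0].values)
    X = np.stack([r.as_array(names) for r in records])
    red = ParameterReducer(k=k).fit(X)
    return ReductionModel(means=red.mean_, scales=red.scale_,
                          components=red.components_,
                          explained_variance=red.explained_variance_,
                          k=k, param_names=names)


def apply_reduction(model: ReductionModel, rec: ParameterRecord) -> ReducedFeatures:
    if set(rec.values) != set(model.param_names):
        raise SchemaError(
            f"record {rec.sample_id!r} parameter names do not match the reduction model")
    x = rec.as_array(model.param_names)
    z = (x - model.means) / model.scales
    return ReducedFeatures(sample_id=rec.sample_id, values=model.components @ z)


# --------------------------------------------------------------- clustering

def calinski_harabasz(points: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Between/within dispersion ratio ``(B/(k-1)) / (W/(n-k))``.

    ``B`` is the cluster-size-weighted scatter of centroids around the
    global mean, ``W`` the pooled within-cluster sum of squared deviations.
    A collapsed ``W`` (all clusters degenerate) returns a large finite
    sentinel instead of infinity.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = points.shape[0]
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    uniq = np.unique(labels)
    if len(uniq) != k:
        raise ValueError(f"expected {k} non-empty clusters, found {len(uniq)}")
    mu = points.mean(axis=0)
    B = 0.0
    W = 0.0
    for u in uniq:
        cluster = points[labels == u]
        cmu = cluster.mean(axis=0)
        B += len(cluster) * float(((cmu - mu) ** 2).sum())
        W += float(((cluster - cmu) ** 2).sum())
    if W <= 1e-12:
        return CH_SENTINEL if B > 0 else 0.0
    return (B / (k - 1)) / (W / (n - k))


def select_cluster_count(points: np.ndarray, k_range=range(2, 11),
                         seed: int = 0) -> int:
    """Pick the cluster count maximizing the Calinski-Harabasz score.

    Each candidate k is clustered with seeded k-means (10 restarts); ties
    resolve to the smallest k.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, n-1]={[2, n - 1]}, got {ks}")
    best_k, best_score = None, -np.inf
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(points)
        # k-means can return fewer occupied clusters on degenerate data
        k_eff = len(np.unique(labels))
        score = calinski_harabasz(points, labels, k_eff) if k_eff >= 2 else -np.inf
        if score > best_score:
            best_k, best_score = k, score
    return int(best_k)
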