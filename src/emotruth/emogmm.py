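"""Automatic emotion detection with a GMM universal background model.

One large diagonal-covariance mixture (the UBM) is trained on all emotions
pooled, then adapted to each emotion class by maximum-a-posteriori (MAP)
re-estimation of the component means.  Utterances are scored by total frame
log-likelihood under each class model and classified with equal class
priors; evaluation is stratified K-fold cross-validation.

The means-only MAP rule with relevance factor r follows the
speaker-verification lineage: with soft counts n_k and posterior data means
E_k(x),

    m_hat_k = alpha_k E_k(x) + (1 - alpha_k) m_k,   alpha_k = n_k / (n_k + r).

Mixture weights and covariances are copied from the UBM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .frontend import FeatureMatrix
from .labels import EMOTIONS, N_EMOTIONS, EmotionLabel

DEFAULT_M = 64
DEFAULT_RELEVANCE = 16.0
VARIANCE_FLOOR_FRACTION = 1e-3


@dataclass(frozen=True)
class GaussianMixture:
    """Diagonal-covariance Gaussian mixture (weights, means, variances)."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        var = np.asarray(self.covariances, dtype=float)
        if mu.ndim != 2 or var.shape != mu.shape or w.shape != (mu.shape[0],):
            raise ValueError("inconsistent mixture parameter shapes")
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if np.any(var <= 0):
            raise ValueError("covariance entries must be positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "covariances", var)

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]

    def component_log_densities(self, x: np.ndarray) -> np.ndarray:
        """log [w_k N(x_t; m_k, S_k)] for every frame t and component k."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        const = -0.5 * (
            self.n_dims * np.log(2 * np.pi) + np.sum(np.log(self.covariances), axis=1)
        )
        # (T, M): broadcast quadratic form over diagonal covariances
        quad = (
            np.sum((x**2)[:, None, :] / self.covariances[None], axis=2)
            - 2 * x @ (self.means / self.covariances).T
            + np.sum(self.means**2 / self.covariances, axis=1)[None]
        )
        return np.log(self.weights)[None] + const[None] - 0.5 * quad

    def log_likelihood(self, x: np.ndarray) -> float:
        """Total log-likelihood of the frames (frames independent)."""
        return float(np.sum(logsumexp(self.component_log_densities(x), axis=1)))

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        lg = self.component_log_densities(x)
        return np.exp(lg - logsumexp(lg, axis=1, keepdims=True))


@dataclass(frozen=True)
class EmotionModelSet:
    """UBM plus one MAP-adapted mixture per emotion class."""

    ubm: GaussianMixture
    class_models: dict[EmotionLabel, GaussianMixture]
    relevance_factor: float = DEFAULT_RELEVANCE

    def __post_init__(self) -> None:
        for label, gmm in self.class_models.items():
            if gmm.means.shape != self.ubm.means.shape:
                raise ValueError(f"class model {label} does not match the UBM shape")


@dataclass(frozen=True)
class ConcordanceMatrix:
    """5 x 5 confusion counts (rows = true emotion, cols = predicted)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (N_EMOTIONS, N_EMOTIONS):
            raise ValueError("concordance matrix must be 5 x 5")
        object.__setattr__(self, "counts", c)

    @property
    def accuracy_overall(self) -> float:
        return float(np.trace(self.counts)) / float(self.counts.sum())

    @property
    def accuracy_per_class(self) -> np.ndarray:
        totals = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.diag(self.counts) / totals
        return np.where(totals > 0, acc, np.nan)


def _pool(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.frames
    if isinstance(features, np.ndarray):
        return np.atleast_2d(features)
    return np.vstack([_pool(f) for f in features])


def train_ubm(
    features,
    n_components: int = DEFAULT_M,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-4,
    return_history: bool = False,
):
    """Fit a diagonal-covariance GMM by expectation-maximization.

    Initialization: means drawn from distinct random frames, shared global
    variance, uniform weights.  Variances are floored at a fraction of the
    global per-dimension variance to prevent component collapse.  The
    per-iteration log-likelihood is non-decreasing (an EM guarantee the
    test suite checks numerically).
    """
    x = _pool(features)
    T, D = x.shape
    if T < n_components:
        raise ValueError(f"need at least {n_components} frames, got {T}")
    rng = np.random.default_rng(seed)
    global_var = np.maximum(x.var(axis=0), 1e-12)
    floor = VARIANCE_FLOOR_FRACTION * global_var

    means = x[rng.choice(T, size=n_components, replace=False)]
    var = np.tile(global_var, (n_components, 1))
    weights = np.full(n_components, 1.0 / n_components)
    gmm = GaussianMixture(weights, means, var)

    history = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        lg = gmm.component_log_densities(x)
        frame_ll = logsumexp(lg, axis=1)
        ll = float(frame_ll.sum())
        history.append(ll)
        if ll - prev_ll < tol * max(1.0, abs(ll)) and np.isfinite(prev_ll):
            break
        prev_ll = ll
        resp = np.exp(lg - frame_ll[:, None])
        nk = resp.sum(axis=0) + 1e-12
        means = (resp.T @ x) / nk[:, None]
        var = (resp.T @ (x**2)) / nk[:, None] - means**2
        var = np.maximum(var, floor)
        weights = nk / nk.sum()
        gmm = GaussianMixture(weights, means, var)

    if return_history:
        return gmm, np.array(history)
    return gmm


def map_adapt(
    ubm: GaussianMixture, class_features, relevance_factor: float = DEFAULT_RELEVANCE
) -> GaussianMixture:
    """Means-only MAP adaptation of the UBM toward a class's frames."""
    if relevance_factor <= 0:
        raise ValueError("relevance factor must be positive")
    x = _pool(class_features) if class_features is not None else np.empty((0, ubm.n_dims))
    if x.size == 0:
        return GaussianMixture(ubm.weights, ubm.means.copy(), ubm.covariances.copy())
    if x.shape[1] != ubm.n_dims:
        raise ValueError("feature dimensionality does not match the UBM")
    resp = ubm.responsibilities(x)
    nk = resp.sum(axis=0)
    with np.errstate(invalid="ignore"):
        ex = (resp.T @ x) / nk[:, None]
    ex = np.where(nk[:, None] > 0, ex, ubm.means)
    alpha = nk / (nk + relevance_factor)
    means = alpha[:, None] * ex + (1 - alpha[:, None]) * ubm.means
    return GaussianMixture(ubm.weights, means, ubm.covariances.copy())


def train_model_set(
    corpus: dict[EmotionLabel, list],
    n_components: int = DEFAULT_M,
    relevance_factor: float = DEFAULT_RELEVANCE,
    seed: int = 0,
    **em_kwargs,
) -> EmotionModelSet:
    """UBM on the pooled corpus, then MAP-adapt one model per emotion."""
    pooled = np.vstack([_pool(f) for feats in corpus.values() for f in feats])
    ubm = train_ubm(pooled, n_components, seed, **em_kwargs)
    class_models = {
        label: map_adapt(ubm, feats, relevance_factor) for label, feats in corpus.items()
    }
    return EmotionModelSet(ubm, class_models, relevance_factor)


def score(models: EmotionModelSet, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Per-emotion total frame log-likelihoods, in canonical label order."""
    x = _pool(features)
    if x.shape[0] == 0:
        raise ValueError("cannot score an empty feature matrix")
    return np.array(
        [models.class_models[label].log_likelihood(x) for label in EMOTIONS]
    )


def classify(
    models: EmotionModelSet, features: FeatureMatrix | np.ndarray
) -> tuple[EmotionLabel, np.ndarray]:
    """Equal-prior Bayes decision from the class scores.

    Posterior ∝ exp(score) with equal priors; ties at the maximum go to the
    first label in canonical order.
    """
    s = score(models, features)
    posterior = np.exp(s - logsumexp(s))
    return EMOTIONS[int(np.argmax(s))], posterior


def kfold_evaluate(
    corpus: dict[EmotionLabel, list],
    k: int = 10,
    n_components: int = DEFAULT_M,
    relevance_factor: float = DEFAULT_RELEVANCE,
    seed: int = 0,
    **em_kwargs,
) -> ConcordanceMatrix:
    """Stratified K-fold cross-validation of the full train/classify chain.

    Every fold trains a fresh UBM + per-class MAP models on the training
    split and predicts the held-out utterances; counts are aggregated into
    a single concordance matrix.
    """
    rng = np.random.default_rng(seed)
    folds: dict[EmotionLabel, list[np.ndarray]] = {}
    for label, feats in corpus.items():
        if len(feats) < k:
            raise ValueError(
                f"class {label} has {len(feats)} items < K={k}; use a smaller K"
            )
        order = rng.permutation(len(feats))
        folds[label] = np.array_split(order, k)

    counts = np.zeros((N_EMOTIONS, N_EMOTIONS), dtype=int)
    for fold in range(k):
        train = {
            label: [corpus[label][i] for part in (folds[label][:fold] + folds[label][fold + 1 :]) for i in part]
            for label in corpus
        }
        models = train_model_set(
            train, n_components, relevance_factor, seed=seed + fold, **em_kwargs
        )
        for label in corpus:
            for i in folds[label][fold]:
                pred, _ = classify(models, corpus[label][i])
                counts[int(label), int(pred)] += 1
    return ConcordanceMatrix(counts)
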