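"""Two-class Fisher linear discriminant with Gaussian posterior read-out.

The discriminant direction w maximizes the Fisher criterion

    J(w) = (w' S_B w) / (w' S_W w)

where S_B is the between-class scatter of the class means about the grand
mean and S_W the within-class scatter about the class means. For two
classes the maximizer has the closed form w ~ (S_W + ridge I)^{-1}
(mu1 - mu0); a small ridge keeps the solve well-posed when the window
count is small relative to the feature dimension.

Posterior probabilities come from one-dimensional Gaussian
class-conditionals on the projection z = w'x, using the per-class
projected means and variances estimated on the training data and equal
class priors. This is the minimal generative completion of the Fisher
criterion; a pooled-variance variant is available via ``fit(...,
pooled_variance=True)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FLDAModel", "fit", "posterior", "classify", "fisher_criterion"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class FLDAModel:
    """Fitted two-class Fisher discriminant.

    ``proj_means``/``proj_vars`` hold the mean and (unbiased) variance of
    z = w'x per class on the training data; these two numbers per class are
    all that scoring needs. ``proj_vars`` may be zero for degenerate
    training data, in which case the posterior hard-thresholds at the
    projected midpoint.
    """

    w: np.ndarray
    class_means: np.ndarray  # (2, d), row c = mu_c
    grand_mean: np.ndarray
    S_B: np.ndarray = field(repr=False)
    S_W: np.ndarray = field(repr=False)
    proj_means: np.ndarray = field(default=None)  # type: ignore[assignment]
    proj_vars: np.ndarray = field(default=None)  # type: ignore[assignment]
    ridge: float = 0.0
    priors: tuple[float, float] = (0.5, 0.5)
    pooled_variance: bool = False
    feature_names: tuple[str, ...] | None = None

    @property
    def n_features(self) -> int:
        return self.w.shape[0]


def _scatter_matrices(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Class means, grand mean, S_B and S_W per their defining sums."""
    mu = np.stack([X[y == c].mean(axis=0) for c in (0, 1)])
    xbar = X.mean(axis=0)
    dev = mu - xbar
    S_B = dev.T @ dev  # sum over classes of (mu_c - xbar)(mu_c - xbar)'
    S_W = np.zeros((X.shape[1], X.shape[1]))
    for c in (0, 1):
        centered = X[y == c] - mu[c]
        S_W += centered.T @ centered
    return mu, xbar, S_B, S_W


def fisher_criterion(w: np.ndarray, S_B: np.ndarray, S_W: np.ndarray) -> float:
    """Evaluate J(w) = (w' S_B w) / (w' S_W w); scale-invariant in w."""
    w = np.asarray(w, dtype=float)
    denom = float(w @ S_W @ w)
    if denom <= 0:
        return np.inf if float(w @ S_B @ w) > 0 else 0.0
    return float(w @ S_B @ w) / denom


def fit(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float | None = None,
    *,
    pooled_variance: bool = False,
    feature_names: tuple[str, ...] | None = None,
) -> FLDAModel:
    """Fit the two-class discriminant.

    Parameters
    ----------
    X : ndarray, shape (n, d)
        Feature matrix.
    y : ndarray
        Binary labels; class 1 is the target state.
    ridge : float, optional
        Regularization added to S_W's diagonal; defaults to
        ``1e-6 * trace(S_W) / d``.
    pooled_variance : bool
        Use one pooled projected variance for both classes instead of
        per-class variances in the posterior model.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths differ")
    if X.shape[1] == 0:
        raise ValueError("need at least one feature")
    for c in (0, 1):
        if (y == c).sum() < 2:
            raise ValueError(f"class {c} needs >= 2 points")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")

    mu, xbar, S_B, S_W = _scatter_matrices(X, y)
    d = X.shape[1]
    if ridge is None:
        ridge = 1e-6 * float(np.trace(S_W)) / d
    w = np.linalg.solve(S_W + ridge * np.eye(d), mu[1] - mu[0])
    norm = np.linalg.norm(w)
    if norm == 0:
        # identical class means: fall back to the first axis
        w = np.zeros(d)
        w[0] = 1.0
    else:
        w = w / norm
    if float(w @ mu[1]) < float(w @ mu[0]):
        w = -w

    z = X @ w
    proj_means = np.array([z[y == c].mean() for c in (0, 1)])
    proj_vars = np.array(
        [z[y == c].var(ddof=1) for c in (0, 1)]
    )
    if pooled_variance or (proj_vars > 0).sum() == 1:
        n0, n1 = (y == 0).sum(), (y == 1).sum()
        pooled = (
            (n0 - 1) * proj_vars[0] + (n1 - 1) * proj_vars[1]
        ) / (n0 + n1 - 2)
        proj_vars = np.array([pooled, pooled])
    return FLDAModel(
        w=w,
        class_means=mu,
        grand_mean=xbar,
        S_B=S_B,
        S_W=S_W,
        proj_means=proj_means,
        proj_vars=proj_vars,
        ridge=float(ridge),
        pooled_variance=bool(pooled_variance),
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


def posterior(model: FLDAModel, x: np.ndarray) -> np.ndarray | float:
    """Posterior probability of the target class (class 1).

    Accepts one feature vector or an (n, d) batch; returns a float or an
    array of probabilities in [0, 1] with p(1|x) + p(0|x) = 1. If both
    projected variances are zero the posterior degenerates to a hard
    threshold at the projected midpoint (>= midpoint -> 1).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"input has {X.shape[1]} features, model expects {model.n_features}"
        )
    z = X @ model.w
    m0, m1 = model.proj_means
    v0, v1 = model.proj_vars
    if v0 <= 0 and v1 <= 0:
        p = (z >= (m0 + m1) / 2.0).astype(float)
    else:
        log_prior0, log_prior1 = np.log(model.priors)
        ll0 = -0.5 * (_LOG_2PI + np.log(v0) + (z - m0) ** 2 / v0) + log_prior0
        ll1 = -0.5 * (_LOG_2PI + np.log(v1) + (z - m1) ** 2 / v1) + log_prior1
        # p1 = 1 / (1 + exp(ll0 - ll1)), computed stably
        diff = np.clip(ll0 - ll1, -745.0, 745.0)
        p = 1.0 / (1.0 + np.exp(diff))
    return float(p[0]) if single else p


def classify(model: FLDAModel, x: np.ndarray) -> np.ndarray | int:
    """Hard label: 1 (target state) iff posterior >= 0.5."""
    p = posterior(model, x)
    if np.isscalar(p):
        return int(p >= 0.5)
    return (p >= 0.5).astype(int)
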