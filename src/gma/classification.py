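"""GM-type classification: canonicalization, LLGMN posteriors, rejection.

Index vectors are first *canonicalized* (z-standardized) against a reference
group of clinically normal general movements, so each entry measures the
deviation from normal motion in reference-SD units.

The classifier is a log-linearized Gaussian mixture network (LLGMN): the
input ``z`` is expanded to its quadratic monomials
``[1, z, z_i z_j (i <= j)]``, each (class, component) pair carries a linear
score on that expansion, a softmax over all components yields component
posteriors, and a class posterior is the sum over its components.  With this
parametrization each component realizes a Gaussian density in ``z`` up to a
shared normalizer, so the network outputs exact Gaussian-mixture class
posteriors.  Training maximizes the penalized log-likelihood of the teacher
labels with L-BFGS; a small L2 ridge keeps the fit stable at clinical sample
sizes (tens of intervals per class).

Classification of an analysis interval averages the posteriors of all index
vectors in the interval, applies the entropy gate
(``S = -sum_c Y_c ln Y_c > S_th`` -> Type 0) and the no-movement rule
(upper- or lower-body movement frequency ``I1 = 0`` -> Type 0), and
otherwise assigns the argmax class: 1 WM, 2 FM, 3 CS, 4 PR.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = [
    "CanonicalizationParams",
    "fit_canonicalization",
    "canonicalize",
    "quadratic_expand",
    "LLGMN",
    "entropy",
    "ClassificationResult",
    "classify_interval",
    "leave_one_out_accuracy",
    "TYPE_LABELS",
]

logger = logging.getLogger(__name__)

TYPE_LABELS = {0: "rejected", 1: "WM", 2: "FM", 3: "CS", 4: "PR"}


# ---------------------------------------------------------------------------
# canonicalization


@dataclass
class CanonicalizationParams:
    """Per-index mean/SD of the normal-GM reference group."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma must be positive")

    def to_dict(self) -> dict:
        return {"mu": self.mu.tolist(), "sigma": self.sigma.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "CanonicalizationParams":
        return cls(np.array(d["mu"]), np.array(d["sigma"]))


def fit_canonicalization(index_vectors: np.ndarray) -> CanonicalizationParams:
    """Estimate mu_j / sigma_j from reference (normal-GM) index vectors."""
    x = np.atleast_2d(np.asarray(index_vectors, dtype=np.float64))
    if x.shape[0] < 2:
        raise ValueError("need at least 2 reference samples")
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=0)
    dead = np.nonzero(sigma == 0)[0]
    if dead.size:
        raise ValueError(f"zero variance in reference indices at positions {dead.tolist()}")
    return CanonicalizationParams(mu, sigma)


def canonicalize(x: np.ndarray, params: CanonicalizationParams) -> np.ndarray:
    """Elementwise ``z_j = (I_j - mu_j) / sigma_j``."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != params.mu.shape[0]:
        raise ValueError(
            f"dimension mismatch: {x.shape[-1]} indices vs {params.mu.shape[0]} parameters"
        )
    return (x - params.mu) / params.sigma


# ---------------------------------------------------------------------------
# LLGMN


def quadratic_expand(z: np.ndarray) -> np.ndarray:
    """Expand inputs to ``[1, z, z_i z_j (i <= j)]`` (one row per sample)."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    n, d = z.shape
    iu, ju = np.triu_indices(d)
    return np.hstack([np.ones((n, 1)), z, z[:, iu] * z[:, ju]])


class LLGMN:
    """Log-linearized Gaussian mixture network classifier.

    Parameters
    ----------
    n_classes : int
        Number of GM classes ``C`` (>= 2).
    n_components : int
        Gaussian components per class (default 1).
    l2 : float
        Ridge penalty on the weights (excluding none); stabilizes training
        when samples are few relative to the quadratic expansion.
    max_iter, tol : optimizer budget and gradient tolerance.
    seed : int
        Controls the random weight initialization.
    """

    def __init__(
        self,
        n_classes: int,
        n_components: int = 1,
        *,
        l2: float = 1.0,
        max_iter: int = 500,
        tol: float = 1e-8,
        seed: int = 0,
    ) -> None:
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        if n_components < 1:
            raise ValueError("need at least 1 component per class")
        self.n_classes = n_classes
        self.n_components = n_components
        self.l2 = l2
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed
        self.weights_: np.ndarray | None = None  # (H, C*M), last column fixed 0
        self.n_features_: int | None = None
        self.converged_: bool = False
        self.n_iter_: int = 0

    # -- internals ---------------------------------------------------------

    def _scores(self, X: np.ndarray, W: np.ndarray) -> np.ndarray:
        return X @ W

    def _component_log_posteriors(self, X: np.ndarray, W: np.ndarray) -> np.ndarray:
        a = self._scores(X, W)
        return a - logsumexp(a, axis=1, keepdims=True)

    def _class_posteriors(self, X: np.ndarray, W: np.ndarray) -> np.ndarray:
        log_o = self._component_log_posteriors(X, W)
        o = np.exp(log_o)
        return o.reshape(len(X), self.n_classes, self.n_components).sum(axis=2)

    def _nll_grad(self, wfree: np.ndarray, X: np.ndarray, T: np.ndarray) -> tuple[float, np.ndarray]:
        h = X.shape[1]
        k = self.n_classes * self.n_components
        W = np.zeros((h, k))
        W[:, :-1] = wfree.reshape(h, k - 1)
        o = np.exp(self._component_log_posteriors(X, W))
        y = o.reshape(len(X), self.n_classes, self.n_components).sum(axis=2)
        y = np.clip(y, 1e-300, None)
        nll = -float(np.sum(T * np.log(y)))
        # responsibility of each component for its class's teacher signal
        ratio = (T / y)[:, :, None]  # (n, C, 1)
        r = (o.reshape(len(X), self.n_classes, self.n_components) * ratio).reshape(len(X), k)
        grad = X.T @ (o - r)
        nll += self.l2 * float(np.sum(W[:, :-1] ** 2))
        grad[:, :-1] += 2 * self.l2 * W[:, :-1]
        return nll, grad[:, :-1].ravel()

    # -- API ---------------------------------------------------------------

    def fit(self, Z: np.ndarray, y: Sequence[int]) -> "LLGMN":
        """Train on canonicalized samples ``Z`` with integer labels ``0..C-1``."""
        Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
        y = np.asarray(y, dtype=int)
        if len(Z) != len(y):
            raise ValueError("Z and y length mismatch")
        present = np.unique(y)
        if np.any((present < 0) | (present >= self.n_classes)):
            raise ValueError("labels outside 0..C-1")
        if len(present) < self.n_classes:
            missing = sorted(set(range(self.n_classes)) - set(present.tolist()))
            raise ValueError(f"classes {missing} absent from training labels")

        X = quadratic_expand(Z)
        self.n_features_ = Z.shape[1]
        T = np.zeros((len(y), self.n_classes))
        T[np.arange(len(y)), y] = 1.0

        h = X.shape[1]
        k = self.n_classes * self.n_components
        rng = np.random.default_rng(self.seed)
        w0 = rng.normal(0.0, 0.01, size=h * (k - 1))
        res = minimize(
            self._nll_grad,
            w0,
            args=(X, T),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "gtol": self.tol},
        )
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        if not self.converged_:
            logger.warning("LLGMN training did not converge in %d iterations "
                           "(using best-so-far weights)", self.max_iter)
        W = np.zeros((h, k))
        W[:, :-1] = res.x.reshape(h, k - 1)
        self.weights_ = W
        return self

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        """Posterior probabilities ``Y`` (rows sum to 1)."""
        if self.weights_ is None:
            raise RuntimeError("model is not trained")
        Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
        if not np.all(np.isfinite(Z)):
            raise ValueError("non-finite input")
        if Z.shape[1] != self.n_features_:
            raise ValueError(f"expected {self.n_features_} features, got {Z.shape[1]}")
        return self._class_posteriors(quadratic_expand(Z), self.weights_)

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return self.predict_proba(Z).argmax(axis=1)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        if self.weights_ is None:
            raise RuntimeError("model is not trained")
        return {
            "n_classes": self.n_classes,
            "n_components": self.n_components,
            "l2": self.l2,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "seed": self.seed,
            "n_features": self.n_features_,
            "converged": self.converged_,
            "n_iter": self.n_iter_,
            "weights": self.weights_.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "LLGMN":
        model = cls(
            d["n_classes"],
            d["n_components"],
            l2=d["l2"],
            max_iter=d["max_iter"],
            tol=d["tol"],
            seed=d["seed"],
        )
        model.weights_ = np.array(d["weights"])
        model.n_features_ = d["n_features"]
        model.converged_ = d["converged"]
        model.n_iter_ = d["n_iter"]
        return model

    @classmethod
    def load(cls, path) -> "LLGMN":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# entropy gate and interval classification


def entropy(y: np.ndarray, base: float = np.e) -> float:
    """Shannon entropy of a posterior vector (``0 log 0 := 0``)."""
    y = np.asarray(y, dtype=np.float64)
    nz = y[y > 0]
    s = -float(np.sum(nz * np.log(nz)))
    if base != np.e:
        s /= np.log(base)
    return s + 0.0  # normalize -0.0


@dataclass
class ClassificationResult:
    """Outcome for one analysis interval."""

    posterior: np.ndarray
    entropy: float
    gm_type: int
    reason: str  # "none", "entropy", or "no_movement"

    @property
    def label(self) -> str:
        return TYPE_LABELS.get(self.gm_type, str(self.gm_type))


def classify_interval(
    posteriors: np.ndarray,
    s_th: float = 1.0,
    i1_upper: float | None = None,
    i1_lower: float | None = None,
    *,
    entropy_base: float = np.e,
    per_step_entropy: bool = False,
) -> ClassificationResult:
    """Average per-step posteriors, apply rejection rules, assign a type.

    Type 0 when the entropy of the mean posterior exceeds ``s_th`` or when
    the upper- or lower-body movement frequency ``I1`` is zero; otherwise
    the argmax class (1-based: WM, FM, CS, PR).  With ``per_step_entropy``
    the gate uses the mean of per-step entropies instead.
    """
    p = np.atleast_2d(np.asarray(posteriors, dtype=np.float64))
    if p.size == 0:
        raise ValueError("empty interval: no posteriors to classify")
    mean_y = p.mean(axis=0)
    if per_step_entropy:
        s = float(np.mean([entropy(row, entropy_base) for row in p]))
    else:
        s = entropy(mean_y, entropy_base)

    if (i1_upper is not None and i1_upper == 0) or (
        i1_lower is not None and i1_lower == 0
    ):
        return ClassificationResult(mean_y, s, 0, "no_movement")
    if s > s_th:
        return ClassificationResult(mean_y, s, 0, "entropy")
    return ClassificationResult(mean_y, s, int(mean_y.argmax()) + 1, "none")


# ---------------------------------------------------------------------------
# evaluation harness


def leave_one_out_accuracy(
    Z: np.ndarray, y: Sequence[int], *, n_components: int = 1, l2: float = 1.0,
    max_iter: int = 300, seed: int = 0
) -> float:
    """Leave-one-out accuracy of the LLGMN on a labelled sample set."""
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    y = np.asarray(y, dtype=int)
    n = len(y)
    n_classes = int(y.max()) + 1
    hits = 0
    for i in range(n):
        keep = np.arange(n) != i
        model = LLGMN(n_classes, n_components, l2=l2, max_iter=max_iter, seed=seed)
        model.fit(Z[keep], y[keep])
        hits += int(model.predict(Z[i : i + 1])[0] == y[i])
    return hits / n
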