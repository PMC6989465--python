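"""Index reduction by partial Kullback-Leibler information.

The contribution of index ``i`` to the classification is measured by
retraining the classifier without it and comparing the Kullback-Leibler
information between teacher labels and model posteriors:

.. math::

    G_{[i]} = K(Q'_{[i]}, C'_{[i]}) / K(Q, C),

where ``K`` is operationalized as the teacher-posterior KL summed over the
evaluation samples (one-hot teacher, so ``K = sum_n -ln Y_{true}``).  An
index that carries no class information leaves the fit unchanged, giving
``G ~ 1``; backward elimination therefore repeatedly removes the index whose
``G`` is closest to 1, recording the classification accuracy at each
remaining-index count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classification import LLGMN

__all__ = [
    "PartialKLReport",
    "kl_information",
    "partial_kl",
    "backward_elimination",
]

logger = logging.getLogger(__name__)

EPS = 1e-12


def kl_information(model: LLGMN, Z: np.ndarray, y: Sequence[int]) -> float:
    """KL information between one-hot teacher labels and model posteriors.

    ``K = sum_n sum_c T log(T / Y) = sum_n -log Y_{n, y_n} >= 0``.  Zero
    posteriors at the teacher-positive class are clamped at a documented
    epsilon (logged).
    """
    y = np.asarray(y, dtype=int)
    proba = model.predict_proba(Z)[np.arange(len(y)), y]
    n_clamped = int(np.sum(proba < EPS))
    if n_clamped:
        logger.info("kl_information: clamped %d near-zero posterior(s)", n_clamped)
    return float(-np.log(np.clip(proba, EPS, None)).sum())


def _fit(Z: np.ndarray, y: np.ndarray, model_kw: dict) -> LLGMN:
    n_classes = int(np.max(y)) + 1
    model = LLGMN(n_classes, **model_kw)
    model.fit(Z, y)
    return model


def partial_kl(
    Z: np.ndarray,
    y: Sequence[int],
    base_k: float,
    index: int,
    model_kw: dict | None = None,
) -> float:
    """``G_[i]``: KL ratio after fully retraining with index ``i`` removed."""
    if base_k <= 0:
        raise ValueError("base KL information must be positive")
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    y = np.asarray(y, dtype=int)
    keep = [j for j in range(Z.shape[1]) if j != index]
    reduced = _fit(Z[:, keep], y, model_kw or {})
    return kl_information(reduced, Z[:, keep], y) / base_k


@dataclass
class PartialKLReport:
    """Backward-elimination trace: removal order, G values, accuracy curve."""

    elimination_order: list[str]          # removed first -> last
    g_values: list[float]                 # G of the index removed each round
    accuracy_curve: dict[int, float]      # remaining-index count -> accuracy
    remaining: list[str]                  # indices never removed
    n_samples: int
    fallback_rounds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "elimination_order": self.elimination_order,
            "g_values": self.g_values,
            "accuracy_curve": {str(k): v for k, v in self.accuracy_curve.items()},
            "remaining": self.remaining,
            "n_samples": self.n_samples,
            "fallback_rounds": self.fallback_rounds,
        }

    def to_dataframe(self) -> pd.DataFrame:
        counts = sorted(self.accuracy_curve, reverse=True)
        return pd.DataFrame(
            {"n_indices": counts, "accuracy": [self.accuracy_curve[c] for c in counts]}
        )


def backward_elimination(
    Z: np.ndarray,
    y: Sequence[int],
    names: Sequence[str] | None = None,
    *,
    min_indices: int = 1,
    n_components: int = 1,
    l2: float = 1.0,
    max_iter: int = 300,
    seed: int = 0,
) -> PartialKLReport:
    """Sequentially remove the least informative index by partial KL.

    Each round retrains the classifier once per candidate index, removes the
    index with ``|G - 1|`` smallest (ties: the later canonical position goes,
    for determinism), and records training accuracy on the evaluation
    samples.  If the base fit is perfect (``K = 0``, so ``G`` is undefined)
    the round falls back to ranking by accuracy drop (logged and recorded).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    y = np.asarray(y, dtype=int)
    d = Z.shape[1]
    if d < 2:
        raise ValueError("need at least 2 indices")
    names = list(names) if names is not None else [f"idx{i}" for i in range(d)]
    if len(names) != d:
        raise ValueError("names length mismatch")
    model_kw = dict(n_components=n_components, l2=l2, max_iter=max_iter, seed=seed)

    active = list(range(d))
    order: list[str] = []
    gs: list[float] = []
    curve: dict[int, float] = {}
    fallback_rounds: list[int] = []

    while len(active) > min_indices:
        Za = Z[:, active]
        base = _fit(Za, y, model_kw)
        curve[len(active)] = float(np.mean(base.predict(Za) == y))
        base_k = kl_information(base, Za, y)

        candidates = []
        for pos in range(len(active)):
            keep = [p for p in range(len(active)) if p != pos]
            reduced = _fit(Za[:, keep], y, model_kw)
            if base_k > 0:
                gval = kl_information(reduced, Za[:, keep], y) / base_k
                score = abs(gval - 1.0)
            else:
                gval = float("nan")
                score = float(np.mean(base.predict(Za) == y)) - float(
                    np.mean(reduced.predict(Za[:, keep]) == y)
                )
            candidates.append((score, pos, gval))
        if base_k <= 0:
            fallback_rounds.append(len(active))
            logger.warning("base KL is zero with %d indices; accuracy-drop fallback",
                           len(active))
        # smallest score wins; ties resolved toward the larger canonical position
        best_score = min(c[0] for c in candidates)
        best = max(p for s, p, _ in candidates if s == best_score)
        gval = next(g for s, p, g in candidates if p == best)
        order.append(names[active[best]])
        gs.append(gval)
        del active[best]

    final = _fit(Z[:, active], y, model_kw)
    curve[len(active)] = float(np.mean(final.predict(Z[:, active]) == y))
    return PartialKLReport(
        elimination_order=order,
        g_values=gs,
        accuracy_curve=curve,
        remaining=[names[i] for i in active],
        n_samples=len(y),
        fallback_rounds=fallback_rounds,
    )
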