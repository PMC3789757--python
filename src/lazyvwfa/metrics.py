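"""Confusion-matrix summaries: accuracy, adjacency share, adjacency index.

Confusion matrices are plain ``(L, L)`` arrays of non-negative counts with
rows = true location class and columns = guessed class.

The adjacency index (AI) condenses a 6-class confusion matrix into one
number in [0, 1]: 1 for an identity matrix (perfect classification), 0 for
a uniform matrix (chance), increasing as guesses concentrate near the true
location.  With e = |guessed - true| pooled over test items,

    AI = sqrt( max(0, 1 - mean(e)/mean_u(e)) * max(0, 1 - sd(e)/sd_u(e)) )

where the ``_u`` moments are computed on a uniform confusion matrix with the
same true-class margins.  It behaves like the geometric mean of overall
accuracy and of the error distribution's departure from uniformity.
Moments use absolute errors and population (ddof=0) standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _as_cm(cm) -> np.ndarray:
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any() or cm.sum() <= 0:
        raise ValueError("confusion matrix needs non-negative counts, > 0 total")
    return cm


def accuracy(cm) -> float:
    """trace / total."""
    cm = _as_cm(cm)
    return float(np.trace(cm) / cm.sum())


def adjacent_pct(cm) -> tuple[float, bool]:
    """Share of misclassifications landing next to the true class.

    Returns ``(share, defined)``.  With zero misclassifications the share is
    reported as 1.0 with ``defined=False`` (a perfect classifier makes no
    non-adjacent errors).
    """
    cm = _as_cm(cm)
    L = cm.shape[0]
    i, j = np.indices((L, L))
    off = i != j
    total_err = cm[off].sum()
    if total_err == 0:
        return 1.0, False
    adj = cm[(np.abs(i - j) == 1) & off].sum()
    return float(adj / total_err), True


def _error_moments(cm: np.ndarray) -> tuple[float, float]:
    L = cm.shape[0]
    i, j = np.indices((L, L))
    e = np.abs(i - j).astype(float)
    w = cm / cm.sum()
    mu = float((w * e).sum())
    var = float((w * e**2).sum()) - mu**2
    return mu, float(np.sqrt(max(var, 0.0)))


def adjacency_index(cm) -> float:
    """AI in [0, 1]; see module docstring for the formula."""
    cm = _as_cm(cm)
    margins = cm.sum(axis=1, keepdims=True)
    uniform = np.tile(margins / cm.shape[0], (1, cm.shape[0]))
    mu, sd = _error_moments(cm)
    mu_max, sd_max = _error_moments(uniform)
    a = max(0.0, 1.0 - mu / mu_max)
    b = max(0.0, 1.0 - sd / sd_max)
    return float(np.sqrt(a * b))


@dataclass(frozen=True)
class AdjacencyReport:
    """Bundle of confusion-matrix summaries for one decoding condition."""

    accuracy: float
    adjacent_pct: float
    adjacent_defined: bool
    ai: float
    mu: float
    sigma: float
    mu_max: float
    sigma_max: float


def adjacency_report(cm) -> AdjacencyReport:
    cm = _as_cm(cm)
    margins = cm.sum(axis=1, keepdims=True)
    uniform = np.tile(margins / cm.shape[0], (1, cm.shape[0]))
    mu, sd = _error_moments(cm)
    mu_max, sd_max = _error_moments(uniform)
    adj, defined = adjacent_pct(cm)
    return AdjacencyReport(
        accuracy=accuracy(cm),
        adjacent_pct=adj,
        adjacent_defined=defined,
        ai=adjacency_index(cm),
        mu=mu,
        sigma=sd,
        mu_max=mu_max,
        sigma_max=sd_max,
    )
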