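"""Exponential decay fitting, slow-phase half-lives, group comparison.

Four decay models are supported::

    m1: exp(-t/B)                     1 parameter
    m2: A exp(-t/B)                   2 parameters
    m3: A exp(-t/B) + (1-A) exp(-t/D) 3 parameters (two phases)
    m4: A exp(-t/B) + C exp(-t/D)     4 parameters (two phases)

The slow-phase half-life is ln2 times the larger time constant.  Fits
use bounded nonlinear least squares with multi-start initialisation
from log-spaced time constants (two-phase exponentials are multimodal).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MODELS",
    "DecayFit",
    "fit_decay",
    "fit_all_models",
    "half_life",
    "compare_groups",
]

logger = logging.getLogger(__name__)

MODELS = ("m1", "m2", "m3", "m4")
_N_PARAMS = {"m1": 1, "m2": 2, "m3": 3, "m4": 4}


def _model_value(model: str, t: np.ndarray, p: np.ndarray) -> np.ndarray:
    if model == "m1":
        return np.exp(-t / p[0])
    if model == "m2":
        return p[0] * np.exp(-t / p[1])
    if model == "m3":
        return p[0] * np.exp(-t / p[1]) + (1.0 - p[0]) * np.exp(-t / p[2])
    if model == "m4":
        return p[0] * np.exp(-t / p[1]) + p[2] * np.exp(-t / p[3])
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


@dataclass
class DecayFit:
    """Result of fitting one decay model to one series."""

    model: str
    params: Dict[str, float]
    rss: float
    half_life: float
    extrapolated: bool = False
    t_max: float = 0.0
    normalization: float = 1.0

    def predict(self, t: np.ndarray) -> np.ndarray:
        p = _pack(self.model, self.params)
        return _model_value(self.model, np.asarray(t, dtype=float), p)


_PARAM_NAMES = {
    "m1": ("B",),
    "m2": ("A", "B"),
    "m3": ("A", "B", "D"),
    "m4": ("A", "B", "C", "D"),
}


def _pack(model: str, params: Dict[str, float]) -> np.ndarray:
    return np.array([params[k] for k in _PARAM_NAMES[model]])


def _bounds(model: str, t_max: float) -> Tuple[np.ndarray, np.ndarray]:
    big = 1e4 * t_max
    tiny = 1e-6 * t_max
    if model == "m1":
        return np.array([tiny]), np.array([big])
    if model == "m2":
        return np.array([0.0, tiny]), np.array([2.0, big])
    if model == "m3":
        return np.array([0.0, tiny, tiny]), np.array([1.0, big, big])
    return np.array([0.0, tiny, 0.0, tiny]), np.array([2.0, big, 2.0, big])


def _starts(model: str, t_max: float, n_tau: int = 7) -> List[np.ndarray]:
    taus = np.geomspace(0.1 * t_max, 100.0 * t_max, n_tau)
    starts: List[np.ndarray] = []
    if model == "m1":
        starts = [np.array([tau]) for tau in taus]
    elif model == "m2":
        starts = [np.array([1.0, tau]) for tau in taus]
    elif model == "m3":
        for b in taus:
            for d in taus:
                if d >= b:
                    starts.append(np.array([0.5, b, d]))
    else:
        for b in taus:
            for d in taus:
                if d >= b:
                    starts.append(np.array([0.5, b, 0.5, d]))
    return starts


def normalize_series(
    t: np.ndarray, y: np.ndarray, head_points: int = 1
) -> Tuple[np.ndarray, float]:
    """Divide by the mean of the first ``head_points`` values so y(0) ~ 1."""
    y0 = float(np.mean(y[: max(1, head_points)]))
    if y0 <= 0:
        raise ValueError("cannot normalize a series with non-positive head")
    return y / y0, y0


def fit_decay(
    t: Sequence[float],
    y: Sequence[float],
    model: str = "m3",
    normalize: bool = True,
    head_points: int = 1,
) -> DecayFit:
    """Fit one decay model by bounded multi-start least squares.

    The series is normalised by the mean of its first ``head_points``
    values unless ``normalize=False`` (the models carry no offset
    term).  Deterministic: start points are a fixed log-spaced grid.

    Raises ``ValueError`` with the best residual if no start converges,
    or when there are fewer points than parameters + 1.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    npar = _N_PARAMS[model]
    if len(t) < npar + 1:
        raise ValueError(
            f"need at least {npar + 1} points to fit {model}, got {len(t)}"
        )
    if np.any(t < 0):
        raise ValueError("time values must be non-negative")
    norm = 1.0
    if normalize:
        y, norm = normalize_series(t, y, head_points)
    t_max = float(t.max()) if t.max() > 0 else 1.0
    lo, hi = _bounds(model, t_max)

    def residual(p: np.ndarray) -> np.ndarray:
        return _model_value(model, t, p) - y

    best: Optional[optimize.OptimizeResult] = None
    best_cost = math.inf
    for p0 in _starts(model, t_max):
        try:
            res = optimize.least_squares(
                residual, p0, bounds=(lo, hi), method="trf", xtol=1e-12,
                ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # numerical failure on this start only
            continue
        if res.cost < best_cost:
            best, best_cost = res, res.cost
    if best is None:
        raise ValueError(f"no start point converged for model {model}")
    params = {k: float(v) for k, v in zip(_PARAM_NAMES[model], best.x)}
    fit = DecayFit(
        model=model,
        params=params,
        rss=float(2.0 * best.cost),
        half_life=_half_life_from_params(model, params),
        t_max=t_max,
        normalization=norm,
    )
    fit.extrapolated = bool(fit.half_life > t_max)
    if fit.extrapolated:
        logger.warning(
            "half-life %.3g exceeds the fitted time range %.3g "
            "(extrapolated)", fit.half_life, t_max
        )
    return fit


def fit_all_models(
    t: Sequence[float], y: Sequence[float], **kwargs
) -> Dict[str, DecayFit]:
    """Fit every model that has enough data points."""
    out: Dict[str, DecayFit] = {}
    for model in MODELS:
        if len(np.asarray(t)) >= _N_PARAMS[model] + 1:
            out[model] = fit_decay(t, y, model=model, **kwargs)
    return out


def _half_life_from_params(model: str, params: Dict[str, float]) -> float:
    if model in ("m1", "m2"):
        slow = params["B"]
    else:
        slow = max(params["B"], params["D"])
    return math.log(2.0) * slow


def half_life(fit: DecayFit) -> float:
    """ln2 times the slow (largest) time constant of the fit."""
    return _half_life_from_params(fit.model, fit.params)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = True,
) -> Tuple[float, float]:
    """Unpaired two-sample t-test (equal-variance Student by default).

    Returns ``(t statistic, two-sided p value)``.  Degenerate
    zero-variance inputs use the convention p = 1 for equal means and
    p = 0 otherwise (logged).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        logger.warning(
            "zero variance with different means: p = 0 by convention"
        )
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t_stat), float(p)
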