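"""Constrained least-squares estimation of the aging-model parameters.

Observed E_add fractions (optionally pooled with long-horizon *trend
anchors* — pseudo-observations at 3600/7200 days that pin the model's
extrapolation) are fitted by minimizing the weighted sum of squared
residuals subject to non-negativity of B, C, N, F, G.  The Arrhenius
composite K and the hydrolysis constant pK0 are fixed by default (K = -4330
K from a 36 kJ/mol activation energy; pK0 = 7.7 from bulk-solution
chemistry); a free-pK0 variant bounds pK0 to [3, 10].

The optimizer is a trust-region-reflective nonlinear least-squares solve
with box constraints, wrapped in a seeded multi-start (the objective is
nonconvex in N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model import ModelParams, SoilSample, _predict_arrays

__all__ = [
    "EObservation",
    "TrendAnchor",
    "FitResult",
    "fit_params",
    "fit_free_pk",
    "goodness_of_fit",
    "FREE_DEFAULT",
]

#: Parameters estimated by default; K and pK0 stay fixed.
FREE_DEFAULT = ("b", "c", "n", "f", "g")

_BOUNDS = {
    "b": (0.0, np.inf),
    "c": (0.0, np.inf),
    "n": (0.0, np.inf),
    "f": (0.0, np.inf),
    "g": (0.0, np.inf),
    "k": (-np.inf, 0.0),
    "pk0": (3.0, 10.0),
}


@dataclass(frozen=True)
class EObservation:
    """A measured E_add fraction attached to a soil sample; unit of fitting."""

    sample: SoilSample
    e_add_obs: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.e_add_obs):
            raise ValueError("e_add_obs must be finite")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass(frozen=True)
class TrendAnchor:
    """A long-horizon pseudo-observation constraining the fitted trend.

    The target E_add at the anchor horizon (conventionally 3600 or 7200
    days) comes from an external long-term model or expert judgement; it
    enters the objective like an observation with its own weight.
    """

    sample: SoilSample
    e_add_target: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.e_add_target <= 1.0:
            raise ValueError("e_add_target must be in [0, 1]")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class FitResult:
    """Estimated parameters plus goodness of fit.

    ``r2`` and ``rmse`` are computed over the real observations only;
    anchors contribute to the objective but not to the fit statistics, so
    the statistics stay comparable across anchor choices.
    """

    params: ModelParams
    r2: float
    rmse: float
    residuals: np.ndarray
    n_obs: int
    converged: bool
    n_iterations: int
    objective: float
    free: tuple = FREE_DEFAULT
    start_objectives: np.ndarray = field(default_factory=lambda: np.empty(0))


def _stack(obs, anchors):
    """Pool observations and anchors into covariate/target/weight arrays."""
    samples = [o.sample for o in obs] + [a.sample for a in anchors]
    targets = np.array([o.e_add_obs for o in obs] + [a.e_add_target for a in anchors])
    weights = np.array([o.weight for o in obs] + [a.weight for a in anchors])
    ph = np.array([s.ph for s in samples])
    corg = np.array([s.corg for s in samples])
    temp = np.array([s.temperature for s in samples])
    time = np.array([s.time for s in samples])
    return ph, corg, temp, time, targets, weights


def _sample_starts(rng, free, init_vec):
    """Seeded multi-start initial points: the caller's init plus random draws."""
    draws = {
        "b": lambda: rng.uniform(0.0, 3.0),
        "f": lambda: rng.uniform(0.0, 3.0),
        "c": lambda: rng.uniform(0.0, 10.0),
        "g": lambda: rng.uniform(0.0, 10.0),
        "n": lambda: 10.0 ** rng.uniform(-2.0, 4.0),
        "k": lambda: rng.uniform(-8000.0, -100.0),
        "pk0": lambda: rng.uniform(3.0, 10.0),
    }
    return np.array([draws[name]() for name in free]), init_vec


def fit_params(
    obs,
    anchors=(),
    fixed: ModelParams | None = None,
    init: ModelParams | None = None,
    free=FREE_DEFAULT,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Fit the aging model by constrained weighted least squares.

    Parameters
    ----------
    obs : sequence of EObservation
        Measured E_add fractions.
    anchors : sequence of TrendAnchor, optional
        Long-horizon pseudo-observations pooled into the objective.
    fixed : ModelParams, optional
        Values of the non-free parameters (default: the published fit,
        i.e. K = -4330, pK0 = 7.7).
    init : ModelParams, optional
        First multi-start point (default: ``fixed``).
    free : sequence of str
        Names of parameters to estimate; the rest are held at ``fixed``.
    n_starts : int
        Number of multi-start initializations (the first is ``init``).
    seed : int
        Seed for the multi-start draws; the fit is deterministic given
        data, settings and seed.

    Raises
    ------
    ValueError
        If there are fewer pooled data points than free parameters.
    """
    obs = list(obs)
    anchors = list(anchors)
    free = tuple(free)
    fixed = fixed if fixed is not None else ModelParams()
    init = init if init is not None else fixed

    n_data = len(obs) + len(anchors)
    if n_data < len(free):
        raise ValueError(
            f"{n_data} data points cannot constrain {len(free)} free parameters"
        )
    if "pk0" in free and "b" not in free and fixed.b == 0.0:
        warnings.warn(
            "pk0 is unidentifiable when B is fixed at 0 (the hydrolysis term "
            "is absent from the model)",
            stacklevel=2,
        )

    ph, corg, temp, time, targets, weights = _stack(obs, anchors)
    sw = np.sqrt(weights)
    lb = np.array([_BOUNDS[p][0] for p in free])
    ub = np.array([_BOUNDS[p][1] for p in free])

    def make_params(x) -> ModelParams:
        return fixed.replace(**{name: float(v) for name, v in zip(free, x)})

    def residuals(x):
        p = make_params(x)
        _, _, _, pred, _ = _predict_arrays(ph, corg, temp, time, p)
        return sw * (targets - pred)

    init_vec = np.clip([getattr(init, p) for p in free], lb, ub)
    rng = np.random.default_rng(seed)
    starts = [init_vec] + [
        np.clip(_sample_starts(rng, free, init_vec)[0], lb, ub)
        for _ in range(max(0, n_starts - 1))
    ]

    best = None
    start_objs = []
    total_nfev = 0
    for x0 in starts:
        sol = least_squares(
            residuals,
            x0,
            bounds=(lb, ub),
            method="trf",
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            x_scale="jac",
        )
        total_nfev += sol.nfev
        start_objs.append(2.0 * sol.cost)  # cost is 0.5 * SSR
        if best is None or sol.cost < best.cost:
            best = sol

    params = make_params(best.x)
    if obs:
        _, _, _, pred_obs, _ = _predict_arrays(
            *(a[: len(obs)] for a in (ph, corg, temp, time)), params
        )
        res_obs = np.array([o.e_add_obs for o in obs]) - pred_obs
        r2, rmse = _r2_rmse(np.array([o.e_add_obs for o in obs]), pred_obs)
    else:
        res_obs = np.empty(0)
        r2, rmse = np.nan, np.nan

    return FitResult(
        params=params,
        r2=r2,
        rmse=rmse,
        residuals=res_obs,
        n_obs=len(obs),
        converged=bool(best.success),
        n_iterations=total_nfev,
        objective=2.0 * best.cost,
        free=free,
        start_objectives=np.asarray(start_objs),
    )


def fit_free_pk(obs, anchors=(), fixed=None, init=None, n_starts=10, seed=0) -> FitResult:
    """Variant of :func:`fit_params` that also estimates pK0 (bounded [3, 10])."""
    return fit_params(
        obs,
        anchors,
        fixed=fixed,
        init=init,
        free=FREE_DEFAULT + ("pk0",),
        n_starts=n_starts,
        seed=seed,
    )


def _r2_rmse(observed, predicted):
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("all observations identical: R^2 undefined")
    return 1.0 - ss_res / ss_tot, float(np.sqrt(ss_res / observed.size))


def goodness_of_fit(obs, params: ModelParams):
    """R^2 (about the observation mean) and RMSE (denominator n) of predictions."""
    obs = list(obs)
    if len(obs) < 2:
        raise ValueError("need at least 2 observations for goodness of fit")
    ph, corg, temp, time, targets, _ = _stack(obs, [])
    _, _, _, pred, _ = _predict_arrays(ph, corg, temp, time, params)
    return _r2_rmse(targets, pred)
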