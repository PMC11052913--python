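"""Parameter estimation and the five-statistic goodness-of-fit scorecard.

The headline objective is the average absolute relative deviation

    AARD(%) = 100 / N * sum |y2_cal - y2_exp| / y2_exp

formed in mole-fraction space, which is how published correlation
batteries rank models; sum-of-squares on y2 is available as an
alternative. Fitting is best-of-``n_starts`` bounded local minimization:
for models linear in their native space the exact OLS solution is the
first start, followed by multiplicative jitters of it and Latin-hypercube
draws; every start is refined by a trust-region least-squares pass on
relative residuals and the leading candidates are polished with
Nelder-Mead on the exact objective. The contract is "best local optimum
found, deterministically for a given seed" - not global optimality.

Scorecard conventions (matching how such tables are printed): SSE is the
plain sum of squared y2 residuals, RMSE is sqrt(SSE) so the two columns
are internally consistent (the conventional sqrt(SSE/N) is exposed as
``rmse_mean``), R2 uses the standard total-sum-of-squares denominator,
and the adjusted R2 is the absolute-value form
``|R2 - Q (1 - R2) / (N - Q - 1)|`` with Q the number of independent
state variables of the model (not its parameter count).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .data import SolubilityDataset, ValidationError
from .models import ModelSpec, make_env, ModelEnv
from .models.base import y2_to_native

_PENALTY = 1e10
#: Latin-hypercube draws are taken inside the bounds intersected with this
#: box; coefficients of well-scaled solubility correlations live well
#: inside it, while the nominal +/-1e6 bounds only cap the local solver.
_SAMPLING_HALF_WIDTH = 100.0


class FitFailure(RuntimeError):
    """No start of a multistart fit converged."""


class DegeneracyError(ValueError):
    """A linear solve or statistic is not identifiable on these data."""


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def aard(observed, predicted) -> float:
    """Average absolute relative deviation, in percent."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValidationError("aard: vectors must be non-empty and of equal length")
    if np.any(obs <= 0):
        raise ValidationError("aard: observed values must be strictly positive")
    return 100.0 * float(np.mean(np.abs(pred - obs) / obs))


def r_squared(observed, predicted) -> float:
    """Standard coefficient of determination, 1 - SSE / SStot."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegeneracyError("r_squared: observations have zero variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def r_squared_printed(observed, predicted) -> float:
    """Nonstandard printed variant with sum((mean_obs - pred)^2) denominator.

    Exposed for completeness only; :func:`r_squared` is the statistic used
    throughout this package.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    denom = float(np.sum((obs.mean() - pred) ** 2))
    if denom == 0.0:
        raise DegeneracyError("r_squared_printed: zero denominator")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / denom


def adjusted_r_squared(r2: float, n: int, q: int) -> float:
    """Absolute-value adjusted R2, |R2 - Q (1 - R2) / (N - Q - 1)|."""
    if n <= q + 1:
        raise DegeneracyError(f"adjusted_r_squared: need N > Q + 1, got N={n}, Q={q}")
    return abs(r2 - q * (1.0 - r2) / (n - q - 1))


@dataclass(frozen=True)
class Scorecard:
    """AARD (%), R2, adjusted R2, SSE, RMSE (= sqrt(SSE)) and sqrt(SSE/N)."""

    aard: float
    r2: float
    r_adj: float
    sse: float
    rmse: float
    rmse_mean: float


def scorecard(observed, predicted, q: int) -> Scorecard:
    """All five statistics for a prediction vector; q = # state variables."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    sse = float(np.sum((obs - pred) ** 2))
    return Scorecard(
        aard=aard(obs, pred),
        r2=r_squared(obs, pred),
        r_adj=adjusted_r_squared(r_squared(obs, pred), obs.size, q),
        sse=sse,
        rmse=float(np.sqrt(sse)),
        rmse_mean=float(np.sqrt(sse / obs.size)),
    )


# ---------------------------------------------------------------------------
# Configuration and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Multistart settings. objective is 'aard' or 'sse'."""

    objective: str = "aard"
    n_starts: int = 64
    seed: int = 0
    max_iterations: int = 4000
    tolerance: float = 1e-10
    polish_top: int = 3
    bounds: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.objective not in ("aard", "sse"):
            raise ValidationError(f"FitConfig: unknown objective {self.objective!r}")
        if self.n_starts < 1:
            raise ValidationError("FitConfig: n_starts must be >= 1")
        if self.tolerance <= 0:
            raise ValidationError("FitConfig: tolerance must be positive")


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus the scorecard and stored predictions."""

    model: str
    params: np.ndarray
    aard: float
    r2: float
    r_adj: float
    sse: float
    rmse: float
    rmse_mean: float
    objective: str
    objective_value: float
    converged: bool
    predicted: np.ndarray
    n_obs: int
    q: int

    def coefficient(self, name: str, spec: ModelSpec) -> float:
        """Look up a fitted parameter by its symbol in the spec."""
        return float(self.params[spec.param_names.index(name)])


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def linear_fit(spec: ModelSpec, dataset: SolubilityDataset) -> np.ndarray:
    """Exact OLS in the model's native transformed space.

    Only valid for specs with ``linear_in_params``; raises
    :class:`DegeneracyError` on a rank-deficient design.
    """
    if not spec.linear_in_params:
        raise ValidationError(f"linear_fit: model {spec.key!r} is not linear in parameters")
    env = make_env(dataset)
    if len(dataset) < spec.n_params:
        raise DegeneracyError(f"linear_fit: {len(dataset)} points < {spec.n_params} parameters")
    X, offset = spec.design(env)
    y = y2_to_native(spec.space, env) - offset
    # rank check on column-normalized design so raw unit scales don't matter
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0) or np.linalg.matrix_rank(X / norms, tol=1e-10) < spec.n_params:
        raise DegeneracyError(f"linear_fit: rank-deficient design for model {spec.key!r}")
    q, *_ = np.linalg.lstsq(X, y, rcond=None)
    return q if spec.from_linear is None else spec.from_linear(q)


def _safe_predict(spec: ModelSpec, params, env: ModelEnv) -> np.ndarray | None:
    try:
        with np.errstate(all="ignore"):
            y = spec.predict_y2(np.asarray(params, float), env)
    except ArithmeticError:
        return None
    return y


def _objective_fn(spec: ModelSpec, env: ModelEnv, obs: np.ndarray, objective: str,
                  lo: np.ndarray, hi: np.ndarray):
    def fun(params: np.ndarray) -> float:
        if np.any(params < lo) or np.any(params > hi):
            return _PENALTY
        y = _safe_predict(spec, params, env)
        if y is None:
            return _PENALTY
        if objective == "aard":
            return float(np.mean(np.abs(y - obs) / obs))
        return float(np.sum((y - obs) ** 2))

    return fun


def _initial_starts(spec: ModelSpec, dataset: SolubilityDataset, env: ModelEnv,
                    config: FitConfig, lo: np.ndarray, hi: np.ndarray) -> list[np.ndarray]:
    rng = np.random.default_rng(config.seed)
    starts: list[np.ndarray] = []
    anchor = None
    if spec.linear_in_params:
        try:
            anchor = np.clip(linear_fit(spec, dataset), lo, hi)
        except (DegeneracyError, ValidationError):
            anchor = None
    if anchor is not None:
        starts.append(anchor)
        n_jitter = min(8, max(0, config.n_starts - 1))
        for _ in range(n_jitter):
            jitter = anchor * (1.0 + 0.3 * rng.standard_normal(spec.n_params))
            starts.append(np.clip(jitter, lo, hi))
    n_lhs = config.n_starts - len(starts)
    if n_lhs > 0:
        sampler = qmc.LatinHypercube(d=spec.n_params, seed=rng)
        box_lo = np.maximum(lo, -_SAMPLING_HALF_WIDTH)
        box_hi = np.minimum(hi, _SAMPLING_HALF_WIDTH)
        draws = qmc.scale(sampler.random(n_lhs), box_lo, box_hi)
        starts.extend(np.asarray(d, float) for d in draws)
    return starts[: config.n_starts] if len(starts) > config.n_starts else starts


def fit(spec: ModelSpec, dataset: SolubilityDataset, config: FitConfig | None = None) -> FitResult:
    """Best-of-``n_starts`` bounded local minimization of the objective.

    Deterministic for a fixed seed and configuration; ties between starts
    are broken by lexicographically smallest parameter vector.
    """
    config = config or FitConfig()
    if len(dataset) <= spec.n_params:
        raise DegeneracyError(
            f"fit: need more data points than parameters for {spec.key!r}")
    env = make_env(dataset)
    obs = env.y2_obs
    bounds = config.bounds or spec.param_bounds()
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    objective = _objective_fn(spec, env, obs, config.objective, lo, hi)

    def residuals(params: np.ndarray) -> np.ndarray:
        y = _safe_predict(spec, params, env)
        if y is None:
            return np.full(obs.size, 1e6)
        r = (y - obs) / obs if config.objective == "aard" else (y - obs)
        return np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=-1e6)

    candidates: list[tuple[float, np.ndarray]] = []
    for x0 in _initial_starts(spec, dataset, env, config, lo, hi):
        candidates.append((objective(x0), np.asarray(x0, float)))
        try:
            with np.errstate(all="ignore"):
                res = optimize.least_squares(
                    residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac",
                    max_nfev=2000)
            candidates.append((objective(res.x), res.x))
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
    candidates = [c for c in candidates if np.isfinite(c[0]) and c[0] < _PENALTY]
    if not candidates:
        raise FitFailure(f"fit: no start converged for model {spec.key!r}")
    candidates.sort(key=lambda c: (c[0], tuple(c[1])))

    polished: list[tuple[float, np.ndarray]] = []
    for val, x in candidates[: max(1, config.polish_top)]:
        res = optimize.minimize(
            objective, x, method="Nelder-Mead",
            options={"maxiter": config.max_iterations, "xatol": config.tolerance,
                     "fatol": config.tolerance * 1e-2, "adaptive": True})
        px = np.clip(res.x, lo, hi)
        polished.append((objective(px), px))
    polished.extend(candidates)
    polished.sort(key=lambda c: (c[0], tuple(c[1])))
    best_val, best_x = polished[0]

    predicted = _safe_predict(spec, best_x, env)
    card = scorecard(obs, predicted, q=len(spec.depends_on))
    return FitResult(
        model=spec.key, params=best_x, aard=card.aard, r2=card.r2, r_adj=card.r_adj,
        sse=card.sse, rmse=card.rmse, rmse_mean=card.rmse_mean,
        objective=config.objective, objective_value=best_val, converged=True,
        predicted=predicted, n_obs=obs.size, q=len(spec.depends_on))


def deterministic_fit(spec: ModelSpec, dataset: SolubilityDataset,
                      objective: str = "aard") -> FitResult:
    """Single-start fit anchored at the exact linear solution.

    No random draws are consumed, so the result is reproducible with no
    seed bookkeeping; used for enthalpy extraction and diagnostics.
    """
    return fit(spec, dataset, FitConfig(objective=objective, n_starts=1, seed=0))


def fit_report(dataset: SolubilityDataset, specs: Sequence[ModelSpec],
               config: FitConfig | None = None) -> pd.DataFrame:
    """One row per model with parameters and the scorecard, plus group means.

    Per-model failures become flagged rows instead of aborting the batch.
    """
    config = config or FitConfig()
    rows = []
    for spec in specs:
        base = {"model": spec.key, "name": spec.name, "group": spec.group,
                "n_params": spec.n_params}
        try:
            result = fit(spec, dataset, config)
        except (FitFailure, DegeneracyError) as exc:
            rows.append({**base, "converged": False, "error": str(exc)})
            continue
        params = {f"p_{sym}": v for sym, v in zip(spec.param_names, result.params)}
        rows.append({**base, "converged": True, **params,
                     "AARD_pct": result.aard, "R2": result.r2, "R_adj": result.r_adj,
                     "SSE": result.sse, "RMSE": result.rmse})
    report = pd.DataFrame(rows)
    if report.empty:
        return report
    for group in sorted(report["group"].dropna().unique()):
        sub = report[(report["group"] == group) & report.get("converged", False)]
        if len(sub) and "AARD_pct" in sub:
            rows.append({"model": f"average_group_{group}", "name": f"Average (Group {group})",
                         "group": group, "AARD_pct": float(sub["AARD_pct"].mean())})
    return pd.DataFrame(rows)
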