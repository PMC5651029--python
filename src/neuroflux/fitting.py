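"""Constrained least-squares fitting and Monte-Carlo uncertainty.

The model is fitted to the six amino-acid ¹³C turnover curves by
bounded trust-region nonlinear least squares.  The neurotransmitter
cycling fluxes are not free: the ratios V_cyc(Glu-Gln)/V_tca(Glu) and
V_cyc(GABA-Gln)/V_tca(GABA) are held at fixed region-specific values,
so every candidate (and every Monte-Carlo replicate) satisfies the
ratio constraints exactly by construction.  Ten fluxes are varied by
default: the three net TCA rates, the GABA shunt, pyruvate carboxylase,
the αKG↔glutamate exchange and the four dilution fluxes.

Uncertainty is estimated parametrically: Gaussian noise (multiplicative
CV with an additive enrichment floor) is added to the best-fit
noiseless curves, the fit is repeated per replicate, and the mean and
SD of each free flux over replicates are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fluxes import PRIMARY_FLUXES, FluxSet
from .model import (FITTED_CURVES, PlasmaInput, PoolSpec, measured_curves,
                    simulate_states)

__all__ = [
    "FitConstraints",
    "FitResult",
    "objective",
    "fit_model",
    "monte_carlo_uncertainty",
]

#: Default box bounds per free flux (μmol/g/min; v_x is an exchange rate
#: and may run much faster than the net fluxes).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    **{name: (1e-4, 3.0) for name in PRIMARY_FLUXES},
    "v_x": (0.02, 20.0),
}


@dataclass(frozen=True)
class FitConstraints:
    """Ratio constraints, free-parameter set and bounds for a fit."""

    ratio_glu: float
    ratio_gaba: float
    free_parameters: tuple[str, ...] = PRIMARY_FLUXES
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ratio_glu <= 0 or self.ratio_gaba <= 0:
            raise ValueError("ratio constraints must be positive")
        if not self.free_parameters:
            raise ValueError("free parameter set must be non-empty")
        unknown = set(self.free_parameters) - set(PRIMARY_FLUXES)
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        for name, (lo, hi) in self.bounds.items():
            if lo < 0 or hi <= lo:
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS[name])


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`fit_model`, optionally Monte-Carlo augmented."""

    fluxes: FluxSet
    objective: float
    residuals: pd.DataFrame
    converged: bool
    constraints: FitConstraints
    seed: int | None = None
    n_starts: int = 1
    weighting: str = "unit"
    monte_carlo_mean: dict[str, float] | None = None
    monte_carlo_sd: dict[str, float] | None = None
    n_replicates: int = 0
    n_dropped: int = 0


class _Problem:
    """Precomputed observation layout for fast repeated residual calls."""

    def __init__(self, data: pd.DataFrame, constraints: FitConstraints,
                 init: FluxSet, pools: PoolSpec, plasma: PlasmaInput,
                 method: str = "expm"):
        allowed = set(FITTED_CURVES)
        rows = data[[c in allowed for c in
                     zip(data["metabolite"], data["carbon_position"])]]
        if rows.empty:
            raise ValueError("data contains none of the fitted turnover curves")
        self.data = rows.reset_index(drop=True)
        self.times = np.sort(rows["time_min"].unique())
        self.curves = list(FITTED_CURVES)
        curve_ix = {c: i for i, c in enumerate(self.curves)}
        time_ix = {t: j for j, t in enumerate(self.times)}
        self.row_curve = np.array([
            curve_ix[(m, p)] for m, p in
            zip(self.data["metabolite"], self.data["carbon_position"])])
        self.row_time = np.array([time_ix[t] for t in self.data["time_min"]])
        self.obs = self.data["enrichment_fraction"].to_numpy(float)
        if "weight" in self.data.columns:
            w = self.data["weight"].to_numpy(float)
            if np.any(w <= 0):
                raise ValueError("weights must be positive")
            self.sqrt_w = np.sqrt(1.0 / w)
        else:
            self.sqrt_w = np.ones_like(self.obs)
        self.constraints = constraints
        self.init = init
        self.pools = pools
        self.plasma = plasma
        self.method = method
        self.free = tuple(constraints.free_parameters)
        self.fixed = {k: v for k, v in init.primary().items()
                      if k not in self.free}

    def fluxset(self, theta: np.ndarray) -> FluxSet:
        params = dict(self.fixed)
        params.update(zip(self.free, theta))
        return FluxSet.from_primary(
            ratio_glu=self.constraints.ratio_glu,
            ratio_gaba=self.constraints.ratio_gaba,
            **params)

    def predict(self, fluxes: FluxSet) -> np.ndarray:
        network, _, X = simulate_states(fluxes, self.pools, self.plasma,
                                        self.times, method=self.method)
        meas = measured_curves(network, self.pools, X)
        sim = np.stack([meas[c] for c in self.curves])  # (curve, time)
        return sim[self.row_curve, self.row_time]

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        return (self.predict(self.fluxset(theta)) - self.obs) * self.sqrt_w

    def theta0(self) -> np.ndarray:
        return np.array([getattr(self.init, name) for name in self.free])

    def box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.constraints.bound(n)[0] for n in self.free])
        hi = np.array([self.constraints.bound(n)[1] for n in self.free])
        return lo, hi


def objective(
    candidate: FluxSet,
    data: pd.DataFrame,
    pools: PoolSpec,
    plasma: PlasmaInput,
    *,
    constraints: FitConstraints | None = None,
    method: str = "expm",
) -> float:
    """Weighted sum of squared residuals of ``candidate`` against ``data``.

    Unit weights by default; a positive ``weight`` column in ``data``
    switches to inverse-variance weighting (residual² / weight).
    """
    if constraints is None:
        constraints = FitConstraints(
            ratio_glu=candidate.v_cyc_glu_gln / candidate.v_tca_glu,
            ratio_gaba=candidate.v_cyc_gaba_gln / candidate.v_tca_gaba)
    prob = _Problem(data, constraints, candidate, pools, plasma, method)
    r = (prob.predict(candidate) - prob.obs) * prob.sqrt_w
    return float(r @ r)


def fit_model(
    data: pd.DataFrame,
    constraints: FitConstraints,
    init: FluxSet,
    pools: PoolSpec,
    plasma: PlasmaInput,
    *,
    n_starts: int = 3,
    seed: int | None = 0,
    max_nfev: int = 500,
    method: str = "expm",
    weighting: str = "unit",
    noise_cv: float = 0.05,
    noise_floor: float = 0.005,
) -> FitResult:
    """Fit the three-compartment model to enrichment time courses.

    ``init`` supplies starting values for the free fluxes and fixed
    values for the rest; ``n_starts`` runs additional fits from
    log-normally jittered starting points as a guard against local
    minima and the best optimum is kept.  Non-convergence is reported
    through ``FitResult.converged`` rather than an exception.

    ``weighting`` selects the residual weights: ``"unit"`` (default)
    weighs every point equally; ``"variance"`` performs one
    iteratively-reweighted pass, deriving per-point inverse-variance
    weights max(noise_cv·ŷ, noise_floor)² from the unit-weight fit's
    own curves ŷ.  A positive ``weight`` (variance) column in ``data``
    always takes precedence.
    """
    if weighting not in ("unit", "variance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if data["time_min"].nunique() < 2:
        raise ValueError(
            "single-time-point data cannot constrain the kinetic model; "
            "use the initial-rate estimators (neuroflux.initial_rate)")
    prob = _Problem(data, constraints, init, pools, plasma, method)
    lo, hi = prob.box()
    rng = np.random.default_rng(seed)
    starts = [np.clip(prob.theta0(), lo, hi)]
    for _ in range(max(0, n_starts - 1)):
        jitter = np.exp(rng.normal(0.0, 0.2, size=len(prob.free)))
        starts.append(np.clip(starts[0] * jitter, lo, hi))

    best = None
    converged = False
    for theta0 in starts:
        sol = least_squares(prob.residuals, theta0, bounds=(lo, hi),
                            method="trf", max_nfev=max_nfev,
                            x_scale=np.maximum(theta0, 1e-3))
        if best is None or sol.cost < best.cost:
            best = sol
        converged = converged or (sol.status > 0)

    if weighting == "variance" and "weight" not in prob.data.columns:
        # one reweighting pass: inverse-variance weights from the
        # unit-weight fit's own predicted curves
        yhat = prob.predict(prob.fluxset(best.x))
        sd = np.maximum(noise_cv * np.abs(yhat), noise_floor)
        prob.sqrt_w = 1.0 / sd
        sol = least_squares(prob.residuals, best.x, bounds=(lo, hi),
                            method="trf", max_nfev=max_nfev,
                            x_scale=np.maximum(best.x, 1e-3))
        if sol.status > 0:
            best = sol
            converged = True

    fitted = prob.fluxset(best.x)
    res_df = prob.data.copy()
    res_df["simulated"] = prob.predict(fitted)
    res_df["residual"] = res_df["simulated"] - res_df["enrichment_fraction"]
    return FitResult(
        fluxes=fitted,
        objective=float(2.0 * best.cost),  # cost is 0.5 * sum r^2
        residuals=res_df,
        converged=converged,
        constraints=constraints,
        seed=seed,
        n_starts=len(starts),
        weighting=weighting,
    )


def monte_carlo_uncertainty(
    fit: FitResult,
    pools: PoolSpec,
    plasma: PlasmaInput,
    *,
    n_replicates: int = 500,
    noise_cv: float = 0.05,
    noise_floor: float = 0.005,
    seed: int = 0,
    max_nfev: int = 200,
    method: str = "expm",
) -> FitResult:
    """Parametric-bootstrap uncertainty for a converged fit.

    Regenerates the noiseless best-fit curves at the fitted data's
    sampling layout, adds per-point Gaussian noise with
    SD = max(noise_cv · value, noise_floor) to each of ``n_replicates``
    synthetic data sets, refits each from the point estimate, and
    stores the mean and SD of every free flux.  Fully deterministic
    given ``seed``.  Replicates whose refit fails to converge are
    dropped and counted; more than 10% dropped raises a warning.
    """
    if not fit.converged:
        raise ValueError("Monte-Carlo uncertainty requires a converged fit")
    constraints = fit.constraints
    data = fit.residuals.drop(columns=["simulated", "residual"])
    prob = _Problem(data, constraints, fit.fluxes, pools, plasma, method)
    noiseless = prob.predict(fit.fluxes)
    sd = np.maximum(noise_cv * np.abs(noiseless), noise_floor)
    if fit.weighting == "variance" and np.all(sd > 0):
        # replicate the original fit's inverse-variance weighting
        prob.sqrt_w = 1.0 / sd
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=(n_replicates, noiseless.size)) * sd

    lo, hi = prob.box()
    theta_hat = np.array([getattr(fit.fluxes, n) for n in prob.free])
    theta_hat = np.clip(theta_hat, lo, hi)
    samples = []
    dropped = 0
    for k in range(n_replicates):
        prob.obs = np.clip(noiseless + noise[k], 0.0, None)
        sol = least_squares(prob.residuals, theta_hat, bounds=(lo, hi),
                            method="trf", max_nfev=max_nfev,
                            x_scale=np.maximum(theta_hat, 1e-3))
        if sol.status > 0:
            samples.append(sol.x)
        else:
            dropped += 1
    if n_replicates and dropped > 0.1 * n_replicates:
        warnings.warn(
            f"{dropped}/{n_replicates} Monte-Carlo replicates failed to "
            "converge", RuntimeWarning, stacklevel=2)
    arr = np.asarray(samples)
    mc_mean = dict(zip(prob.free, arr.mean(axis=0))) if len(arr) else None
    mc_sd = dict(zip(prob.free, arr.std(axis=0, ddof=1))) if len(arr) > 1 else (
        dict(zip(prob.free, np.zeros(len(prob.free)))) if len(arr) else None)
    return dc_replace(fit, monte_carlo_mean=mc_mean, monte_carlo_sd=mc_sd,
                      n_replicates=n_replicates, n_dropped=dropped, seed=seed)
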