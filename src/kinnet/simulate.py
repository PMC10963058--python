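"""Deterministic simulation: ODE time courses, steady states, parameter scans.

The reaction network is compiled into d[X]/dt = N v(X) where N is the
stoichiometric matrix over the free (non-fixed) metabolites and v the
vector of rate-law velocities.  Time courses are integrated with the
stiffness-switching LSODA solver; steady states are sought by Newton-type
root-finding on the right-hand side with a long-horizon integration
fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import ConfigurationError, LookupErrorKN, SolverError
from .model import Model, get_parameter, set_parameter

DEFAULT_REL_TOL = 1e-6
DEFAULT_ABS_TOL = 1e-12
DEFAULT_N_POINTS = 1000

#: horizon cap for the steady-state integration fallback (in model time units)
STEADY_STATE_HORIZON = 1e7


@dataclass
class Trajectory:
    """Time-indexed concentration matrix from a deterministic simulation."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (n_times, n_metabolites)
    metabolite_order: list[str]
    solver_diagnostics: dict = field(default_factory=dict)

    def final_state(self) -> dict[str, float]:
        return dict(zip(self.metabolite_order, self.concentrations[-1]))

    def column(self, metabolite_id: str) -> np.ndarray:
        try:
            j = self.metabolite_order.index(metabolite_id)
        except ValueError:
            raise LookupErrorKN(f"no metabolite {metabolite_id!r} in trajectory")
        return self.concentrations[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations, columns=self.metabolite_order)
        df.insert(0, "time", self.times)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SteadyStateResult:
    concentrations: dict[str, float]
    residual_norm: float
    status: Literal["found", "not_found"]
    fluxes: dict[str, float] = field(default_factory=dict)
    method: str = ""

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "status": self.status,
                "method": self.method,
                "residual_norm": self.residual_norm,
                "concentrations": self.concentrations,
                "fluxes": self.fluxes,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class ScanItem:
    """One perturbed quantity: a parameter path and its two endpoint values."""

    target: str
    initial_value: float
    final_value: float


class _CompiledSystem:
    """The ODE right-hand side compiled from a model."""

    def __init__(self, model: Model):
        model.validate()
        unparameterized = [r.id for r in model.reactions if r.rate_law is None]
        if unparameterized:
            raise ConfigurationError(
                f"model {model.id!r} has unparameterized reactions: "
                f"{unparameterized}"
            )
        self.model = model
        self.all_ids = model.metabolite_ids
        self.free_ids = [m.id for m in model.metabolites if not m.fixed]
        self.fixed_env = {
            m.id: m.initial_concentration for m in model.metabolites if m.fixed
        }
        self.index = {sid: i for i, sid in enumerate(self.free_ids)}

        self.rates = []
        n_free, n_rxn = len(self.free_ids), len(model.reactions)
        self.N = np.zeros((n_free, n_rxn))
        volumes = dict(model.compartments)
        for j, r in enumerate(model.reactions):
            env_params = dict(volumes)
            env_params.update(model.global_parameters)
            env_params.update(r.parameter_values)
            self.rates.append((r.rate_expression(), env_params))
            for sid, coef in r.reactants.items():
                if sid in self.index:
                    self.N[self.index[sid], j] -= coef
            for sid, coef in r.products.items():
                if sid in self.index:
                    self.N[self.index[sid], j] += coef

    def x0(self) -> np.ndarray:
        return np.array(
            [self.model.metabolite(sid).initial_concentration for sid in self.free_ids]
        )

    def velocities(self, x: np.ndarray) -> np.ndarray:
        env_conc = dict(zip(self.free_ids, np.maximum(x, 0.0)))
        env_conc.update(self.fixed_env)
        v = np.empty(len(self.rates))
        for j, (expr, params) in enumerate(self.rates):
            v[j] = expr({**params, **env_conc})
        return v

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.N @ self.velocities(x)

    def full_state(self, x_free: np.ndarray) -> dict[str, float]:
        state = dict(zip(self.free_ids, x_free))
        state.update(self.fixed_env)
        return state


def simulate_time_course(
    model: Model,
    duration: float,
    n_points: int = DEFAULT_N_POINTS,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
) -> Trajectory:
    """Integrate the reaction ODEs over ``[0, duration]``.

    Output is sampled at ``n_points + 1`` uniform times including t=0 and
    t=duration.  Fixed metabolites are held at their initial value.  Tiny
    negative solver excursions (within ``abs_tol``-scale) are clamped to
    zero; anything larger raises :class:`SolverError`.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    sys = _CompiledSystem(model)
    t_eval = np.linspace(0.0, duration, n_points + 1)
    sol = solve_ivp(
        sys.rhs,
        (0.0, duration),
        sys.x0(),
        method="LSODA",
        t_eval=t_eval,
        rtol=rel_tol,
        atol=abs_tol,
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        raise SolverError(
            f"integration failed at t={last_t:g}: {sol.message}"
        )
    X_free = sol.y.T
    neg_floor = -max(abs_tol, 1e-9) * max(1.0, float(np.max(np.abs(X_free))))
    if np.any(X_free < neg_floor):
        raise SolverError(
            f"solution went negative beyond tolerance (min {X_free.min():g})"
        )
    X_free = np.clip(X_free, 0.0, None)

    # assemble full matrix in model metabolite order, fixed columns constant
    n_t = len(t_eval)
    full = np.empty((n_t, len(sys.all_ids)))
    for k, sid in enumerate(sys.all_ids):
        if sid in sys.index:
            full[:, k] = X_free[:, sys.index[sid]]
        else:
            full[:, k] = sys.fixed_env[sid]
    return Trajectory(
        times=t_eval,
        concentrations=full,
        metabolite_order=list(sys.all_ids),
        solver_diagnostics={
            "n_rhs_evaluations": int(sol.nfev),
            "n_jacobian_evaluations": int(sol.njev),
            "rel_tol": rel_tol,
            "abs_tol": abs_tol,
            "method": "LSODA",
        },
    )


def find_steady_state(
    model: Model,
    tolerance: float = 1e-9,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
) -> SteadyStateResult:
    """Find concentrations where every free species' net rate is zero.

    Strategy: Newton-type root-finding on the right-hand side from the
    initial state; if that fails (non-convergence or a negative solution),
    fall back to integrating forward until ``||dX/dt||_inf < tolerance``
    or a horizon cap is reached.  A divergent system yields
    ``status="not_found"`` rather than an exception.
    """
    sys = _CompiledSystem(model)
    x0 = sys.x0()

    def residual(x: np.ndarray) -> float:
        return float(np.max(np.abs(sys.rhs(0.0, x)))) if x.size else 0.0

    if not sys.free_ids:
        return SteadyStateResult(
            concentrations=sys.full_state(x0),
            residual_norm=0.0,
            status="found",
            fluxes=_fluxes(sys, x0),
            method="trivial",
        )

    # conservation constraints: Newton can slide off the stoichiometric
    # compatibility class of the initial state, so solutions violating a
    # left-null-space invariant are rejected in favour of integration
    from scipy.linalg import null_space

    L = null_space(sys.N.T) if sys.N.size else np.zeros((len(x0), 0))

    def on_compatibility_class(x: np.ndarray) -> bool:
        if L.shape[1] == 0:
            return True
        drift = L.T @ (x - x0)
        scale = max(1.0, float(np.max(np.abs(x0))))
        return bool(np.max(np.abs(drift)) <= 1e-9 * scale)

    try:
        sol = root(lambda x: sys.rhs(0.0, x), x0, method="hybr")
        if sol.success and np.all(sol.x >= -tolerance) and on_compatibility_class(sol.x):
            x = np.clip(sol.x, 0.0, None)
            res = residual(x)
            if res <= tolerance:
                return SteadyStateResult(
                    concentrations=sys.full_state(x),
                    residual_norm=res,
                    status="found",
                    fluxes=_fluxes(sys, x),
                    method="newton",
                )
    except Exception:
        pass

    # integration fallback: geometric horizon doubling
    x = x0
    t_reached = 0.0
    horizon = 10.0
    while t_reached < STEADY_STATE_HORIZON:
        span = min(horizon, STEADY_STATE_HORIZON - t_reached)
        try:
            sol_ivp = solve_ivp(
                sys.rhs,
                (0.0, span),
                x,
                method="LSODA",
                rtol=rel_tol,
                atol=abs_tol,
            )
        except Exception:
            break
        if not sol_ivp.success:
            break
        x = np.clip(sol_ivp.y[:, -1], 0.0, None)
        t_reached += span
        res = residual(x)
        if res < tolerance:
            return SteadyStateResult(
                concentrations=sys.full_state(x),
                residual_norm=res,
                status="found",
                fluxes=_fluxes(sys, x),
                method="integration",
            )
        horizon *= 10.0
    return SteadyStateResult(
        concentrations=sys.full_state(x),
        residual_norm=residual(x),
        status="not_found",
        method="none",
    )


def _fluxes(sys: _CompiledSystem, x: np.ndarray) -> dict[str, float]:
    v = sys.velocities(x)
    return {r.id: float(v[j]) for j, r in enumerate(sys.model.reactions)}


def parameter_scan(
    model: Model,
    items: Sequence[ScanItem],
    mode: Literal["timecourse", "steadystate"] = "timecourse",
    duration: float = 100.0,
    n_points: int = DEFAULT_N_POINTS,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
):
    """Run the model once at every item's initial value and once at its
    final value; return ``(baseline_output, perturbed_output)``.

    The model's stored values are restored afterwards (the scan operates
    on an internal copy), so the model serializes identically before and
    after.
    """
    for item in items:
        get_parameter(model, item.target)  # raises LookupErrorKN early

    def run(values: Sequence[float]):
        work = model.copy()
        for item, value in zip(items, values):
            set_parameter(work, item.target, value)
        if mode == "timecourse":
            return simulate_time_course(work, duration, n_points, rel_tol, abs_tol)
        if mode == "steadystate":
            return find_steady_state(work, rel_tol=rel_tol, abs_tol=abs_tol)
        raise ConfigurationError(f"unknown scan mode {mode!r}")

    baseline = run([item.initial_value for item in items])
    perturbed = run([item.final_value for item in items])
    return baseline, perturbed
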