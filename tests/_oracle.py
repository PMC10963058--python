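"""Independent fixed-step RK4 integrator used as a simulation oracle.

Deliberately avoids the package's solver path: it builds its own rate
evaluation from the model structure and steps with classical
Runge-Kutta, so agreement with the adaptive solver is a genuine
cross-check.
"""

from __future__ import annotations

import numpy as np

from kinnet.model import Model


def _rate(reaction, model, state):
    law = reaction.rate_law
    params = dict(model.global_parameters)
    params.update(reaction.parameter_values)
    if law.kind == "mass_action_irreversible":
        v = params["k"]
        for sid, coef in reaction.reactants.items():
            v *= state[sid] ** coef
        return v
    if law.kind == "mass_action_reversible":
        vf, vr = params["kf"], params["kr"]
        for sid, coef in reaction.reactants.items():
            vf *= state[sid] ** coef
        for sid, coef in reaction.products.items():
            vr *= state[sid] ** coef
        return vf - vr
    if law.kind == "michaelis_menten_irreversible":
        (sid,) = reaction.reactants
        s = state[sid]
        return params["V"] * s / (params["Km"] + s)
    raise NotImplementedError(law.kind)


def rk4_time_course(model: Model, duration: float, n_steps: int) -> dict[str, np.ndarray]:
    """Classical RK4 at fixed step duration/n_steps; returns each free
    metabolite's sampled series (including t=0)."""
    free = [m.id for m in model.metabolites if not m.fixed]
    fixed = {m.id: m.initial_concentration for m in model.metabolites if m.fixed}
    x = np.array([model.metabolite(s).initial_concentration for s in free])

    def f(x):
        state = dict(zip(free, x))
        state.update(fixed)
        dx = np.zeros_like(x)
        for r in model.reactions:
            v = _rate(r, model, state)
            for sid, coef in r.reactants.items():
                if sid in fixed:
                    continue
                dx[free.index(sid)] -= coef * v
            for sid, coef in r.products.items():
                if sid in fixed:
                    continue
                dx[free.index(sid)] += coef * v
        return dx

    h = duration / n_steps
    out = [x.copy()]
    for _ in range(n_steps):
        k1 = f(x)
        k2 = f(x + 0.5 * h * k1)
        k3 = f(x + 0.5 * h * k2)
        k4 = f(x + h * k3)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(x.copy())
    arr = np.array(out)
    return {sid: arr[:, j] for j, sid in enumerate(free)}
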