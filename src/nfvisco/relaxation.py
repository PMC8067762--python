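"""Relaxation-modulus construction and Prony-series fitting.

After a step stretch to hold strain eps0, the relaxation modulus is
E(t) = sigma(t) / eps0 with time re-zeroed at the start of the hold
(loading-phase samples are excluded: at the high pulling rates considered
the loading transient is short against the hold and its response can be
ignored).  The trace is then fitted to the generalized-Maxwell form

    E(t) = E1 + sum_i Ei * exp(-t / tau_i)

by minimizing the L2 norm of the residual with a derivative-free simplex
search (Nelder-Mead) under multi-start.  Non-negativity of the moduli and
positivity of the relaxation times are enforced structurally: the search
runs over sqrt(Ei) and log(tau_i), so every candidate the simplex visits
maps to an admissible model.

The "three-parameter model" is one branch plus the long-term modulus; when
the fitted long-term modulus is negligible against E(0) the material is
reclassified as a "two-parameter model" and refitted with E1 pinned to 0.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .exceptions import FitFailureError, InsufficientDataError, ParameterError
from .models import FitResult, GroupStressSeries, PronyModel, RelaxationTrace

THREE_PARAMETER = "three_parameter"
TWO_PARAMETER = "two_parameter"


def relaxation_modulus(
    stress: GroupStressSeries,
    hold_strain: float,
    hold_start: float = 0.0,
) -> RelaxationTrace:
    """Relaxation modulus E(t) = axial stress(t) / hold_strain.

    Samples before ``hold_start`` (ps) belong to the loading phase and are
    dropped; time is re-zeroed at the first retained sample.
    """
    if hold_strain <= 0:
        raise ParameterError(f"hold_strain must be > 0, got {hold_strain}")
    mask = stress.time >= hold_start
    if not np.any(mask):
        raise ParameterError("stress series does not cover the hold period")
    t = stress.time[mask]
    return RelaxationTrace(
        time=t - t[0],
        modulus=stress.axial_stress[mask] / hold_strain,
        hold_strain=hold_strain,
    )


def evaluate(model: PronyModel, t):
    """E(t) in GPa; module-level alias for :meth:`PronyModel.evaluate`."""
    return model.evaluate(t)


# ---------------------------------------------------------------------------
# fitting


def _pack(model: PronyModel, pin_long_term: bool) -> np.ndarray:
    theta = [] if pin_long_term else [np.sqrt(model.long_term)]
    for e, tau in model.branches:
        theta += [np.sqrt(e), np.log(tau)]
    return np.array(theta)


def _unpack(theta: np.ndarray, n_branches: int, pin_long_term: bool) -> PronyModel:
    k = 0 if pin_long_term else 1
    long_term = 0.0 if pin_long_term else theta[0] ** 2
    branches = tuple(
        (theta[k + 2 * i] ** 2, float(np.exp(theta[k + 2 * i + 1])))
        for i in range(n_branches)
    )
    return PronyModel(long_term, branches)


def _initial_guess(trace: RelaxationTrace, n_branches: int) -> PronyModel:
    """Deterministic, scale-free starting model.

    E1 from the tail mean (last 10% of samples), the instantaneous excess
    E(0)-E1 split equally across branches, and relaxation times from the
    1/e crossing of the decaying part (log-spaced around it for multiple
    branches).
    """
    e_inf = float(np.mean(trace.modulus[-max(1, len(trace) // 10):]))
    e_inf = max(e_inf, 0.0)
    e0 = float(trace.modulus[0])
    decay = max(e0 - e_inf, 1e-12)
    target = e_inf + decay / np.e
    below = np.nonzero(trace.modulus <= target)[0]
    t_end = trace.time[-1] if trace.time[-1] > 0 else 1.0
    tau0 = float(trace.time[below[0]]) if below.size and trace.time[below[0]] > 0 else t_end / 3.0
    if n_branches == 1:
        taus = [tau0]
    else:  # spread starts over two decades around the crossing time
        taus = list(np.geomspace(tau0 / 3.0, tau0 * 3.0, n_branches))
    return PronyModel(e_inf, tuple((decay / n_branches, tau) for tau in taus))


def fit_prony(
    trace: RelaxationTrace,
    n_branches: int = 1,
    restarts: int = 8,
    seed: int = 0,
    pin_long_term: bool = False,
    threshold_frac: float | None = None,
) -> FitResult:
    """Fit a Prony series to a relaxation trace by multi-start Nelder-Mead.

    Parameters
    ----------
    n_branches:
        Number of exponential branches (1 gives the three-parameter model).
    restarts:
        Additional starts beyond the deterministic initial guess; each
        jitters every packed parameter by an independent U(0.5, 2) factor
        drawn from ``seed``.
    pin_long_term:
        Fit with E1 fixed at 0 (the two-parameter family).
    threshold_frac:
        If given, apply :func:`select_form` with this threshold and refit
        with E1 pinned when the two-parameter form is selected.

    Returns the best restart; raises :class:`FitFailureError` with
    per-start diagnostics if no start converges.
    """
    n_params = 1 + 2 * n_branches
    if len(trace) < 3 * n_params:
        raise InsufficientDataError(
            f"need at least {3 * n_params} samples to fit {n_params} parameters, "
            f"got {len(trace)}"
        )
    if restarts < 0:
        raise ParameterError("restarts must be >= 0")

    y = trace.modulus
    t = trace.time

    def objective(theta: np.ndarray) -> float:
        model = _unpack(theta, n_branches, pin_long_term)
        return float(np.linalg.norm(model.evaluate(t) - y))

    start = _pack(_initial_guess(trace, n_branches), pin_long_term)
    rng = np.random.default_rng(seed)
    starts = [start]
    for _ in range(restarts):
        starts.append(start * rng.uniform(0.5, 2.0, size=start.shape))

    best = None
    diagnostics = []
    for i, theta0 in enumerate(starts):
        res = minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            options={
                "xatol": 1e-8,
                "fatol": 1e-8,
                "maxfev": 10_000,
                "maxiter": 10_000,
            },
        )
        diagnostics.append(
            {"start": i, "converged": bool(res.success), "objective": float(res.fun)}
        )
        if res.success and (best is None or res.fun < best[0]):
            best = (float(res.fun), res.x, i)
    if best is None:
        raise FitFailureError(
            "Prony fit failed to converge from every start", diagnostics
        )

    objective_value, theta, _ = best
    model = _unpack(theta, n_branches, pin_long_term).canonical()
    result = FitResult(
        model=model,
        objective=objective_value,
        n_restarts_used=len(starts),
        selected_form=TWO_PARAMETER if pin_long_term else THREE_PARAMETER,
    )
    if threshold_frac is not None and not pin_long_term:
        form = select_form(result, threshold_frac)
        if form == TWO_PARAMETER:
            result = fit_prony(
                trace,
                n_branches=n_branches,
                restarts=restarts,
                seed=seed,
                pin_long_term=True,
            )
    return result


def select_form(result: FitResult, threshold_frac: float = 0.01) -> str:
    """Classify a fit as two- or three-parameter.

    Two-parameter iff the fitted long-term modulus is below
    ``threshold_frac * E(0)`` — the material relaxes to (numerically)
    zero stress, as observed at the higher pulling rate.
    """
    e0 = result.model.instantaneous
    if e0 <= 0:
        return TWO_PARAMETER
    return (
        TWO_PARAMETER
        if result.model.long_term < threshold_frac * e0
        else THREE_PARAMETER
    )
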