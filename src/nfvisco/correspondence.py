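"""Elastic-viscoelastic correspondence: E(t) -> G(t), K(t).

Alfrey's correspondence principle maps the elastic relations between
Young's, shear, and bulk moduli into the Laplace domain:

    G*(s) = E*(s) / (2 (1 + nu*(s)))
    K*(s) = E*(s) / (3 (1 - 2 nu*(s)))

For a constant Poisson's ratio nu the division commutes with the inverse
Laplace transform, so a Prony-series relaxation modulus converts in closed
form: every modulus (long-term and each branch) is scaled by 1/(2(1+nu))
for shear and 1/(3(1-2nu)) for bulk, and the relaxation times are
unchanged:

    G(t) = G1 + G2 exp(-t/tau),   Gi = Ei / (2 (1 + nu))
    K(t) = K1 + K2 exp(-t/tau),   Ki = Ei / (3 (1 - 2 nu))

The closed form is the primary path; :func:`inverse_laplace_check`
re-derives G(t) and K(t) by numerical inversion (mpmath's Talbot contour)
of the Laplace-domain expressions and serves as an independent oracle.

K diverges in the incompressible limit nu -> 0.5; conversions at
nu >= 0.5 raise :class:`SingularityError` saying so.
"""

from __future__ import annotations

import warnings

import mpmath
import numpy as np
import pandas as pd

from .exceptions import ParameterError, SingularityError
from .models import ConvertedModuli, PronyModel

#: default Poisson's ratios: a compressible and a nearly incompressible case
DEFAULT_POISSONS = (0.33, 0.48)


def _check_poisson(poisson: float) -> float:
    if not 0 <= poisson:
        raise ParameterError(f"Poisson's ratio must be >= 0, got {poisson}")
    if poisson >= 0.5:
        raise SingularityError(
            f"Poisson's ratio {poisson} is at or beyond the incompressible "
            "limit: the bulk modulus diverges as nu -> 0.5"
        )
    return float(poisson)


def to_shear(model: PronyModel, poisson: float) -> PronyModel:
    """Shear Prony parameters: Gi = Ei / (2 (1 + nu)), tau unchanged."""
    nu = _check_poisson(poisson)
    f = 1.0 / (2.0 * (1.0 + nu))
    return PronyModel(
        model.long_term * f, tuple((e * f, tau) for e, tau in model.branches)
    )


def to_bulk(model: PronyModel, poisson: float) -> PronyModel:
    """Bulk Prony parameters: Ki = Ei / (3 (1 - 2 nu)), tau unchanged."""
    nu = _check_poisson(poisson)
    f = 1.0 / (3.0 * (1.0 - 2.0 * nu))
    return PronyModel(
        model.long_term * f, tuple((e * f, tau) for e, tau in model.branches)
    )


def convert(model: PronyModel, poisson: float) -> ConvertedModuli:
    """Closed-form conversion to shear and bulk moduli at constant nu."""
    return ConvertedModuli(
        poisson=float(poisson),
        shear=to_shear(model, poisson),
        bulk=to_bulk(model, poisson),
    )


def _laplace_modulus(model: PronyModel, s):
    """L[E](s) = E1/s + sum Ei / (s + 1/tau_i)."""
    out = model.long_term / s
    for e, tau in model.branches:
        out += e / (s + 1.0 / tau)
    return out


def inverse_laplace_check(
    model: PronyModel,
    poisson: float,
    t_grid,
    dps: int = 30,
    method: str = "talbot",
) -> tuple[np.ndarray, np.ndarray]:
    """Numerically invert the Laplace-domain G*(s), K*(s) on ``t_grid``.

    Returns (G(t), K(t)) samples in GPa.  This is an independent check of
    the closed-form conversion: it never calls :func:`to_shear` or
    :func:`to_bulk`, only the Laplace-domain expressions and a standard
    contour inversion.  Points where the inversion is unstable are
    reported with a warning and returned as NaN, never smoothed over.
    """
    nu = _check_poisson(poisson)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid <= 0):
        raise ParameterError("numerical inversion requires t > 0")

    g_factor = 1.0 / (2.0 * (1.0 + nu))
    k_factor = 1.0 / (3.0 * (1.0 - 2.0 * nu))

    def g_bar(s):
        return _laplace_modulus(model, s) * g_factor

    def k_bar(s):
        return _laplace_modulus(model, s) * k_factor

    g_out = np.empty_like(t_grid)
    k_out = np.empty_like(t_grid)
    failed = []
    with mpmath.workdps(dps):
        for i, t in enumerate(t_grid):
            try:
                g_out[i] = float(mpmath.invertlaplace(g_bar, t, method=method))
                k_out[i] = float(mpmath.invertlaplace(k_bar, t, method=method))
            except Exception:
                failed.append(t)
                g_out[i] = np.nan
                k_out[i] = np.nan
    if failed:
        warnings.warn(
            f"Laplace inversion unstable at t = {failed} ps; returned NaN",
            stacklevel=2,
        )
    return g_out, k_out


def moduli_table(
    models: dict[str, PronyModel], poissons=DEFAULT_POISSONS
) -> pd.DataFrame:
    """Shear/bulk parameter table for one-branch models.

    Rows G1, G2, tau_G, K1, K2, tau_K (GPa / ps); one column per
    (Poisson's ratio, model label) pair.
    """
    columns = {}
    for nu in poissons:
        for label, model in models.items():
            if len(model.branches) != 1:
                raise ParameterError(
                    "moduli_table expects one-branch (three-parameter) models"
                )
            conv = convert(model, nu)
            (g2, tau_g), = conv.shear.branches
            (k2, tau_k), = conv.bulk.branches
            columns[(f"nu={nu}", label)] = [
                conv.shear.long_term, g2, tau_g,
                conv.bulk.long_term, k2, tau_k,
            ]
    index = ["G1_GPa", "G2_GPa", "tau_G_ps", "K1_GPa", "K2_GPa", "tau_K_ps"]
    return pd.DataFrame(columns, index=index)
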