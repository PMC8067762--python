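"""Core domain containers.

The central object is :class:`PronyModel`, a generalized-Maxwell (Prony
series) relaxation modulus

    E(t) = E1 + sum_i Ei * exp(-t / tau_i)

with the long-term modulus ``E1`` in GPa and relaxation times ``tau_i`` in
ps.  The one-branch case is the "three-parameter model" (E1, E2, tau); with
E1 pinned to zero it degenerates to the "two-parameter model" of a pure
Maxwell element.  Time-series containers (relaxation traces, stress-strain
curves, group stress/strain series) are thin wrappers over numpy arrays
with the invariants each pipeline stage relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ParameterError

#: 1 atm expressed in GPa; per-atom stress*volume output is atm*A^3 in the
#: LAMMPS "real" unit convention, so stress/volume comes out in atm.
ATM_TO_GPA = 1.01325e-4

#: order of the six independent components of a symmetric stress tensor
STRESS_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclass(frozen=True)
class PronyModel:
    """Prony-series relaxation modulus E(t) = E1 + sum Ei exp(-t/tau_i).

    Parameters
    ----------
    long_term:
        Long-term (equilibrium) modulus E1 in GPa; must be >= 0.
    branches:
        Sequence of ``(Ei, tau_i)`` pairs, moduli in GPa, relaxation times
        in ps; all Ei >= 0 and tau_i > 0.
    """

    long_term: float
    branches: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.long_term < 0:
            raise ParameterError(f"long_term modulus must be >= 0, got {self.long_term}")
        object.__setattr__(self, "long_term", float(self.long_term))
        branches = tuple((float(e), float(tau)) for e, tau in self.branches)
        for e, tau in branches:
            if e < 0:
                raise ParameterError(f"branch modulus must be >= 0, got {e}")
            if tau <= 0:
                raise ParameterError(f"relaxation time must be > 0, got {tau}")
        object.__setattr__(self, "branches", branches)

    @property
    def n_params(self) -> int:
        """1 (long-term) + 2 per branch; 3 for the one-branch model."""
        return 1 + 2 * len(self.branches)

    @property
    def instantaneous(self) -> float:
        """E(0) = E1 + sum Ei."""
        return self.long_term + sum(e for e, _ in self.branches)

    def evaluate(self, t):
        """Evaluate E(t) in GPa at time(s) ``t`` (ps, t >= 0)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ParameterError("relaxation modulus is defined for t >= 0 only")
        out = np.full_like(t, self.long_term, dtype=float)
        for e, tau in self.branches:
            out = out + e * np.exp(-t / tau)
        return out if out.ndim else float(out)

    def canonical(self) -> "PronyModel":
        """Branches sorted by increasing relaxation time."""
        return PronyModel(self.long_term, tuple(sorted(self.branches, key=lambda b: b[1])))

    def to_dict(self) -> dict:
        return {
            "long_term_GPa": self.long_term,
            "branches": [{"modulus_GPa": e, "tau_ps": tau} for e, tau in self.branches],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PronyModel":
        return cls(
            d["long_term_GPa"],
            tuple((b["modulus_GPa"], b["tau_ps"]) for b in d["branches"]),
        )

    @classmethod
    def from_json(cls, path) -> "PronyModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _ascending(name: str, arr: np.ndarray):
    if arr.ndim != 1:
        raise ParameterError(f"{name} must be one-dimensional")
    if len(arr) > 1 and not np.all(np.diff(arr) > 0):
        raise ParameterError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class RelaxationTrace:
    """Relaxation modulus samples E(t) at a fixed hold strain.

    Time is measured in ps from the start of the hold (time[0] == 0);
    modulus in GPa; ``hold_strain`` is the dimensionless engineering
    strain held during relaxation.
    """

    time: np.ndarray
    modulus: np.ndarray
    hold_strain: float

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        modulus = np.asarray(self.modulus, dtype=float)
        _ascending("time", time)
        if len(time) != len(modulus):
            raise ParameterError("time and modulus must have equal length")
        if len(time) and time[0] != 0:
            raise ParameterError("relaxation trace time must start at 0")
        if self.hold_strain <= 0:
            raise ParameterError(f"hold_strain must be > 0, got {self.hold_strain}")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "modulus", modulus)

    def __len__(self):
        return len(self.time)


@dataclass(frozen=True)
class StressStrainCurve:
    """Engineering strain vs axial stress (GPa) at a nominal strain rate."""

    strain: np.ndarray
    stress: np.ndarray
    strain_rate: float
    label: str = "synthetic"

    def __post_init__(self):
        strain = np.asarray(self.strain, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        if strain.ndim != 1 or len(strain) != len(stress):
            raise ParameterError("strain and stress must be equal-length vectors")
        if len(strain) > 1 and np.any(np.diff(strain) < 0):
            raise ParameterError("strain must be non-decreasing")
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress", stress)

    def __len__(self):
        return len(self.strain)


@dataclass(frozen=True)
class GroupStressSeries:
    """Group stress tensor (GPa, components xx,yy,zz,xy,xz,yz) over time (ps)."""

    time: np.ndarray
    stress_tensor: np.ndarray  # shape (n, 6)
    axial_stress: np.ndarray  # GPa, normal component along the pulling axis

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        tensor = np.asarray(self.stress_tensor, dtype=float)
        axial = np.asarray(self.axial_stress, dtype=float)
        _ascending("time", time)
        if tensor.shape != (len(time), 6):
            raise ParameterError("stress_tensor must have shape (n_times, 6)")
        if len(axial) != len(time):
            raise ParameterError("axial_stress must match time length")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "stress_tensor", tensor)
        object.__setattr__(self, "axial_stress", axial)

    def __len__(self):
        return len(self.time)


@dataclass(frozen=True)
class StrainSeries:
    """Engineering strain of the pulled group over time (ps); strain(0) = 0."""

    time: np.ndarray
    strain: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        strain = np.asarray(self.strain, dtype=float)
        _ascending("time", time)
        if len(strain) != len(time):
            raise ParameterError("strain must match time length")
        if len(strain) and abs(strain[0]) > 1e-12:
            raise ParameterError("strain must be 0 at the first frame")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "strain", strain)

    def __len__(self):
        return len(self.time)


@dataclass(frozen=True)
class StiffnessEstimate:
    """OLS slope of stress vs strain over a strain window."""

    window: tuple[float, float]
    slope: float  # GPa
    intercept: float  # GPa
    residual_rms: float  # GPa
    n_points: int = 0


@dataclass(frozen=True)
class FitResult:
    """Outcome of a Prony-series fit."""

    model: PronyModel
    objective: float  # L2 norm of residuals, GPa
    n_restarts_used: int
    selected_form: str  # "two_parameter" | "three_parameter"

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "objective_GPa": self.objective,
            "n_restarts_used": self.n_restarts_used,
            "selected_form": self.selected_form,
        }


@dataclass(frozen=True)
class ConvertedModuli:
    """Shear and bulk Prony parameters for a given (constant) Poisson's ratio."""

    poisson: float
    shear: PronyModel
    bulk: PronyModel

    def to_dict(self) -> dict:
        return {
            "poisson": self.poisson,
            "shear": self.shear.to_dict(),
            "bulk": self.bulk.to_dict(),
        }
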