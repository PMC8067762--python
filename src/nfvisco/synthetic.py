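"""Synthetic stand-ins for steered-MD output, with known ground truth.

Three generators cover the three kinds of raw material the pipeline
consumes:

* relaxation traces E(t) = E1 + sum Ei exp(-t/tau_i) + Gaussian noise,
  sampled on a uniform ps grid (a 1 ns hold at the paper-scale defaults);
* two-stage tensile curves: a low-slope unfolding segment followed by a
  stiffer stretching segment, continuous at the breakpoint, with additive
  Gaussian fluctuation — higher nominal strain rates are emulated simply
  by prescribing a steeper stretch slope;
* toy trajectory frames whose per-atom stress*volume entries sum, by
  construction, to a prescribed group stress tensor, so the extraction
  stage can be checked against an exact prescription.

All generators are deterministic given their seed.  The noise models are
the simplest ones that exercise the downstream fitters: additive i.i.d.
Gaussian on the sampled values.  Real MD fluctuations are correlated in
time and strain; see the methods note for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ParameterError
from .models import ATM_TO_GPA, PronyModel, RelaxationTrace, StressStrainCurve
from .trajectory import AtomFrame, voronoi_volumes

#: hold strain of the relaxation protocol (80% pre-stretch)
DEFAULT_HOLD_STRAIN = 0.8


@dataclass(frozen=True)
class RelaxationGenSpec:
    """Parameters for a synthetic relaxation trace.

    duration/dt in ps, noise_sd in GPa.  Defaults mirror the 1 ns hold at
    1 ps sampling; noise_sd default 0.05 GPa is a documented choice (about
    5% of a ~1 GPa instantaneous modulus), not a measured value.
    """

    model: PronyModel
    duration: float = 1000.0
    dt: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0
    hold_strain: float = DEFAULT_HOLD_STRAIN

    def __post_init__(self):
        if self.duration <= 0 or self.dt <= 0:
            raise ParameterError("duration and dt must be positive")
        if self.dt > self.duration:
            raise ParameterError("dt must not exceed duration")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.hold_strain <= 0:
            raise ParameterError("hold_strain must be > 0")


@dataclass(frozen=True)
class TensileGenSpec:
    """Parameters for a synthetic two-stage tensile curve.

    Slopes in GPa (stress per unit engineering strain); the unfolding
    segment runs on [0, unfold_end_strain], the stretching segment on
    [unfold_end_strain, max_strain], continuous at the breakpoint.
    """

    strain_rate: float = 1e8
    max_strain: float = 2.2
    unfold_end_strain: float = 1.5
    unfold_slope: float = 0.05
    stretch_slope: float = 0.5
    fluctuation_sd: float = 0.02
    seed: int = 0
    n_points: int = 500
    label: str = "synthetic"

    def __post_init__(self):
        if self.max_strain <= 0:
            raise ParameterError("max_strain must be > 0")
        if not 0 < self.unfold_end_strain < self.max_strain:
            raise ParameterError("need 0 < unfold_end_strain < max_strain")
        if not self.stretch_slope > self.unfold_slope >= 0:
            raise ParameterError("need stretch_slope > unfold_slope >= 0")
        if self.fluctuation_sd < 0:
            raise ParameterError("fluctuation_sd must be >= 0")
        if self.n_points < 2:
            raise ParameterError("n_points must be >= 2")


@dataclass(frozen=True)
class FrameGenSpec:
    """Parameters for toy trajectory frames with prescribed group stress.

    ``stress_history`` is one target stress tensor (GPa) per frame; each
    entry may be a scalar p (isotropic diag(p,p,p)), a 6-vector
    (xx,yy,zz,xy,xz,yz), or a symmetric 3x3 matrix.
    """

    n_atoms: int = 50
    box_edge: float = 50.0
    stress_history: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_atoms < 1:
            raise ParameterError("n_atoms must be >= 1")
        if self.box_edge <= 0:
            raise ParameterError("box_edge must be > 0")
        if len(self.stress_history) == 0:
            raise ParameterError("stress_history must be non-empty")
        object.__setattr__(
            self,
            "stress_history",
            tuple(_as_voigt(s) for s in self.stress_history),
        )


def _as_voigt(stress) -> tuple:
    arr = np.asarray(stress, dtype=float)
    if arr.ndim == 0:
        return (float(arr),) * 3 + (0.0, 0.0, 0.0)
    if arr.shape == (6,):
        return tuple(arr)
    if arr.shape == (3, 3):
        if not np.allclose(arr, arr.T):
            raise ParameterError("stress tensor must be symmetric")
        return (arr[0, 0], arr[1, 1], arr[2, 2], arr[0, 1], arr[0, 2], arr[1, 2])
    raise ParameterError(f"cannot interpret stress of shape {arr.shape}")


def generate_relaxation_trace(spec: RelaxationGenSpec) -> RelaxationTrace:
    """Sample E(t) on the uniform grid 0, dt, ..., floor(duration/dt)*dt.

    The noiseless expectation at each sample equals the Prony model value;
    identical seeds give bit-identical traces.
    """
    n = int(np.floor(spec.duration / spec.dt)) + 1
    t = np.arange(n) * spec.dt
    modulus = spec.model.evaluate(t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        modulus = modulus + spec.noise_sd * rng.standard_normal(n)
    return RelaxationTrace(time=t, modulus=modulus, hold_strain=spec.hold_strain)


def tensile_mean_stress(spec: TensileGenSpec, strain) -> np.ndarray:
    """Noiseless piecewise-linear stress at the given strain values (GPa)."""
    strain = np.asarray(strain, dtype=float)
    b = spec.unfold_end_strain
    stress = np.where(
        strain <= b,
        spec.unfold_slope * strain,
        spec.unfold_slope * b + spec.stretch_slope * (strain - b),
    )
    return stress if stress.ndim else float(stress)


def generate_tensile_curve(spec: TensileGenSpec) -> StressStrainCurve:
    """Two-stage unfolding/stretching curve with additive fluctuation."""
    strain = np.linspace(0.0, spec.max_strain, spec.n_points)
    stress = tensile_mean_stress(spec, strain)
    if spec.fluctuation_sd > 0:
        rng = np.random.default_rng(spec.seed)
        stress = stress + spec.fluctuation_sd * rng.standard_normal(spec.n_points)
    return StressStrainCurve(
        strain=strain, stress=stress, strain_rate=spec.strain_rate, label=spec.label
    )


def generate_frames(spec: FrameGenSpec) -> list[AtomFrame]:
    """Toy frames whose extracted group stress equals the prescription.

    Atoms are placed uniformly in a cubic box (same positions every frame)
    and each frame's total stress*volume, -sigma/ATM_TO_GPA * sum(v_i), is
    partitioned across atoms with a random zero-sum perturbation, so the
    volume-weighted extraction recovers the prescribed tensor exactly (to
    rounding) using the same Voronoi volumes.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.array([[0.0, spec.box_edge]] * 3)
    # margin keeps the points well-separated for a stable tessellation
    coords = rng.uniform(0.05 * spec.box_edge, 0.95 * spec.box_edge, size=(spec.n_atoms, 3))
    ids = np.arange(1, spec.n_atoms + 1)
    template = AtomFrame(
        timestep=0,
        box_bounds=box,
        ids=ids,
        coords=coords,
        stress_pv=np.zeros((spec.n_atoms, 6)),
    )
    volumes = voronoi_volumes(template)  # positions are id-sorted already

    frames = []
    for step, target in enumerate(spec.stress_history):
        sigma_atm = np.asarray(target, dtype=float) / ATM_TO_GPA
        stress_pv = -np.outer(volumes, sigma_atm)  # exact volume-weighted split
        if spec.n_atoms > 1:
            scale = 0.1 * (abs(sigma_atm).max() + 1.0) * volumes.mean()
            noise = rng.normal(0.0, scale, size=(spec.n_atoms, 6))
            stress_pv = stress_pv + (noise - noise.mean(axis=0))  # zero-sum
        frames.append(
            AtomFrame(
                timestep=step,
                box_bounds=box,
                ids=ids,
                coords=coords,
                stress_pv=stress_pv,
            )
        )
    return frames
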