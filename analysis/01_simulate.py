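#!/usr/bin/env python
"""Generate the synthetic study inputs.

Stands in for the steered-MD output: noisy 1 ns relaxation traces at an
80% hold for the two fitted filament models (one per nominal pulling
rate), two-stage tensile curves at 1e8 and 1e9 /s, and a short toy
trajectory whose group stress follows a prescribed exponential decay.
Everything downstream (02-05) reads the files written here.
"""

from pathlib import Path

import numpy as np

from nfvisco import (
    FrameGenSpec,
    PronyModel,
    RelaxationGenSpec,
    TensileGenSpec,
    generate_frames,
    generate_relaxation_trace,
    generate_tensile_curve,
    write_dump,
)
from nfvisco.io import write_curve_csv, write_trace_csv

SEED = 20260930
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"

# fitted relaxation models of the sidearm at the two nominal pulling rates
MODELS = {
    "rate1e8": PronyModel(0.103, ((0.827, 87.866),)),
    "rate1e9": PronyModel(0.0, ((2.0, 100.0),)),
}
# stretch-stage slopes emulate the stiffer response at the higher rate;
# recorded strain ranges ~220% (low rate) and ~360% (high rate)
CURVES = {
    "rate1e8": TensileGenSpec(strain_rate=1e8, stretch_slope=0.3, max_strain=2.17,
                              fluctuation_sd=0.02, seed=SEED),
    "rate1e9": TensileGenSpec(strain_rate=1e9, stretch_slope=0.5, max_strain=3.6,
                              fluctuation_sd=0.02, seed=SEED + 1),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    for name, model in MODELS.items():
        spec = RelaxationGenSpec(model=model, duration=1000.0, dt=1.0,
                                 noise_sd=0.05, seed=SEED, hold_strain=0.8)
        trace = generate_relaxation_trace(spec)
        write_trace_csv(trace, OUT / f"relaxation_{name}.csv")
        print(f"relaxation_{name}.csv: {len(trace)} samples, "
              f"E(0) noiseless = {model.instantaneous:.3f} GPa")

    for name, spec in CURVES.items():
        curve = generate_tensile_curve(spec)
        write_curve_csv(curve, OUT / f"tensile_{name}.csv")
        print(f"tensile_{name}.csv: {len(curve)} points to strain "
              f"{spec.max_strain}, stretch slope {spec.stretch_slope} GPa")

    # toy trajectory: axial stress decays exponentially over 8 frames
    t = np.arange(8, dtype=float)
    sigma = 0.744 * np.exp(-t / 2.5)
    history = tuple(np.array([s, 0.0, 0.0, 0.0, 0.0, 0.0]) for s in sigma)
    frames = generate_frames(FrameGenSpec(n_atoms=24, box_edge=40.0,
                                          stress_history=history, seed=SEED))
    write_dump(frames, OUT / "frames.dump")
    print(f"frames.dump: {len(frames)} frames, 24 atoms, axial stress "
          f"{sigma[0]:.3f} -> {sigma[-1]:.3f} GPa")


if __name__ == "__main__":
    main()
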