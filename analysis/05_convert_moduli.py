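#!/usr/bin/env python
"""Convert the fitted relaxation models to shear and bulk moduli.

Applies the constant-Poisson's-ratio correspondence conversion to the fit
results from 04 at nu = 0.33 and 0.48, cross-checks the closed form
against numerical Laplace inversion, and writes the shear/bulk parameter
table plus a G(t)/K(t) figure.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import json

import matplotlib.pyplot as plt
import numpy as np

from nfvisco import (
    PronyModel,
    inverse_laplace_check,
    moduli_table,
    to_bulk,
    to_shear,
)
from nfvisco.io import dump_json

RESULTS = Path(__file__).resolve().parents[1] / "results"
POISSONS = (0.33, 0.48)


def main() -> None:
    models = {}
    for name in ("rate1e8", "rate1e9"):
        with open(RESULTS / f"fit_{name}.json") as fh:
            models[name] = PronyModel.from_dict(json.load(fh)["model"])

    table = moduli_table(models, POISSONS)
    table.to_csv(RESULTS / "moduli_table.csv")
    print(table.round(4).to_string())

    # independent cross-check: numerical inversion of the Laplace-domain
    # expressions vs the closed-form scaling
    t = np.geomspace(1.0, 1000.0, 13)
    worst = 0.0
    for model in models.values():
        for nu in POISSONS:
            g_num, k_num = inverse_laplace_check(model, nu, t)
            worst = max(
                worst,
                float(np.max(np.abs(g_num / to_shear(model, nu).evaluate(t) - 1))),
                float(np.max(np.abs(k_num / to_bulk(model, nu).evaluate(t) - 1))),
            )
    print(f"closed form vs numerical Laplace inversion: "
          f"max relative difference {worst:.2e}")
    dump_json(
        {"conversions": {f"nu={nu}": {name: {
            "shear": to_shear(m, nu).to_dict(), "bulk": to_bulk(m, nu).to_dict()}
            for name, m in models.items()} for nu in POISSONS},
         "laplace_inversion_max_rel_err": worst},
        RESULTS / "converted_moduli.json",
    )

    t_plot = np.linspace(0.0, 1000.0, 400)
    fig, axes = plt.subplots(2, 2, figsize=(8, 5.5), sharex=True)
    for j, (name, model) in enumerate(models.items()):
        for nu in POISSONS:
            axes[0, j].plot(t_plot, to_shear(model, nu).evaluate(t_plot),
                            label=f"nu={nu}")
            axes[1, j].plot(t_plot, to_bulk(model, nu).evaluate(t_plot),
                            label=f"nu={nu}")
        axes[0, j].set_title(name.replace("rate", "rate "))
        axes[0, j].set_ylabel("G(t) (GPa)")
        axes[1, j].set_ylabel("K(t) (GPa)")
        axes[1, j].set_xlabel("time (ps)")
        axes[0, j].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(RESULTS / "shear_bulk_moduli.png", dpi=150)
    print(f"figure written to {RESULTS / 'shear_bulk_moduli.png'}")


if __name__ == "__main__":
    main()
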