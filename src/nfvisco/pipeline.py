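"""End-to-end orchestration: simulate/load -> extract -> fit -> convert -> report.

A run is a pure function of (inputs, config): every artifact embeds the
seed and a hash of the config, and re-running with the same config gives
byte-identical JSON.  Stages log one line each (row counts in/out) to
stderr and to ``run.log`` in the output directory; a stage failure aborts
with the stage name while keeping whatever artifacts were already written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import correspondence, relaxation, synthetic, tensile
from .exceptions import NFViscoError, ParameterError
from .io import (
    dump_json,
    read_curve_csv,
    read_trace_csv,
    write_curve_csv,
    write_trace_csv,
)
from .models import PronyModel

logger = logging.getLogger("nfvisco")


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration.

    ``mode`` is "relaxation" or "tensile".  Relaxation mode requires
    ``hold_strain``; tensile mode requires at least one curve source
    (synthetic spec or input CSV).  ``raw`` keeps the full config mapping
    for hashing and for generator parameters.
    """

    mode: str
    seed: int
    output_dir: Path
    hold_strain: float | None = None
    poisson_list: tuple[float, ...] = correspondence.DEFAULT_POISSONS
    n_branches: int = 1
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict, output_dir) -> "RunConfig":
        mode = data.get("mode")
        if mode not in ("relaxation", "tensile"):
            raise ParameterError(f"mode must be 'relaxation' or 'tensile', got {mode!r}")
        hold_strain = data.get("hold_strain")
        if mode == "relaxation":
            if hold_strain is None:
                raise ParameterError("relaxation mode requires hold_strain")
            if hold_strain <= 0:
                raise ParameterError("hold_strain must be > 0")
            if not (data.get("synthetic") or data.get("trace_csv")):
                raise ParameterError(
                    "relaxation mode requires a 'synthetic' spec or 'trace_csv'"
                )
        else:
            if not (data.get("curves") or data.get("curve_csvs")):
                raise ParameterError(
                    "tensile mode requires 'curves' specs or 'curve_csvs'"
                )
        return cls(
            mode=mode,
            seed=int(data.get("seed", 0)),
            output_dir=Path(output_dir),
            hold_strain=hold_strain,
            poisson_list=tuple(data.get("poisson_list", correspondence.DEFAULT_POISSONS)),
            n_branches=int(data.get("n_branches", 1)),
            raw=dict(data),
        )

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"seed": self.seed, "config_hash": self.config_hash}


def _setup_logging(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    logger.setLevel(logging.INFO)
    logger.handlers = [
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "run.log", mode="a"),
    ]
    for h in logger.handlers:
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))


class _Stage:
    """Context manager that names the failing stage and preserves outputs."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            logger.error("stage %s failed: %s", self.name, exc)
            raise NFViscoError(
                f"pipeline aborted in stage '{self.name}': {exc} "
                "(partial outputs preserved)"
            ) from exc
        return False


def _model_from_config(spec: dict) -> PronyModel:
    return PronyModel(
        float(spec.get("long_term", 0.0)),
        tuple((float(e), float(tau)) for e, tau in spec.get("branches", [])),
    )


def run_relaxation_pipeline(config: RunConfig) -> dict:
    """Trace -> Prony fit -> shear/bulk conversion -> report bundle.

    Returns a dict of artifact paths; outputs land in ``config.output_dir``.
    """
    outdir = config.output_dir
    _setup_logging(outdir)
    artifacts: dict[str, Path] = {}

    with _Stage("simulate/load"):
        syn = config.raw.get("synthetic")
        if syn is not None:
            spec = synthetic.RelaxationGenSpec(
                model=_model_from_config(syn.get("model", {})),
                duration=float(syn.get("duration", 1000.0)),
                dt=float(syn.get("dt", 1.0)),
                noise_sd=float(syn.get("noise_sd", 0.05)),
                seed=config.seed,
                hold_strain=config.hold_strain,
            )
            trace = synthetic.generate_relaxation_trace(spec)
        else:
            trace = read_trace_csv(config.raw["trace_csv"])
        path = outdir / "relaxation_trace.csv"
        write_trace_csv(trace, path)
        artifacts["trace"] = path
        logger.info("simulate/load: %d trace samples out", len(trace))

    with _Stage("relax-fit"):
        fit = relaxation.fit_prony(
            trace,
            n_branches=config.n_branches,
            seed=config.seed,
            threshold_frac=float(config.raw.get("threshold_frac", 0.01)),
        )
        path = outdir / "fit.json"
        dump_json({**fit.to_dict(), **config.provenance()}, path)
        artifacts["fit"] = path
        logger.info(
            "relax-fit: %d samples in, %s with objective %.3e",
            len(trace), fit.selected_form, fit.objective,
        )

    with _Stage("convert"):
        converted = {}
        for nu in config.poisson_list:
            conv = correspondence.convert(fit.model, nu)
            converted[f"nu={nu}"] = conv.to_dict()
        path = outdir / "converted_moduli.json"
        dump_json({"conversions": converted, **config.provenance()}, path)
        artifacts["converted"] = path
        table = correspondence.moduli_table(
            {"fitted": fit.model}, config.poisson_list
        )
        table_path = outdir / "moduli_table.csv"
        table.to_csv(table_path)
        artifacts["table"] = table_path
        logger.info("convert: %d Poisson ratios out", len(config.poisson_list))

    with _Stage("report"):
        path = outdir / "report.txt"
        with open(path, "w") as fh:
            fh.write("relaxation pipeline report\n")
            fh.write(f"seed: {config.seed}  config: {config.config_hash}\n")
            fh.write(f"samples: {len(trace)}  hold strain: {trace.hold_strain}\n")
            fh.write(f"selected form: {fit.selected_form}\n")
            fh.write(f"model: {fit.model.to_dict()}\n")
            fh.write(f"objective (L2, GPa): {fit.objective:.6e}\n\n")
            fh.write(table.to_string() + "\n")
        artifacts["report"] = path
        logger.info("report: written to %s", path)
    return {k: str(v) for k, v in artifacts.items()}


def run_tensile_pipeline(config: RunConfig) -> dict:
    """Curves -> per-rate stiffness table with rate-ordering flag."""
    outdir = config.output_dir
    _setup_logging(outdir)
    artifacts: dict[str, Path] = {}

    with _Stage("simulate/load"):
        curves = []
        for i, spec in enumerate(config.raw.get("curves", [])):
            gen = synthetic.TensileGenSpec(
                strain_rate=float(spec["strain_rate"]),
                max_strain=float(spec.get("max_strain", 2.2)),
                unfold_end_strain=float(spec.get("unfold_end_strain", 1.5)),
                unfold_slope=float(spec.get("unfold_slope", 0.05)),
                stretch_slope=float(spec.get("stretch_slope", 0.5)),
                fluctuation_sd=float(spec.get("fluctuation_sd", 0.02)),
                n_points=int(spec.get("n_points", 500)),
                seed=config.seed + i,
                label=spec.get("label", f"synthetic-{i}"),
            )
            curves.append(synthetic.generate_tensile_curve(gen))
        for path in config.raw.get("curve_csvs", []):
            curves.append(read_curve_csv(path))
        for i, curve in enumerate(curves):
            path = outdir / f"curve_{i}.csv"
            write_curve_csv(curve, path)
            artifacts[f"curve_{i}"] = path
        logger.info("simulate/load: %d curves out", len(curves))

    with _Stage("stiffness"):
        window = config.raw.get("window")
        window = tuple(window) if window else None
        if len(curves) == 1:
            est = tensile.stiffness(
                curves[0], window or (curves[0].strain[0], curves[0].strain[-1])
            )
            summary = {
                "rows": [
                    {
                        "label": curves[0].label,
                        "strain_rate_per_s": curves[0].strain_rate,
                        "slope_GPa": est.slope,
                    }
                ],
                "rate_ordering": "not tested (single curve)",
            }
            table_str = str(est)
        else:
            comparison = tensile.compare_rates(curves, window)
            path = outdir / "stiffness_table.csv"
            comparison.table.to_csv(path, index=False)
            artifacts["stiffness_table"] = path
            summary = {
                "rows": comparison.table.to_dict(orient="records"),
                "rate_ordering": "consistent" if comparison.monotone else "violated",
                "violations": list(comparison.violations),
                "ties": list(comparison.ties),
            }
            table_str = comparison.table.to_string(index=False)
        path = outdir / "stiffness.json"
        dump_json({**summary, **config.provenance()}, path)
        artifacts["stiffness"] = path
        logger.info("stiffness: %d curves in, ordering %s",
                    len(curves), summary["rate_ordering"])

    with _Stage("report"):
        path = outdir / "report.txt"
        with open(path, "w") as fh:
            fh.write("tensile pipeline report\n")
            fh.write(f"seed: {config.seed}  config: {config.config_hash}\n")
            fh.write(f"rate ordering: {summary['rate_ordering']}\n\n")
            fh.write(table_str + "\n")
        artifacts["report"] = path
        logger.info("report: written to %s", path)
    return {k: str(v) for k, v in artifacts.items()}


def run(config: RunConfig) -> dict:
    if config.mode == "relaxation":
        return run_relaxation_pipeline(config)
    return run_tensile_pipeline(config)
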