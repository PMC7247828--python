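"""Experiment plumbing: presets, configuration, artifacts, and the CLI.

Each experiment ties the library modules into one reproducible pipeline
run: simulate, featurize, embed, learn, and write CSV/JSON artifacts plus
a summary and a manifest (config + seeds + library versions) into the
output directory.
"""

from __future__ import annotations

import json
import logging
import platform
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coarse_id import build_density_dataset, check_one_to_one, discover_coarse_variable
from .manifold import KernelConfig
from .oscillator_models import (
    OscillatorEnsemble,
    order_parameter_series,
    sample_cauchy_frequencies,
    simulate,
    to_rotating_frame,
)
from .rhs_learning import (
    RK4NetConfig,
    generate_flow_pairs,
    learn_phi_dynamics,
    ott_antonsen_rhs,
    train_rhs_net,
)
from .effective_params import output_only_effective_param, steady_state_dataset

logger = logging.getLogger("emergent")

EXPERIMENTS = ("coarse-id", "flow-pairs", "learn-rhs", "learn-phi", "effective-params")

#: Reference parameter presets for the reproduction runs.
PRESETS: dict[str, dict] = {
    "paper_4_2": {
        "experiment": "coarse-id",
        "n_oscillators": 8000,
        "coupling": 2.0,
        "gamma": 0.5,
        "tail_cap": 2.5e-4,
        "n_bins": 200,
        "snapshots_per_trajectory": 400,
    },
    "paper_5": {
        "experiment": "learn-rhs",
        "n_pairs": 2000,
        "n_oscillators": 8000,
        "coupling": 2.0,
        "gamma": 0.5,
        "dt": 0.01,
        "epochs": 60000,
        "lr_schedule": "cosine",
    },
    "paper_6_1": {"experiment": "effective-params", "variant": "hetero_k"},
    "paper_6_2": {"experiment": "effective-params", "variant": "firing"},
    "paper_6_3": {"experiment": "effective-params", "variant": "chung_lu"},
}

#: Overrides applied by ``--scale test`` (smaller ensembles, same science).
TEST_SCALE = {
    "coarse-id": {"n_oscillators": 4000, "snapshots_per_trajectory": 200},
    "flow-pairs": {"n_pairs": 500, "n_oscillators": 2000},
    "learn-rhs": {"n_pairs": 500, "n_oscillators": 2000, "epochs": 20000},
    "learn-phi": {"n_pairs": 300, "n_oscillators": 2000, "epochs": 20000, "r_hi": 0.97},
    "effective-params": {"n_oscillators": 800},
}


@dataclass
class ExperimentConfig:
    """One experiment run: tag, model variant, numeric parameters, seed,
    output directory. Unspecified parameters take the preset defaults."""

    experiment: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: Path = Path("runs")
    scale: str = "paper"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        if self.scale not in ("paper", "test"):
            raise ValueError("scale must be 'paper' or 'test'")
        self.out_dir = Path(self.out_dir)
        if self.scale == "test":
            merged = dict(TEST_SCALE.get(self.experiment, {}))
            merged.update(self.params)
            self.params = merged


def _write_manifest(cfg: ExperimentConfig, out: Path) -> None:
    import scipy

    manifest = {
        "experiment": cfg.experiment,
        "params": cfg.params,
        "seed": cfg.seed,
        "scale": cfg.scale,
        "versions": {
            "emergent": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _coarse_id_trajectories(p: dict):
    """The two reference trajectories: one started fully synchronized
    (all phases pi), one started incoherent (equally spaced phases).

    Per-branch snapshot windows span each branch's actual R excursion
    (the synchronized start relaxes within a few time units, the
    structured incoherent start grows slowly), avoiding oversampling of
    the steady-state plateau.
    """
    n = p.get("n_oscillators", 8000)
    omega = sample_cauchy_frequencies(
        p.get("gamma", 0.5), n, p.get("tail_cap", 2.5e-4)
    )
    ensemble = OscillatorEnsemble(
        phases=np.zeros(n), frequencies=omega, coupling=p.get("coupling", 2.0)
    )
    n_snap = p.get("snapshots_per_trajectory", 400)
    runs = (
        (np.full(n, np.pi), np.linspace(p.get("t_high_start", 0.5), p.get("t_high_end", 4.0), n_snap)),
        (
            np.linspace(0.0, 2.0 * np.pi, n, endpoint=False),
            np.linspace(p.get("t_low_start", 4.0), p.get("t_low_end", 20.0), n_snap),
        ),
    )
    return [to_rotating_frame(simulate(ensemble, s, t)) for s, t in runs]


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute one experiment and write its artifact bundle.

    Returns the summary dictionary that is also persisted as
    ``summary.json``. Deterministic for a fixed config + seed.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    p = cfg.params
    summary: dict = {"experiment": cfg.experiment, "seed": cfg.seed}
    logger.info("running %s (scale=%s, seed=%d)", cfg.experiment, cfg.scale, cfg.seed)

    if cfg.experiment == "coarse-id":
        trajs = _coarse_id_trajectories(p)
        dataset = build_density_dataset(trajs, n_bins=p.get("n_bins", 200))
        result = discover_coarse_variable(
            dataset, KernelConfig(epsilon=p.get("epsilon"))
        )
        report = check_one_to_one(result.phi(1), dataset.R)
        pd.DataFrame(
            {
                "time": dataset.provenance["time"],
                "trajectory": dataset.provenance["trajectory"],
                "R": dataset.R,
                "phi1": result.phi(1),
            }
        ).to_csv(out / "coarse_variable.csv", index=False)
        summary.update(
            significant_count=len(result.significant),
            significant=result.significant,
            residuals=np.round(result.residuals, 4).tolist(),
            spearman_phi1_vs_R=report["spearman"],
            kernel_epsilon=result.epsilon,
        )

    elif cfg.experiment in ("flow-pairs", "learn-rhs", "learn-phi"):
        pairs = generate_flow_pairs(
            n_pairs=p.get("n_pairs", 2000),
            dt=p.get("dt", 0.01),
            n_oscillators=p.get("n_oscillators", 8000),
            coupling=p.get("coupling", 2.0),
            gamma=p.get("gamma", 0.5),
            seed=cfg.seed,
            retain_phases=cfg.experiment == "learn-phi",
            r_hi=p.get("r_hi", 1.0),
        )
        pd.DataFrame(
            {
                "t_value": pairs.y_start,
                "t_plus_dt_value": pairs.y_end,
                "dt": pairs.dt,
                "branch": pairs.branch,
                "seed": cfg.seed,
            }
        ).to_csv(out / "flow_pairs.csv", index=False)
        summary.update(n_pairs=len(pairs), dt=pairs.dt)

        if cfg.experiment == "learn-rhs":
            model = train_rhs_net(
                pairs,
                RK4NetConfig(
                    epochs=p.get("epochs", 10000),
                    lr_schedule=p.get("lr_schedule", "constant"),
                    seed=cfg.seed,
                ),
            )
            grid = np.linspace(0.0, 1.0, 501)
            err = model.rhs(grid) - ott_antonsen_rhs(
                grid, p.get("coupling", 2.0), p.get("gamma", 0.5)
            )
            (out / "model.json").write_text(model.to_json())
            summary.update(
                final_train_loss=float(model.train_loss[-1]),
                max_rhs_error_vs_oracle=float(np.max(np.abs(err))),
            )
        elif cfg.experiment == "learn-phi":
            result = learn_phi_dynamics(
                pairs,
                net_config=RK4NetConfig(epochs=p.get("epochs", 50000), seed=cfg.seed),
            )
            (out / "model.json").write_text(result.model.to_json())
            summary.update(
                significant_count=len(result.embedding.significant),
                final_train_loss=float(result.model.train_loss[-1]),
                **result.diagnostics,
            )

    elif cfg.experiment == "effective-params":
        variant = p.get("variant", "hetero_k")
        dataset = steady_state_dataset(
            variant, n_oscillators=p.get("n_oscillators"), seed=cfg.seed
        )
        result = output_only_effective_param(dataset, epsilon=p.get("epsilon"))
        dataset.heterogeneities.assign(theta_inf=dataset.phases).to_csv(
            out / "effective_parameter.csv", index=False
        )
        summary.update(
            variant=variant,
            significant_count=len(result.significant),
            significant=result.significant,
            residuals=np.round(result.residuals, 4).tolist(),
            coherence=dataset.coherence,
            sync_time=dataset.sync_time,
        )

    # Runtime is logged, not persisted in the summary: identical config +
    # seed must produce a byte-identical summary.json.
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _write_manifest(cfg, out)
    logger.info(
        "finished %s in %.1fs", cfg.experiment, time.perf_counter() - t_start
    )
    return summary


# ---------------------------------------------------------------------------
# Command-line interface
# ---------------------------------------------------------------------------

def _load_config(config_file: str | None, preset: str | None) -> dict:
    params: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise click.UsageError(f"unknown preset {preset!r}")
        params.update(PRESETS[preset])
    if config_file is not None:
        with open(config_file) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise click.UsageError("config file must be a flat key/value mapping")
        params.update(loaded)
    return params


def _common_options(fn):
    fn = click.option("--config", "config_file", type=click.Path(exists=True), default=None)(fn)
    fn = click.option("--preset", default=None, help="named parameter preset")(fn)
    fn = click.option("--seed", type=int, default=0, show_default=True)(fn)
    fn = click.option("--out", "out_dir", type=click.Path(), default="runs")(fn)
    fn = click.option(
        "--scale", type=click.Choice(["paper", "test"]), default="paper", show_default=True
    )(fn)
    return fn


@click.group()
@click.version_option(__version__)
def main() -> None:
    """Data-driven coarse graining of coupled oscillator networks."""
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO, format="%(asctime)s %(name)s %(message)s"
    )


def _make_command(tag: str):
    @main.command(name=tag)
    @_common_options
    def _cmd(config_file, preset, seed, out_dir, scale, _tag=tag):
        params = _load_config(config_file, preset)
        params.pop("experiment", None)
        cfg = ExperimentConfig(
            experiment=_tag, params=params, seed=seed, out_dir=Path(out_dir), scale=scale
        )
        summary = run_experiment(cfg)
        click.echo(json.dumps(summary, indent=2, sort_keys=True))

    return _cmd


for _tag in EXPERIMENTS:
    _make_command(_tag)


@main.command(name="simulate")
@_common_options
@click.option(
    "--model",
    type=click.Choice(["all2all", "heteroK", "firing", "network"]),
    default="all2all",
    show_default=True,
)
def simulate_cmd(config_file, preset, seed, out_dir, scale, model) -> None:
    """Simulate one ensemble and persist its order-parameter series."""
    params = _load_config(config_file, preset)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n = params.get("n_oscillators", 2000 if scale == "test" else 8000)
    if model == "all2all":
        omega = sample_cauchy_frequencies(params.get("gamma", 0.5), n)
        ensemble = OscillatorEnsemble(
            phases=np.zeros(n), frequencies=omega, coupling=params.get("coupling", 2.0)
        )
        theta0 = rng.uniform(0.0, 2.0 * np.pi, n)
        t_grid = np.linspace(0.0, params.get("t_final", 15.0), 400)
        traj = simulate(ensemble, theta0, t_grid)
        series = order_parameter_series(traj)
        pd.DataFrame({"time": traj.times, "R": series.R, "psi": series.psi}).to_csv(
            out / "order_parameter.csv", index=False
        )
        click.echo(f"wrote {out / 'order_parameter.csv'}")
    else:
        variant = {"heteroK": "hetero_k", "firing": "firing", "network": "chung_lu"}[model]
        dataset = steady_state_dataset(
            variant, n_oscillators=params.get("n_oscillators"), seed=seed
        )
        dataset.heterogeneities.assign(theta_inf=dataset.phases).to_csv(
            out / "steady_state.csv", index=False
        )
        click.echo(f"wrote {out / 'steady_state.csv'}")


if __name__ == "__main__":
    main()
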