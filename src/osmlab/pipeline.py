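"""End-to-end experiment orchestration.

One experiment = generate a task session, train one or more models on
it, extract near/far population vectors at checkpoints, and compare the
resulting cross-correlation structure (final region correlations,
decorrelation trajectories, time-to-threshold order).  Configured from a
dict or YAML file; writes a machine-readable JSON summary plus CSV/PNG
artifacts per model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import repr_analysis as ra
from . import tasks
from .cscg import CSCG
from .hebbian import HebbianRNN, SpikingNetParams
from . import nets


class PipelineError(RuntimeError):
    pass


KEY_REGIONS = ("off_diagonal", "pre_r2", "pre_r1")


@dataclass
class ModelRun:
    """Outcome of one model on one seed."""

    family: str
    seed: int
    final_matrix: np.ndarray
    final_regions: dict
    trajectory: ra.DecorrTrajectory | None
    order: dict | None
    extras: dict = field(default_factory=dict)

    @property
    def pre_reward_mean(self) -> float:
        m = self.final_regions["region_means"]
        return 0.5 * (m["pre_r1"] + m["pre_r2"])


def run_cscg(seed: int = 0, dialect: str = "cscg_visual_first",
             clones_per_symbol: int = 100, n_steps: int = 20,
             n_em_iters: int = 20, batch_trials: int = 20,
             n_trials: int = 200, viterbi_refine: bool = True) -> ModelRun:
    """Train a CSCG on the task and analyse its occupancy PVs."""
    schedule = tasks.sample_session(n_trials, dialect=dialect, seed=seed)
    near = tasks.make_trial("near", dialect)
    far = tasks.make_trial("far", dialect)
    model = CSCG(tasks.alphabet(dialect), clones_per_symbol, seed=seed)
    res = model.fit(schedule, n_steps=n_steps, n_em_iters=n_em_iters,
                    batch_trials=batch_trials, checkpoint_cadence="iteration",
                    probe_trials=[near, far])
    if viterbi_refine:
        model.viterbi_refine([near, far])
    regions = ra.RegionSpec.for_model(dialect)
    pairs = [(a, b) for a, b in res.checkpoint_pvs]
    traj = ra.decorrelation_trajectory(pairs, regions)
    order = ra.decorrelation_order(traj)
    pv_n, pv_f = pairs[-1]
    mat = ra.pv_cross_correlation(pv_n, pv_f)
    return ModelRun("cscg", seed, mat.matrix,
                    ra.region_correlations(mat, regions), traj, order,
                    extras={"loglik_final": float(res.loglik_curve[-1, -1]),
                            "dialect": dialect})


def run_hebbian(seed: int = 0, n_trials: int = 300,
                params: SpikingNetParams | None = None,
                checkpoint_every: int = 50, probe_reps: int = 5) -> ModelRun:
    """Train the spiking Hebbian network by passive exposure."""
    dialect = "cscg_visual_first"
    schedule = tasks.sample_session(n_trials, dialect=dialect, seed=seed)
    net = HebbianRNN(8, params, seed=seed)
    res = net.fit(schedule, checkpoint_every=checkpoint_every,
                  probe_reps=probe_reps)
    regions = ra.RegionSpec.for_model(dialect)
    traj = ra.decorrelation_trajectory(res.checkpoint_pvs, regions)
    order = ra.decorrelation_order(traj)
    pv_n, pv_f = res.checkpoint_pvs[-1]
    mat = ra.pv_cross_correlation(pv_n, pv_f)
    return ModelRun("hebbian", seed, mat.matrix,
                    ra.region_correlations(mat, regions), traj, order)


def run_gradient_net(family: str, seed: int = 0, **kwargs) -> ModelRun:
    """Train a rate RNN / LSTM / transformer and analyse hidden PVs."""
    spec = {"family": family, "seed": seed}
    for key in ("hidden", "activation", "regularizer", "lam",
                "n_layers", "n_heads", "embed", "context_length"):
        if key in kwargs:
            spec[key] = kwargs.pop(key)
    res = nets.train(spec, **kwargs)
    model = res.model
    regions = ra.RegionSpec.for_model("rnn")
    traj = order = None
    if res.checkpoint_pvs:
        traj = ra.decorrelation_trajectory(res.checkpoint_pvs, regions)
        order = ra.decorrelation_order(traj)
    pv_n, pv_f = model.pv_pair()
    mat = ra.pv_cross_correlation(pv_n, pv_f)
    acc = model.next_symbol_accuracy(res.test_trials) if res.test_trials else np.nan
    return ModelRun(family, seed, mat.matrix,
                    ra.region_correlations(mat, regions), traj, order,
                    extras={"test_accuracy": acc,
                            "final_loss": float(res.loss_curve[-1])})


_RUNNERS = {"cscg": run_cscg, "hebbian": run_hebbian,
            "rate_rnn": lambda **kw: run_gradient_net("rate_rnn", **kw),
            "lstm": lambda **kw: run_gradient_net("lstm", **kw),
            "transformer": lambda **kw: run_gradient_net("transformer", **kw)}


def run_experiment(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run every model listed in ``config`` and assemble a report bundle.

    ``config`` has the form::

        {"models": [{"family": "cscg", "seeds": [0, 1], ...params}, ...],
         "name": "experiment"}

    Returns the summary dict; with ``out_dir`` also writes summary.json,
    per-model correlation matrices (CSV) and heatmaps (PNG).  A failing
    stage is recorded in the error manifest rather than aborting the
    bundle, and the summary marks the bundle as partial.
    """
    models = config.get("models")
    if not models:
        raise PipelineError("config lists no models")
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]
    summary = {"name": config.get("name", "experiment"),
               "config_hash": cfg_hash, "models": [], "errors": []}
    for entry in models:
        entry = dict(entry)
        family = entry.pop("family")
        seeds = entry.pop("seeds", [entry.pop("seed", 0)])
        if family not in _RUNNERS:
            summary["errors"].append({"family": family, "error": "unknown family"})
            continue
        runs = []
        for seed in seeds:
            try:
                run = _RUNNERS[family](seed=seed, **entry)
            except Exception as exc:      # noqa: BLE001 - manifest, not crash
                summary["errors"].append({"family": family, "seed": seed,
                                          "error": repr(exc)})
                continue
            runs.append(run)
            if out:
                stem = out / f"{family}_seed{seed}"
                np.savetxt(f"{stem}_matrix.csv", run.final_matrix, delimiter=",")
                _save_heatmap(run.final_matrix, f"{stem}_matrix.png",
                              f"{family} seed {seed}")
        if runs:
            summary["models"].append(_summarize_family(family, runs, entry))
    summary["partial"] = bool(summary["errors"])
    if out:
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


def _summarize_family(family: str, runs: list[ModelRun], params: dict) -> dict:
    pre = [r.pre_reward_mean for r in runs]
    orders = [r.order for r in runs if r.order is not None]
    return {
        "family": family, "params": params,
        "seeds": [r.seed for r in runs],
        "pre_reward_corr_mean": float(np.mean(pre)),
        "pre_reward_corr_per_seed": [float(v) for v in pre],
        "order_match_fraction": (float(np.mean([o["match"] for o in orders]))
                                 if orders else None),
        "final_regions": {k: float(np.mean([r.final_regions["region_means"][k]
                                            for r in runs]))
                          for k in next(iter(runs)).final_regions["region_means"]},
        "off_diagonal": float(np.mean([r.final_regions["off_diagonal"]
                                       for r in runs])),
        "extras": [r.extras for r in runs],
    }


def _save_heatmap(matrix: np.ndarray, path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(matrix, vmin=-1, vmax=1, cmap="RdBu_r", origin="lower")
    ax.set_xlabel("far position")
    ax.set_ylabel("near position")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def load_config(path: str | Path) -> dict:
    import yaml
    with open(path) as fh:
        return yaml.safe_load(fh)
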