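"""Five-stage pipeline orchestration and statistics.

The pipeline per cell (alpha x activation x realization) is: generate the
task dataset, scale the connectome to the requested spectral radius, simulate
the echo-state reservoir, split trials, fit the linear readout, and score.
All randomness derives from a single master seed through stable child seeds,
so adding realizations never changes earlier ones.

On top of `run_experiment` this module provides nonparametric comparison
against degree-preserving rewired nulls (`null_comparison`), per-module
readout stratification with one-way ANOVA (`stratified_readout`), and tidy
reporting (`report`).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import metrics as _metrics
from . import readout as _readout
from . import tasks as _tasks
from .connectome import Connectome, rewire_null, scale_to_alpha, select_nodes
from .errors import NeurorcError, ParameterError
from .esn import EchoStateReservoir, build_input_map, retrieve_states, simulate_esn

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.05, 2.0001, 0.05), 2).tolist())


class PipelineError(NeurorcError, RuntimeError):
    """A stage failed; message carries the stage name and cell coordinates."""


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment (JSON-compatible plus a connectome)."""

    connectome: Connectome
    task: str = "memory_capacity"
    input_nodes: Sequence[int] | Sequence[str] | int | None = None
    readout_nodes: Sequence[int] | Sequence[str] | None = None
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID
    activations: Sequence[str] = ("tanh",)
    n_realizations: int = 50
    seed: int = 0
    # task parameters
    n_trials: int = 1000
    noise_sd: float = 0.2
    coherences: Sequence[float] = _tasks.DEFAULT_COHERENCES
    epoch_lengths: Sequence[int] = _tasks.DEFAULT_EPOCHS
    T: int = 2000
    max_lag: int = 20
    washout: int = 100
    frac_train: float = 0.7
    # model parameters
    regularization: float = 1.0
    # random (seeded) input weights: signed per-channel weights keep multi-channel
    # contrasts (e.g. x2 - x3) visible to the reservoir, which a uniform
    # broadcast would cancel
    input_map_mode: str = "random"
    input_gain: float = 1.0


@dataclass
class PerformanceCurve:
    """Tidy per-cell scores plus per-(alpha, activation, metric) summary."""

    rows: pd.DataFrame      # alpha, activation, metric, realization, value
    summary: pd.DataFrame   # alpha, activation, metric, mean, ci_low, ci_high, n
    meta: dict = field(default_factory=dict)


@dataclass
class NullComparison:
    empirical_value: float
    null_values: np.ndarray
    p_value: float
    alpha_at: float | None
    alternative: str
    statistic: str
    metric: str


@dataclass
class StratifiedResult:
    table: pd.DataFrame     # alpha, module, realization, metric, value
    anova: dict             # F, p, dfs, mean squares, alpha evaluated at
    modules: dict           # label -> node indices


def child_seed(master: int, *key: int) -> int:
    """Stable child seed derived from a master seed and an integer key path."""
    ss = np.random.SeedSequence([int(master), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _resolve_nodes(config: ExperimentConfig) -> tuple[np.ndarray, np.ndarray]:
    c = config.connectome
    n = c.n_nodes
    rng = np.random.default_rng(child_seed(config.seed, 7))

    def resolve(selector, exclude=None):
        if selector is None:
            return None
        if isinstance(selector, (int, np.integer)):
            pool = np.arange(n) if exclude is None else np.setdiff1d(np.arange(n), exclude)
            return np.sort(rng.choice(pool, size=int(selector), replace=False))
        selector = list(selector)
        if selector and isinstance(selector[0], str):
            return np.asarray(select_nodes(c, selector), dtype=int)
        return np.asarray(selector, dtype=int)

    inp = resolve(config.input_nodes)
    if inp is None:
        k = max(1, n // 10)
        inp = np.sort(rng.choice(n, size=k, replace=False))
    out = resolve(config.readout_nodes, exclude=inp)
    if out is None:
        out = np.setdiff1d(np.arange(n), inp)
    if out.size == 0:
        raise ParameterError("readout node set is empty")
    return inp, out


def _make_dataset(config: ExperimentConfig, realization: int) -> _tasks.TaskDataset:
    seed = child_seed(config.seed, 10, realization)
    if config.task == "memory_capacity":
        return _tasks.make_memory_capacity(
            config.T, max_lag=config.max_lag, washout=config.washout, seed=seed
        )
    common = dict(
        n_trials=config.n_trials, coherences=config.coherences,
        epoch_lengths=config.epoch_lengths, noise_sd=config.noise_sd, seed=seed,
    )
    if config.task == "perceptual_dm":
        return _tasks.make_perceptual_dm(**common)
    if config.task == "context_dm":
        return _tasks.make_context_dm(**common)
    raise ParameterError(f"unknown task {config.task!r}")


def _score_cell(
    config: ExperimentConfig,
    ds: _tasks.TaskDataset,
    states: np.ndarray,
    readout_idx: np.ndarray,
    realization: int,
) -> dict[str, float]:
    split_seed = child_seed(config.seed, 11, realization)
    train_idx, test_idx = _tasks.split_trials(ds, config.frac_train, seed=split_seed)
    feats = states[:, readout_idx]
    if ds.is_classification:
        train_mask = ds.trial_time_mask(train_idx) & ds.decision_mask
        test_mask = ds.trial_time_mask(test_idx) & ds.decision_mask
        model = _readout.fit_readout(
            feats[train_mask], ds.targets[train_mask],
            mode="classification", regularization=config.regularization,
        )
        pred, _ = _readout.predict(model, feats[test_mask])
        y_test = ds.targets[test_mask]
        out = {
            "balanced_accuracy": _metrics.balanced_accuracy(y_test, pred).value,
            "f1": _metrics.f1(y_test, pred, average="binary").value,
        }
        # trial-level: majority vote over each test trial's decision timesteps
        test_rows = np.nonzero(test_mask)[0]
        pos = {row: i for i, row in enumerate(test_rows)}
        groups = []
        for t in test_idx:
            s, e = ds.trial_bounds[t]
            groups.append([pos[r] for r in range(s, e) if test_mask[r]])
        trial_pred = _readout.majority_vote(pred, groups)
        trial_true = ds.trial_labels()[test_idx]
        out["balanced_accuracy_trial"] = _metrics.balanced_accuracy(trial_true, trial_pred).value
        out["f1_trial"] = _metrics.f1(trial_true, trial_pred, average="binary").value
        return out
    # regression / memory capacity: contiguous time split
    in_train = np.zeros(ds.n_timesteps, dtype=bool)
    in_train[train_idx] = True
    in_test = np.zeros(ds.n_timesteps, dtype=bool)
    in_test[test_idx] = True
    train_mask = in_train & ds.decision_mask
    test_mask = in_test & ds.decision_mask
    model = _readout.fit_readout(
        feats[train_mask], ds.targets[train_mask],
        mode="regression", regularization=config.regularization,
    )
    pred, _ = _readout.predict(model, feats[test_mask])
    mc = _metrics.memory_capacity(ds.targets[test_mask], pred)
    return {
        "memory_capacity": mc.value,
        "mean_lag_corr_sq": mc.extras["mean_lag_corr_sq"],
    }


def run_experiment(config: ExperimentConfig) -> PerformanceCurve:
    """Run the full alpha x activation x realization sweep for one connectome."""
    input_idx, readout_idx = _resolve_nodes(config)
    rows: list[dict] = []
    dataset_cache: dict[int, _tasks.TaskDataset] = {}
    n_channels = {"memory_capacity": 1, "perceptual_dm": 3, "context_dm": 7}[config.task]
    input_map = build_input_map(
        n_channels, config.connectome.n_nodes, input_idx,
        mode=config.input_map_mode, seed=child_seed(config.seed, 12),
    )
    for act in config.activations:
        for alpha in config.alphas:
            scaled = scale_to_alpha(config.connectome, float(alpha))
            reservoir = EchoStateReservoir(
                weights=scaled.weights, input_map=input_map, activation=act,
                input_gain=config.input_gain, input_nodes=input_idx,
            )
            for r in range(config.n_realizations):
                t0 = time.perf_counter()
                stage = "fetch task dataset"
                try:
                    if r not in dataset_cache:
                        dataset_cache[r] = _make_dataset(config, r)
                    ds = dataset_cache[r]
                    stage = "simulate reservoir dynamics"
                    trace = simulate_esn(reservoir, ds.inputs, alpha=float(alpha))
                    stage = "learning/assess performance"
                    scores = _score_cell(config, ds, trace.states, readout_idx, r)
                except NeurorcError as exc:
                    raise PipelineError(
                        f"stage '{stage}' failed at alpha={alpha}, activation={act}, "
                        f"realization={r}: {exc}"
                    ) from exc
                for name, value in scores.items():
                    rows.append({
                        "alpha": float(alpha), "activation": act, "metric": name,
                        "realization": r, "value": float(value),
                    })
                logger.info(
                    "cell done: alpha=%.3g activation=%s realization=%d elapsed=%.3fs",
                    alpha, act, r, time.perf_counter() - t0,
                )
    rows_df = pd.DataFrame(rows)
    summary = summarize_curve(rows_df)
    meta = {
        "task": config.task, "seed": int(config.seed),
        "n_realizations": int(config.n_realizations),
        "input_nodes": input_idx.tolist(), "readout_nodes": readout_idx.tolist(),
    }
    return PerformanceCurve(rows=rows_df, summary=summary, meta=meta)


def summarize_curve(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-(alpha, activation, metric) mean with a 95% t-interval (needs n >= 2)."""
    recs = []
    for (alpha, act, met), grp in rows.groupby(["alpha", "activation", "metric"]):
        vals = grp["value"].to_numpy()
        n = len(vals)
        mean = float(vals.mean())
        if n >= 2 and vals.std(ddof=1) > 0:
            half = scipy.stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
        elif n >= 2:
            half = 0.0
        else:
            half = np.nan
        recs.append({
            "alpha": alpha, "activation": act, "metric": met,
            "mean": mean, "ci_low": mean - half, "ci_high": mean + half, "n": n,
        })
    return pd.DataFrame(recs).sort_values(["activation", "metric", "alpha"]).reset_index(drop=True)


def _default_metric(task: str) -> str:
    return "memory_capacity" if task == "memory_capacity" else "balanced_accuracy"


def _curve_statistic(curve: PerformanceCurve, metric: str, statistic: str,
                     alpha_at: float | None) -> float:
    sub = curve.summary[curve.summary["metric"] == metric]
    if sub.empty:
        raise ParameterError(f"metric {metric!r} not present in curve")
    if statistic == "peak_over_grid":
        return float(sub["mean"].max())
    if statistic == "value_at_alpha":
        if alpha_at is None:
            raise ParameterError("value_at_alpha requires alpha_at")
        i = (sub["alpha"] - alpha_at).abs().idxmin()
        return float(sub.loc[i, "mean"])
    raise ParameterError(f"unknown statistic {statistic!r}")


def null_comparison(
    config: ExperimentConfig,
    n_nulls: int,
    statistic: str = "value_at_alpha",
    alpha_at: float | None = 1.0,
    alternative: str = "greater",
    metric: str | None = None,
    n_swaps_per_edge: int = 10,
) -> NullComparison:
    """Compare the empirical connectome against rewired degree-preserving nulls.

    Each null runs the identical experiment (matched datasets via the shared
    master seed -- a paired design). The nonparametric p-value uses the +1
    correction, ``p = (1 + #{null >= empirical}) / (1 + n_nulls)`` for
    ``alternative='greater'`` (mirrored for ``'less'``), so the smallest
    attainable p is ``1 / (n_nulls + 1)``.
    """
    if n_nulls < 1:
        raise ParameterError("n_nulls must be >= 1")
    if alternative not in ("greater", "less"):
        raise ParameterError("alternative must be 'greater' or 'less'")
    metric = metric or _default_metric(config.task)
    emp_curve = run_experiment(config)
    emp = _curve_statistic(emp_curve, metric, statistic, alpha_at)
    ensemble = rewire_null(
        config.connectome, n_nulls, n_swaps_per_edge=n_swaps_per_edge,
        seed=child_seed(config.seed, 99),
    )
    null_vals = np.empty(n_nulls)
    for i, w in enumerate(ensemble.replicates):
        null_c = Connectome(
            weights=w, node_ids=list(config.connectome.node_ids),
            directed=config.connectome.directed,
            partition=config.connectome.partition,
        )
        null_curve = run_experiment(replace(config, connectome=null_c))
        null_vals[i] = _curve_statistic(null_curve, metric, statistic, alpha_at)
    if alternative == "greater":
        p = (1 + int(np.sum(null_vals >= emp))) / (1 + n_nulls)
    else:
        p = (1 + int(np.sum(null_vals <= emp))) / (1 + n_nulls)
    return NullComparison(
        empirical_value=emp, null_values=null_vals, p_value=float(p),
        alpha_at=alpha_at if statistic == "value_at_alpha" else None,
        alternative=alternative, statistic=statistic, metric=metric,
    )


def one_way_anova(groups: Sequence[np.ndarray]) -> dict:
    """Standard one-way fixed-effects ANOVA from group samples.

    Returns F = MS_between / MS_within and its p-value. If MS_within is zero
    while MS_between is positive, F is reported as +inf (p = 0) with a note.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ParameterError("ANOVA needs at least 2 groups")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    if dfw <= 0:
        raise ParameterError("ANOVA needs more samples than groups")
    msb = ssb / dfb
    msw = ssw / dfw
    note = None
    if msw == 0:
        if msb > 0:
            f_stat, p = np.inf, 0.0
            note = "zero within-group variance; F reported as +inf"
        else:
            f_stat, p = 0.0, 1.0
            note = "all values identical across groups"
    else:
        f_stat = msb / msw
        p = float(scipy.stats.f.sf(f_stat, dfb, dfw))
    return {"F": float(f_stat), "p": p, "df_between": dfb, "df_within": dfw,
            "ms_between": float(msb), "ms_within": float(msw), "note": note}


def stratified_readout(
    config: ExperimentConfig,
    module_labels: Sequence[str] | None = None,
    alpha_at: float = 1.0,
    metric: str | None = None,
) -> StratifiedResult:
    """Fit one independent readout per partition module on the same traces.

    Returns per-module performance across realizations plus a one-way ANOVA
    across modules at the grid alpha nearest ``alpha_at`` (realizations are
    the sample unit).
    """
    c = config.connectome
    if c.partition is None:
        raise ParameterError("stratified readout needs a node partition")
    by_label = c.labels_to_indices()
    if module_labels is None:
        module_labels = sorted(by_label)
    modules: dict[str, list[int]] = {}
    for lab in module_labels:
        idx = by_label.get(lab, [])
        if not idx:
            warnings.warn(f"module {lab!r} has zero nodes; excluded")
            continue
        modules[lab] = idx
    if len(modules) < 2:
        raise ParameterError("need >= 2 non-empty readout modules")
    metric = metric or _default_metric(config.task)
    input_idx, _ = _resolve_nodes(config)
    n_channels = {"memory_capacity": 1, "perceptual_dm": 3, "context_dm": 7}[config.task]
    input_map = build_input_map(
        n_channels, c.n_nodes, input_idx,
        mode=config.input_map_mode, seed=child_seed(config.seed, 12),
    )
    act = config.activations[0]
    recs = []
    dataset_cache: dict[int, _tasks.TaskDataset] = {}
    for alpha in config.alphas:
        scaled = scale_to_alpha(c, float(alpha))
        reservoir = EchoStateReservoir(
            weights=scaled.weights, input_map=input_map, activation=act,
            input_gain=config.input_gain, input_nodes=input_idx,
        )
        for r in range(config.n_realizations):
            if r not in dataset_cache:
                dataset_cache[r] = _make_dataset(config, r)
            ds = dataset_cache[r]
            trace = simulate_esn(reservoir, ds.inputs, alpha=float(alpha))
            for lab, idx in modules.items():
                scores = _score_cell(config, ds, trace.states, np.asarray(idx), r)
                recs.append({
                    "alpha": float(alpha), "activation": act, "module": lab,
                    "realization": r, "metric": metric, "value": scores[metric],
                })
    table = pd.DataFrame(recs)
    alphas = np.asarray(sorted(set(table["alpha"])))
    a_star = float(alphas[np.argmin(np.abs(alphas - alpha_at))])
    at = table[(table["alpha"] == a_star) & (table["metric"] == metric)]
    groups = [at[at["module"] == lab]["value"].to_numpy() for lab in modules]
    anova = one_way_anova(groups)
    anova["alpha_at"] = a_star
    anova["metric"] = metric
    return StratifiedResult(table=table, anova=anova, modules=modules)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(obj, out_dir: str | Path, figures: bool = False) -> list[Path]:
    """Write tidy CSV + JSON summary (and optional figures) for a result object."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written: list[Path] = []
    if isinstance(obj, PerformanceCurve):
        p1 = out / "curve_rows.csv"
        obj.rows.to_csv(p1, index=False)
        p2 = out / "curve_summary.csv"
        obj.summary.to_csv(p2, index=False)
        p3 = out / "summary.json"
        p3.write_text(json.dumps(obj.meta, indent=2, sort_keys=True))
        written += [p1, p2, p3]
        if figures:
            from .plotting import plot_performance_curve
            written.append(plot_performance_curve(obj, out / "performance_vs_alpha.png"))
    elif isinstance(obj, NullComparison):
        p1 = out / "null_values.csv"
        pd.DataFrame({"null_value": obj.null_values}).to_csv(p1, index=False)
        p2 = out / "null_comparison.json"
        payload = {
            "empirical_value": obj.empirical_value, "p_value": obj.p_value,
            "alpha_at": obj.alpha_at, "alternative": obj.alternative,
            "statistic": obj.statistic, "metric": obj.metric,
            "n_nulls": int(len(obj.null_values)),
        }
        p2.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written += [p1, p2]
        if figures:
            from .plotting import plot_null_distribution
            written.append(plot_null_distribution(obj, out / "null_distribution.png"))
    elif isinstance(obj, StratifiedResult):
        p1 = out / "stratified_rows.csv"
        obj.table.to_csv(p1, index=False)
        p2 = out / "stratified_anova.json"
        p2.write_text(json.dumps(
            {**obj.anova, "modules": {k: list(map(int, v)) for k, v in obj.modules.items()}},
            indent=2, sort_keys=True,
        ))
        written += [p1, p2]
    else:
        raise ParameterError(f"do not know how to report a {type(obj).__name__}")
    return written
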