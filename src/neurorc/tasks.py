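"""Supervised cognitive-task datasets as input/target time series.

Three tasks are implemented:

* perceptual decision making -- a two-alternative forced-choice in which two
  noisy stimulus streams must be integrated over time and the one with the
  higher mean reported;
* context-dependent decision making -- two stimulus pairs are presented on
  every trial and a one-hot contextual cue indicates which pair is relevant;
* memory capacity -- a white-noise stream must be reconstructed at lags
  1..K, the standard probe of a reservoir's fading memory.

Each generator is a pure function of its parameters and seed. Trials tile
the time axis without overlap, classification targets use label 0 for
"no decision required" (fixation/stimulus epochs), and the ``decision_mask``
marks the timesteps on which performance is scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

DEFAULT_EPOCHS = (3, 10, 3)  # fixation, stimulus, decision (timesteps)
DEFAULT_COHERENCES = (0.1, 0.2, 0.4)
DEFAULT_STIM_MEAN = 0.5


@dataclass
class TaskDataset:
    """Input/target time series with trial structure.

    ``inputs`` is T x C, ``targets`` is T (integer labels, classification)
    or T x K (reals, regression). ``trial_bounds`` are half-open (start, end)
    pairs tiling [0, T); ``decision_mask`` is true only on scored timesteps,
    which always lie inside trials.
    """

    inputs: np.ndarray
    targets: np.ndarray
    trial_bounds: list[tuple[int, int]]
    decision_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_timesteps(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.inputs.shape[1]

    @property
    def n_trials(self) -> int:
        return len(self.trial_bounds)

    @property
    def is_classification(self) -> bool:
        return self.meta.get("mode", "classification") == "classification"

    def trial_labels(self) -> np.ndarray:
        """Per-trial target label (classification tasks only)."""
        labels = []
        for s, e in self.trial_bounds:
            seg = self.targets[s:e]
            nz = seg[seg > 0]
            labels.append(int(nz[0]) if nz.size else 0)
        return np.asarray(labels)

    def trial_time_mask(self, trial_indices: Sequence[int]) -> np.ndarray:
        """Boolean T-vector covering the given trials."""
        mask = np.zeros(self.n_timesteps, dtype=bool)
        for t in trial_indices:
            s, e = self.trial_bounds[t]
            mask[s:e] = True
        return mask


def _epoch_check(epoch_lengths: Sequence[int]) -> tuple[int, int, int]:
    if len(epoch_lengths) != 3 or any(int(e) < 1 for e in epoch_lengths):
        raise ParameterError("epoch_lengths must be three integers >= 1")
    return tuple(int(e) for e in epoch_lengths)  # type: ignore[return-value]


def make_perceptual_dm(
    n_trials: int,
    coherences: Sequence[float] = DEFAULT_COHERENCES,
    epoch_lengths: Sequence[int] = DEFAULT_EPOCHS,
    noise_sd: float = 0.2,
    stim_mean: float = DEFAULT_STIM_MEAN,
    seed: int = 0,
) -> TaskDataset:
    """Two-alternative forced-choice on two noisy stimulus streams.

    Channels: x1 is a constant bias (=1 inside trials); x2 and x3 carry the
    stimulus pair during the stimulus epoch, with generating means
    ``stim_mean + delta`` and ``stim_mean - delta`` (or swapped) and additive
    Gaussian noise of sd ``noise_sd``. The per-trial coherence ``delta`` is
    drawn uniformly from ``coherences``. Target y = 1 if x2's generating
    mean is the higher one, else 2, emitted only during the decision epoch.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    coherences = tuple(float(c) for c in coherences)
    if not coherences:
        raise ParameterError("coherence set must be non-empty")
    fix, stim, dec = _epoch_check(epoch_lengths)
    tl = fix + stim + dec
    T = n_trials * tl
    rng = np.random.default_rng(seed)
    X = np.zeros((T, 3))
    y = np.zeros(T, dtype=int)
    mask = np.zeros(T, dtype=bool)
    bounds = []
    for k in range(n_trials):
        s = k * tl
        bounds.append((s, s + tl))
        delta = rng.choice(coherences)
        label = 1 if rng.random() < 0.5 else 2
        hi, lo = stim_mean + delta, stim_mean - delta
        m2, m3 = (hi, lo) if label == 1 else (lo, hi)
        X[s : s + tl, 0] = 1.0
        sl = slice(s + fix, s + fix + stim)
        X[sl, 1] = m2 + rng.normal(0.0, noise_sd, size=stim)
        X[sl, 2] = m3 + rng.normal(0.0, noise_sd, size=stim)
        y[s + fix + stim : s + tl] = label
        mask[s + fix + stim : s + tl] = True
    meta = {
        "task": "perceptual_dm", "mode": "classification", "labels": [1, 2],
        "seed": int(seed), "noise_sd": noise_sd, "coherences": list(coherences),
        "epoch_lengths": [fix, stim, dec], "stim_mean": stim_mean,
    }
    return TaskDataset(X, y, bounds, mask, meta)


def make_context_dm(
    n_trials: int,
    coherences: Sequence[float] = DEFAULT_COHERENCES,
    epoch_lengths: Sequence[int] = DEFAULT_EPOCHS,
    noise_sd: float = 0.2,
    stim_mean: float = DEFAULT_STIM_MEAN,
    seed: int = 0,
) -> TaskDataset:
    """Context-dependent two-alternative discrimination over 7 channels.

    Channels: x1 bias; x2/x3 one-hot context cue held through the whole
    trial; x4/x5 the modality-1 stimulus pair and x6/x7 the modality-2 pair,
    both present on every trial. The target follows ONLY the cued modality:
    y = 1 if the first channel of the cued pair has the higher generating
    mean, else 2.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    coherences = tuple(float(c) for c in coherences)
    if not coherences:
        raise ParameterError("coherence set must be non-empty")
    fix, stim, dec = _epoch_check(epoch_lengths)
    tl = fix + stim + dec
    T = n_trials * tl
    rng = np.random.default_rng(seed)
    X = np.zeros((T, 7))
    y = np.zeros(T, dtype=int)
    mask = np.zeros(T, dtype=bool)
    bounds = []
    for k in range(n_trials):
        s = k * tl
        bounds.append((s, s + tl))
        context = int(rng.integers(0, 2))  # 0 -> modality 1 cued, 1 -> modality 2
        side = np.array([1 if rng.random() < 0.5 else 2 for _ in range(2)])
        delta = rng.choice(coherences, size=2)
        X[s : s + tl, 0] = 1.0
        X[s : s + tl, 1 + context] = 1.0
        sl = slice(s + fix, s + fix + stim)
        for mod in range(2):
            hi, lo = stim_mean + delta[mod], stim_mean - delta[mod]
            a, b = (hi, lo) if side[mod] == 1 else (lo, hi)
            X[sl, 3 + 2 * mod] = a + rng.normal(0.0, noise_sd, size=stim)
            X[sl, 4 + 2 * mod] = b + rng.normal(0.0, noise_sd, size=stim)
        label = int(side[context])
        y[s + fix + stim : s + tl] = label
        mask[s + fix + stim : s + tl] = True
    meta = {
        "task": "context_dm", "mode": "classification", "labels": [1, 2],
        "seed": int(seed), "noise_sd": noise_sd, "coherences": list(coherences),
        "epoch_lengths": [fix, stim, dec], "stim_mean": stim_mean,
    }
    return TaskDataset(X, y, bounds, mask, meta)


def make_memory_capacity(
    T: int,
    max_lag: int = 20,
    washout: int = 100,
    seed: int = 0,
) -> TaskDataset:
    """Lagged-reconstruction (memory capacity) dataset.

    A single channel u(t) ~ Uniform[-1, 1] i.i.d.; target channel k is the
    k-step delayed copy y_k(t) = u(t - k) for k = 1..max_lag. The first
    ``washout + max_lag`` timesteps are excluded from scoring. The whole
    series is one trial.
    """
    if T <= max_lag + washout:
        raise ParameterError("T must exceed max_lag + washout")
    if max_lag < 1:
        raise ParameterError("max_lag must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-1.0, 1.0, size=T)
    Y = np.zeros((T, max_lag))
    for k in range(1, max_lag + 1):
        Y[k:, k - 1] = u[:-k]
    mask = np.zeros(T, dtype=bool)
    mask[washout + max_lag :] = True
    meta = {
        "task": "memory_capacity", "mode": "regression", "seed": int(seed),
        "max_lag": int(max_lag), "washout": int(washout),
    }
    return TaskDataset(u[:, None], Y, [(0, T)], mask, meta)


def split_trials(
    d: TaskDataset, frac_train: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test partition of trials (no trial straddles the split).

    Multi-trial datasets are split by shuffled trial index. Single-trial
    regression datasets (memory capacity) are split along the time axis
    instead, contiguously and train-first; the returned arrays then hold
    time indices rather than trial indices.
    """
    if not (0 < frac_train < 1):
        raise ParameterError("frac_train must lie in (0, 1)")
    if d.n_trials >= 2:
        n = d.n_trials
        n_train = int(round(frac_train * n))
        if n_train == 0 or n_train == n:
            raise ParameterError("split fraction yields an empty partition")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    T = d.n_timesteps
    t_split = int(round(frac_train * T))
    if t_split == 0 or t_split == T:
        raise ParameterError("split fraction yields an empty partition")
    return np.arange(t_split), np.arange(t_split, T)


# ---------------------------------------------------------------------------
# serialization (plain-text: two CSV tables + JSON sidecar)
# ---------------------------------------------------------------------------

def save_dataset(d: TaskDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(d.inputs).to_csv(out / "inputs.csv", index=False)
    pd.DataFrame(np.atleast_2d(d.targets.T).T).to_csv(out / "targets.csv", index=False)
    sidecar = {
        "trial_bounds": [list(b) for b in d.trial_bounds],
        "decision_mask": d.decision_mask.astype(int).tolist(),
        "meta": d.meta,
    }
    (out / "dataset.json").write_text(json.dumps(sidecar))


def load_dataset(in_dir: str | Path) -> TaskDataset:
    src = Path(in_dir)
    inputs = pd.read_csv(src / "inputs.csv").to_numpy(dtype=float)
    targets = pd.read_csv(src / "targets.csv").to_numpy(dtype=float)
    sidecar = json.loads((src / "dataset.json").read_text())
    meta = sidecar["meta"]
    if meta.get("mode", "classification") == "classification":
        targets = targets[:, 0].astype(int)
    return TaskDataset(
        inputs=inputs,
        targets=targets,
        trial_bounds=[tuple(b) for b in sidecar["trial_bounds"]],
        decision_mask=np.asarray(sidecar["decision_mask"], dtype=bool),
        meta=meta,
    )


def make_task(task: str, **kwargs) -> TaskDataset:
    """Dispatch to a task generator by name."""
    generators = {
        "perceptual_dm": make_perceptual_dm,
        "context_dm": make_context_dm,
        "memory_capacity": make_memory_capacity,
    }
    if task not in generators:
        raise ParameterError(f"unknown task {task!r}; available: {sorted(generators)}")
    return generators[task](**kwargs)
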