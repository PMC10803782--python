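"""Connectivity matrices as fixed reservoir architectures.

A :class:`Connectome` wraps a square weighted adjacency matrix together with
node identifiers and an optional partition of nodes into systems (e.g.
intrinsic functional networks). The convention throughout the package is that
``weights[i, j]`` is the connection *from* node ``i`` *to* node ``j``; all
simulators therefore right-multiply row state vectors by the weight matrix.

Besides loading and validation, this module provides the standard matrix
manipulations used before a network is imposed as a reservoir (binarization,
normalization, spectral-radius scaling) and Maslov--Sneppen degree-preserving
rewiring for building null ensembles.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    FormatError,
    ParameterError,
    UnknownLabelError,
    ValidationError,
)

logger = logging.getLogger(__name__)

_SYMMETRY_ATOL = 1e-12


@dataclass
class Connectome:
    """A validated square connectivity matrix.

    Parameters
    ----------
    weights:
        ``n x n`` non-negative matrix; ``weights[i, j]`` is the edge from
        node ``i`` to node ``j``. The diagonal is zero (self-loops are
        stripped at construction).
    node_ids:
        Sequence of ``n`` node identifiers.
    directed:
        Whether the network is directed. For undirected networks the matrix
        is symmetric to within 1e-12.
    partition:
        Optional map from node id to a system label (e.g. ``"Vis"``).
    """

    weights: np.ndarray
    node_ids: list[str]
    directed: bool
    partition: dict[str, str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of binary edges; reciprocal pairs count once if undirected."""
        a = self.weights > 0
        if self.directed:
            return int(a.sum())
        return int(np.triu(a, 1).sum())

    @property
    def density(self) -> float:
        n = self.n_nodes
        possible = n * (n - 1) if self.directed else n * (n - 1) // 2
        return self.n_edges / possible

    def spectral_radius(self) -> float:
        return spectral_radius(self.weights)

    def degrees(self) -> tuple[np.ndarray, np.ndarray]:
        """Binary (in-degree, out-degree); identical vectors if undirected."""
        a = self.weights > 0
        return a.sum(axis=0).astype(int), a.sum(axis=1).astype(int)

    def labels_to_indices(self) -> dict[str, list[int]]:
        """Group node indices by partition label (node order preserved)."""
        if self.partition is None:
            raise ValidationError("connectome has no partition")
        out: dict[str, list[int]] = {}
        for i, nid in enumerate(self.node_ids):
            lab = self.partition.get(nid)
            if lab is not None:
                out.setdefault(lab, []).append(i)
        return out


@dataclass
class NullEnsemble:
    """A family of degree-preserving rewired surrogate matrices."""

    replicates: list[np.ndarray]
    generator_name: str
    seed: int
    n_swaps_per_edge: int = 10
    flagged: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.replicates)


def _validate_matrix(
    w: np.ndarray,
    directed_hint: bool | None,
    allow_negative: bool,
) -> tuple[np.ndarray, bool]:
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise FormatError(f"connectivity matrix must be square, got shape {w.shape}")
    if w.shape[0] < 2:
        raise FormatError("connectome needs at least 2 nodes")
    bad = np.argwhere(~np.isfinite(w))
    if bad.size:
        idx = ", ".join(f"({i},{j})" for i, j in bad[:10])
        raise ValidationError(f"non-finite entries at indices {idx}")
    if not allow_negative and (w < 0).any():
        raise ValidationError(
            "negative weights present; pass allow_negative=True to accept signed networks"
        )
    w = np.asarray(w, dtype=float).copy()
    n_loops = int(np.count_nonzero(np.diag(w)))
    if n_loops:
        logger.warning("stripped %d self-loop(s) from diagonal", n_loops)
        warnings.warn(f"stripped {n_loops} self-loop(s) from diagonal", stacklevel=3)
        np.fill_diagonal(w, 0.0)
    if directed_hint is None:
        directed = not np.allclose(w, w.T, atol=_SYMMETRY_ATOL, rtol=0.0)
    else:
        directed = bool(directed_hint)
        if not directed and not np.allclose(w, w.T, atol=_SYMMETRY_ATOL, rtol=0.0):
            raise ValidationError("matrix declared undirected but is not symmetric")
    return w, directed


def from_matrix(
    weights: np.ndarray,
    node_ids: Sequence[str] | None = None,
    directed: bool | None = None,
    partition: Mapping[str, str] | None = None,
    allow_negative: bool = False,
) -> Connectome:
    """Build a validated :class:`Connectome` from an in-memory array."""
    w, is_directed = _validate_matrix(np.asarray(weights, dtype=float), directed, allow_negative)
    if node_ids is None:
        node_ids = [f"n{i}" for i in range(w.shape[0])]
    node_ids = [str(x) for x in node_ids]
    if len(node_ids) != w.shape[0]:
        raise FormatError("node_ids length does not match matrix size")
    part = dict(partition) if partition is not None else None
    return Connectome(weights=w, node_ids=node_ids, directed=is_directed, partition=part)


def _read_csv_matrix(path: Path) -> tuple[np.ndarray, list[str] | None]:
    raw = pd.read_csv(path, header=None, dtype=str)
    first_row_numeric = raw.iloc[0].map(_is_number).all()
    if first_row_numeric:
        return raw.to_numpy(dtype=float), None
    # header row present; first column may hold node ids
    df = pd.read_csv(path, header=0, index_col=None)
    first_col_numeric = df.iloc[:, 0].map(_is_number).all()
    if not first_col_numeric:
        df = pd.read_csv(path, header=0, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def load_connectome(
    path: str | Path,
    directed_hint: bool | None = None,
    partition_path: str | Path | None = None,
    allow_negative: bool = False,
) -> Connectome:
    """Load a connectome from a dense CSV or a ``.npy`` array file.

    CSV files may carry a header row (and optionally a leading node-id
    column); headers are auto-detected. Symmetry is auto-detected when
    ``directed_hint`` is None. The diagonal is zeroed with a logged count.
    """
    path = Path(path)
    if path.suffix == ".npy":
        w = np.load(path)
        node_ids = None
    else:
        try:
            w, node_ids = _read_csv_matrix(path)
        except (pd.errors.ParserError, ValueError) as exc:
            raise FormatError(f"cannot parse {path} as a dense matrix: {exc}") from exc
    partition = load_partition(partition_path) if partition_path is not None else None
    return from_matrix(
        w, node_ids=node_ids, directed=directed_hint, partition=partition,
        allow_negative=allow_negative,
    )


def load_partition(path: str | Path) -> dict[str, str]:
    """Read a two-column ``node_id,label`` CSV into a dict."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if "node_id" in cols and "label" in cols:
        node_col = df.columns[cols.index("node_id")]
        lab_col = df.columns[cols.index("label")]
    elif df.shape[1] >= 2:
        node_col, lab_col = df.columns[0], df.columns[1]
    else:
        raise FormatError("partition CSV needs node_id and label columns")
    return {str(k): str(v) for k, v in zip(df[node_col], df[lab_col])}


def write_connectome(c: Connectome, path: str | Path) -> None:
    """Write the weight matrix as a headered dense CSV."""
    df = pd.DataFrame(c.weights, columns=c.node_ids)
    df.to_csv(path, index=False)


def write_partition(c: Connectome, path: str | Path) -> None:
    if c.partition is None:
        raise ValidationError("connectome has no partition to write")
    pd.DataFrame(
        {"node_id": list(c.partition.keys()), "label": list(c.partition.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# matrix transforms
# ---------------------------------------------------------------------------

def spectral_radius(w: np.ndarray) -> float:
    """Largest absolute eigenvalue (not singular value) of ``w``."""
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(w, dtype=float)))))


def binarize(c: Connectome) -> Connectome:
    """Map every nonzero weight to 1. Idempotent."""
    return replace(c, weights=(c.weights > 0).astype(float))


def normalize(c: Connectome, mode: str = "max") -> Connectome:
    """Rescale weights by a global factor.

    Modes: ``max`` divides by the maximum absolute weight, ``sum`` by the
    total weight, ``spectral`` by the spectral radius.
    """
    w = c.weights
    if not np.any(w):
        raise DegenerateInputError("cannot normalize an all-zero matrix")
    if mode == "max":
        denom = float(np.abs(w).max())
    elif mode == "sum":
        denom = float(np.abs(w).sum())
    elif mode == "spectral":
        denom = spectral_radius(w)
        if denom <= 1e-12:
            raise DegenerateInputError(
                "spectral radius is zero (nilpotent matrix); spectral normalization undefined"
            )
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")
    return replace(c, weights=w / denom)


def scale_to_alpha(c: Connectome, alpha: float) -> Connectome:
    """Rescale so the spectral radius equals ``alpha``: ``W' = alpha * W / rho(W)``.

    The spectral radius is the control parameter for the reservoir's global
    dynamical regime (stable below 1, chaotic above 1). Re-scaling always
    targets ``alpha`` from the current matrix, so successive calls do not
    compound.
    """
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    rho = spectral_radius(c.weights)
    if rho <= 1e-12:
        raise DegenerateInputError(
            "spectral radius is zero (e.g. a feed-forward/nilpotent graph); "
            "spectral scaling is undefined for this network"
        )
    return replace(c, weights=c.weights * (alpha / rho))


def select_nodes(
    c: Connectome,
    labels: Iterable[str],
    count: int | None = None,
    seed: int | None = None,
) -> list[int]:
    """Indices of nodes whose partition label is in ``labels`` (node order).

    If ``count`` is given, a random subsample of that size is drawn with the
    provided seed.
    """
    if c.partition is None:
        raise ValidationError("connectome has no partition; cannot select by label")
    labels = set(labels)
    available = sorted(set(c.partition.values()))
    missing = labels - set(available)
    if missing:
        raise UnknownLabelError(
            f"unknown label(s) {sorted(missing)}; available: {available}"
        )
    idx = [i for i, nid in enumerate(c.node_ids) if c.partition.get(nid) in labels]
    if count is not None:
        if count > len(idx):
            raise ParameterError(f"requested {count} nodes but only {len(idx)} match")
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(idx, size=count, replace=False).tolist())
    return idx


# ---------------------------------------------------------------------------
# degree-preserving rewiring (Maslov-Sneppen double-edge swaps)
# ---------------------------------------------------------------------------

def _rewire_once(
    c: Connectome, n_swaps_per_edge: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """One rewired replicate; returns (matrix, degenerate_flag)."""
    a = c.weights > 0
    n = a.shape[0]
    if c.directed:
        edges = [tuple(e) for e in np.argwhere(a)]
    else:
        edges = [tuple(e) for e in np.argwhere(np.triu(a, 1))]
    n_edges = len(edges)
    if n_edges < 2:
        raise ParameterError("need at least 2 edges to rewire")
    adj = a.copy()
    attempts = n_swaps_per_edge * n_edges
    successes = 0
    for _ in range(attempts):
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        (u, v), (x, y) = edges[i], edges[j]
        if not c.directed and rng.random() < 0.5:
            x, y = y, x
        if c.directed:
            # (u,v),(x,y) -> (u,y),(x,v)
            if u == y or x == v:
                continue
            if adj[u, y] or adj[x, v]:
                continue
            adj[u, v] = adj[x, y] = False
            adj[u, y] = adj[x, v] = True
            edges[i] = (u, y)
            edges[j] = (x, v)
        else:
            if len({u, v, x, y}) < 4:
                continue
            if adj[u, y] or adj[x, v]:
                continue
            adj[u, v] = adj[v, u] = adj[x, y] = adj[y, x] = False
            adj[u, y] = adj[y, u] = adj[x, v] = adj[v, x] = True
            edges[i] = (u, y) if u < y else (y, u)
            edges[j] = (x, v) if x < v else (v, x)
        successes += 1
    degenerate = successes == 0
    if degenerate:
        warnings.warn(
            "no valid double-edge swap found; replicate is a weight-permuted copy",
            stacklevel=3,
        )
        adj = a.copy()
        if c.directed:
            edges = [tuple(e) for e in np.argwhere(adj)]
        else:
            edges = [tuple(e) for e in np.argwhere(np.triu(adj, 1))]
    # permute the original weight multiset onto the rewired topology
    if c.directed:
        w_src = c.weights[c.weights > 0]
    else:
        triu = np.triu(c.weights, 1)
        w_src = triu[triu > 0]
    perm = rng.permutation(w_src)
    out = np.zeros_like(c.weights)
    for (u, v), w in zip(edges, perm):
        out[u, v] = w
        if not c.directed:
            out[v, u] = w
    return out, degenerate


def rewire_null(
    c: Connectome,
    n_reps: int,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> NullEnsemble:
    """Build an ensemble of degree- and density-preserving rewired surrogates.

    Each replicate is produced by repeated random double-edge swaps that
    reject self-loops and multi-edges, so the binary in- and out-degree
    sequences of the source are preserved exactly, as is the number of edges.
    Weighted networks receive a random permutation of the original weight
    multiset on the rewired topology. Replicates are independent but fully
    determined by ``seed``.
    """
    if c.n_edges < 2:
        raise ParameterError("connectome has fewer than 2 edges; nothing to rewire")
    replicates: list[np.ndarray] = []
    flagged: list[int] = []
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        w, degenerate = _rewire_once(c, n_swaps_per_edge, rng)
        replicates.append(w)
        if degenerate:
            flagged.append(r)
    return NullEnsemble(
        replicates=replicates,
        generator_name="maslov_sneppen",
        seed=int(seed),
        n_swaps_per_edge=n_swaps_per_edge,
        flagged=flagged,
    )


def write_null_ensemble(ens: NullEnsemble, out_dir: str | Path, node_ids: Sequence[str] | None = None) -> None:
    """Write replicates as numbered CSVs plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, w in enumerate(ens.replicates):
        cols = list(node_ids) if node_ids is not None else [f"n{k}" for k in range(w.shape[0])]
        pd.DataFrame(w, columns=cols).to_csv(out / f"null_{i:04d}.csv", index=False)
    manifest = {
        "generator": ens.generator_name,
        "seed": ens.seed,
        "n_swaps_per_edge": ens.n_swaps_per_edge,
        "n_replicates": len(ens),
        "flagged": ens.flagged,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# synthetic connectomes
# ---------------------------------------------------------------------------

def make_synthetic(
    kind: str,
    n: int,
    density: float = 0.1,
    n_blocks: int = 2,
    within_density: float = 0.5,
    between_density: float = 0.05,
    directed: bool = True,
    seed: int = 0,
) -> Connectome:
    """Generate a synthetic connectome for experimentation and testing.

    Kinds
    -----
    ``random``
        Directed (or undirected) Erdos-Renyi graph with uniform(0, 1] weights.
    ``modular``
        Block-structured graph with separate within- and between-block edge
        densities; nodes carry ``M1..Mk`` partition labels.
    ``delay_line``
        Directed chain ``i -> i+1`` with unit weights (n-1 edges). Nilpotent,
        so spectral scaling does not apply.
    ``ring``
        Directed cycle with unit weights; spectral radius exactly 1.
    """
    if n < 2:
        raise ParameterError("n must be >= 2")
    rng = np.random.default_rng(seed)
    if kind == "random":
        w = _random_graph(n, density, directed, rng)
        return from_matrix(w, directed=directed)
    if kind == "modular":
        for d in (within_density, between_density):
            if not (0 < d <= 1):
                raise ParameterError("densities must lie in (0, 1]")
        block = np.array_split(np.arange(n), n_blocks)
        w = np.zeros((n, n))
        mask_within = np.zeros((n, n), dtype=bool)
        for b in block:
            mask_within[np.ix_(b, b)] = True
        np.fill_diagonal(mask_within, False)
        rand = rng.random((n, n))
        if not directed:
            rand = np.triu(rand, 1)
            rand = rand + rand.T
        off = ~np.eye(n, dtype=bool)
        keep = np.where(mask_within, rand < within_density, rand < between_density) & off
        vals = rng.uniform(0.0, 1.0, size=(n, n)) + 1e-12
        if not directed:
            vals = np.triu(vals, 1)
            vals = vals + vals.T
            keep = np.triu(keep, 1)
            keep = keep | keep.T
        w[keep] = vals[keep]
        partition = {f"n{i}": f"M{bi + 1}" for bi, b in enumerate(block) for i in b}
        return from_matrix(w, directed=directed, partition=partition)
    if kind == "delay_line":
        w = np.zeros((n, n))
        w[np.arange(n - 1), np.arange(1, n)] = 1.0
        return from_matrix(w, directed=True)
    if kind == "ring":
        w = np.zeros((n, n))
        w[np.arange(n - 1), np.arange(1, n)] = 1.0
        w[n - 1, 0] = 1.0
        return from_matrix(w, directed=True)
    raise ParameterError(f"unknown synthetic kind {kind!r}")


def _random_graph(n: int, density: float, directed: bool, rng: np.random.Generator) -> np.ndarray:
    if not (0 < density <= 1):
        raise ParameterError("density must lie in (0, 1]")
    rand = rng.random((n, n))
    vals = rng.uniform(0.0, 1.0, size=(n, n)) + 1e-12
    if directed:
        keep = (rand < density) & ~np.eye(n, dtype=bool)
    else:
        keep = np.triu(rand < density, 1)
        keep = keep | keep.T
        vals = np.triu(vals, 1)
        vals = vals + vals.T
    w = np.zeros((n, n))
    w[keep] = vals[keep]
    return w
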