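"""Pseudotime normalization, subsampling-based uncertainty, and permutation.

Pseudotime inferred from single-cell data is random: it depends on which
cells were captured and on the inference algorithm. To propagate that
randomness into differential-expression testing, this module repeatedly
subsamples cells (80% without replacement by default; the bootstrap is
unusable because duplicated cells break trajectory tools), re-runs a
user-supplied pseudotime method on every subsample, and then permutes each
subsample's pseudotime to sever any expression-pseudotime association while
keeping both marginals — the exchangeable null the test is built on.
"""

from __future__ import annotations

import inspect
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


class DegeneratePseudotimeError(ValueError):
    """Pseudotime inference returned a constant (uninformative) vector."""


class UncertaintyEstimationError(RuntimeError):
    """Too few subsamples yielded usable pseudotime."""


@dataclass
class PseudotimeVector:
    """Normalized pseudotime T in [0, 1] with aligned cell identifiers."""

    values: np.ndarray
    cell_ids: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SubsampleDraw:
    indices: np.ndarray
    inferred: PseudotimeVector | None
    permuted: PseudotimeVector | None = None
    status: str = "ok"


@dataclass
class PseudotimeDraws:
    """Original pseudotime plus B subsample realizations (and permutations)."""

    original: PseudotimeVector | None
    subsamples: list[SubsampleDraw] = field(default_factory=list)

    @property
    def n_usable(self) -> int:
        return sum(1 for s in self.subsamples if s.status == "ok")

    def usable(self):
        return [s for s in self.subsamples if s.status == "ok"]


def normalize_pseudotime(raw, cell_ids=None) -> PseudotimeVector:
    """Affine min-max rescaling of a raw pseudotime vector onto [0, 1]."""
    values = np.asarray(getattr(raw, "values", raw), dtype=float).ravel()
    if values.size < 2:
        raise ValueError("pseudotime vector must have length >= 2")
    if np.any(~np.isfinite(values)):
        raise ValueError("pseudotime vector contains missing values")
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        raise DegeneratePseudotimeError("constant pseudotime: inference degenerate")
    return PseudotimeVector(values=(values - lo) / (hi - lo), cell_ids=cell_ids)


def draw_subsamples(n, fraction=0.8, B=1000, groups=None, seed=0):
    """Draw B cell-index subsets of size floor(fraction * n), no replacement.

    With `groups`, sampling is stratified: floor(fraction * group size) per
    group, plus uniformly-sampled leftover cells to reach the overall size.
    Subsample b is generated from its own counter-based RNG stream, so the
    first 100 subsamples of a B=1000 run equal a B=100 run with the same seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    target = int(np.floor(fraction * n))
    if target < 2:
        raise ValueError("fraction * n must be at least 2")
    if groups is not None:
        groups = np.asarray(groups)
        if len(groups) != n:
            raise ValueError("groups must have length n")
        group_idx = [np.flatnonzero(groups == g) for g in pd.unique(groups)]
    sets = []
    for b in range(B):
        rng = np.random.default_rng([seed, 1, b])
        if groups is None:
            idx = rng.choice(n, size=target, replace=False)
        else:
            parts = []
            for gi in group_idx:
                k = int(np.floor(fraction * len(gi)))
                if k > 0:
                    parts.append(rng.choice(gi, size=k, replace=False))
            idx = np.concatenate(parts) if parts else np.empty(0, dtype=int)
            deficit = target - len(idx)
            if deficit > 0:
                pool = np.setdiff1d(np.arange(n), idx)
                idx = np.concatenate([idx, rng.choice(pool, size=deficit, replace=False)])
        sets.append(np.sort(idx))
    return sets


def builtin_pseudotime(counts, n_components: int = 2) -> PseudotimeVector:
    """Principal-component pseudotime: a minimal principal-curve surrogate.

    Library-size-normalizes and log1p-transforms the counts, projects onto
    the leading principal components, and orders cells by the first
    principal axis, with the sign fixed by correlation with total counts
    (fallback: first loading) so the ordering is deterministic.
    """
    X = _as_matrix(counts)
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 cells and 2 genes")
    totals = X.sum(axis=1)
    scale = np.where(totals > 0, totals, 1.0)
    norm = np.log1p(X / scale[:, None] * np.median(np.where(totals > 0, totals, np.nan)))
    norm = norm - norm.mean(axis=0)
    if not np.any(norm):
        raise DegeneratePseudotimeError("zero-variance expression matrix")
    k = min(n_components, min(n, m) - 1)
    U, S, _ = np.linalg.svd(norm, full_matrices=False)
    pc1 = U[:, 0] * S[0]
    r = np.corrcoef(pc1, totals)[0, 1] if np.std(totals) > 0 else 0.0
    if r < 0:
        pc1 = -pc1
    elif r == 0 and pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    return normalize_pseudotime(pc1)


def infer_subsample_pseudotime(
    counts,
    index_sets,
    method,
    original: PseudotimeVector | None = None,
    min_usable: int = 50,
    context=None,
) -> PseudotimeDraws:
    """Run the pseudotime method on every cell subsample.

    `method` maps a (cells x genes) count matrix to one raw pseudotime value
    per row; it is applied with the same parameters as on the full data.
    Failures (exceptions, constant output) are recorded with status='failed'
    and excluded downstream; if fewer than `min_usable` subsamples succeed an
    UncertaintyEstimationError is raised.
    """
    X = _as_matrix(counts)
    if original is None:
        original = normalize_pseudotime(_call_method(method, X, context))
    draws = PseudotimeDraws(original=original)
    for idx in index_sets:
        sub = X[idx]
        try:
            raw = _call_method(method, sub, context)
            vec = normalize_pseudotime(raw)
            if len(vec) != len(idx):
                raise ValueError("pseudotime method returned wrong length")
            draws.subsamples.append(SubsampleDraw(indices=idx, inferred=vec))
        except Exception as exc:  # failed subsample: bookkeep and move on
            draws.subsamples.append(
                SubsampleDraw(indices=idx, inferred=None, status="failed")
            )
            warnings.warn(f"pseudotime inference failed on a subsample: {exc}", stacklevel=2)
    if draws.n_usable < min(min_usable, len(index_sets)):
        raise UncertaintyEstimationError(
            f"only {draws.n_usable} of {len(index_sets)} subsamples usable "
            f"(minimum {min_usable})"
        )
    return draws


def permute_pseudotime(draws: PseudotimeDraws, seed: int = 0) -> PseudotimeDraws:
    """Fill each usable subsample with an independent uniform permutation
    of its inferred pseudotime (multisets preserved exactly)."""
    if draws.n_usable < 1:
        raise UncertaintyEstimationError("no usable subsamples to permute")
    for b, sub in enumerate(draws.subsamples):
        if sub.status != "ok":
            continue
        rng = np.random.default_rng([seed, 2, b])
        perm = rng.permutation(len(sub.inferred))
        sub.permuted = PseudotimeVector(
            values=sub.inferred.values[perm],
            cell_ids=None if sub.inferred.cell_ids is None else sub.inferred.cell_ids[perm],
        )
    return draws


def uncertainty_summary(draws: PseudotimeDraws, cell_ids=None, return_long: bool = False):
    """Per-cell summary of inferred pseudotime across subsamples.

    Each subsample is first oriented against the original pseudotime
    (flipped to 1 - T^b when its Spearman correlation over shared cells is
    negative) — pseudotime direction is unidentifiable across subsamples, and
    this alignment matters only for reporting, not for testing.
    """
    usable = draws.usable()
    if len(usable) < 2:
        raise ValueError("need at least 2 usable subsamples to summarize")
    n = len(draws.original)
    rows = []
    per_cell = [[] for _ in range(n)]
    for b, sub in enumerate(usable):
        vals = sub.inferred.values
        ref = draws.original.values[sub.indices]
        rho = spearmanr(vals, ref).statistic if len(vals) > 2 else np.corrcoef(vals, ref)[0, 1]
        if np.isfinite(rho) and rho < 0:
            vals = 1.0 - vals
        for i, v in zip(sub.indices, vals):
            per_cell[i].append(v)
        rows.append(pd.DataFrame({"cell_index": sub.indices, "subsample": b, "pseudotime": vals}))
    if cell_ids is None:
        cell_ids = (
            draws.original.cell_ids
            if draws.original.cell_ids is not None
            else np.array([f"cell_{i}" for i in range(n)])
        )
    summary = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "n_subsamples": [len(v) for v in per_cell],
            "mean": [np.mean(v) if v else np.nan for v in per_cell],
            "sd": [np.std(v, ddof=1) if len(v) > 1 else np.nan for v in per_cell],
            "q05": [np.quantile(v, 0.05) if v else np.nan for v in per_cell],
            "q95": [np.quantile(v, 0.95) if v else np.nan for v in per_cell],
        }
    )
    if return_long:
        return summary, pd.concat(rows, ignore_index=True)
    return summary


def load_subsample_pseudotime(path, index_sets, cell_ids) -> PseudotimeDraws:
    """Build PseudotimeDraws from a precomputed TSV of per-subsample
    pseudotime (columns: subsample_id, cell_id, pseudotime), supporting
    external trajectory tools run out-of-band."""
    table = pd.read_csv(path, sep="\t")
    required = {"subsample_id", "cell_id", "pseudotime"}
    if not required.issubset(table.columns):
        raise ValueError(f"TSV must have columns {sorted(required)}")
    pos = {c: i for i, c in enumerate(cell_ids)}
    draws = PseudotimeDraws(original=None)
    for b, idx in enumerate(index_sets):
        block = table[table["subsample_id"] == b]
        if block.empty:
            draws.subsamples.append(SubsampleDraw(indices=idx, inferred=None, status="failed"))
            continue
        order = {pos[c]: t for c, t in zip(block["cell_id"], block["pseudotime"])}
        try:
            raw = np.array([order[i] for i in idx])
            vec = normalize_pseudotime(raw)
            draws.subsamples.append(SubsampleDraw(indices=idx, inferred=vec))
        except (KeyError, DegeneratePseudotimeError):
            draws.subsamples.append(SubsampleDraw(indices=idx, inferred=None, status="failed"))
    return draws


def _as_matrix(counts) -> np.ndarray:
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float)
    if hasattr(counts, "X"):  # AnnData
        X = counts.X
        if hasattr(X, "todense"):
            X = np.asarray(X.todense())
        return np.asarray(X, dtype=float)
    if hasattr(counts, "counts"):  # SimulatedDataset
        return np.asarray(counts.counts, dtype=float)
    return np.asarray(counts, dtype=float)


def _call_method(method, X, context):
    if context is not None:
        try:
            sig = inspect.signature(method)
            if len(sig.parameters) >= 2:
                return method(X, context)
        except (TypeError, ValueError):
            pass
    return method(X)
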