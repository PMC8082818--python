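"""Synthetic single-cell lineage data with known differential-expression labels.

Generates dyntoy-style count matrices: cells lie along a latent time in
[0, 1] (single lineage, or two branches sharing a common root), counts are
negative-binomial, and a stated fraction of genes is differentially expressed
— their log-mean follows a random smooth trend in latent time (monotone,
sigmoidal, or transient), scaled to at least a two-fold max/min mean ratio —
while the remaining genes have constant means.

Dispersion tiers map to NB size parameters drawn log-uniformly per gene:
low phi in [10, 100] (near-Poisson), medium [3, 10], high [1, 3]
(strongly overdispersed). These constants are a convention of this package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix
from scipy.special import expit

DISPERSION_TIERS = {"low": (10.0, 100.0), "medium": (3.0, 10.0), "high": (1.0, 3.0)}
TREND_KINDS = ("monotone", "sigmoid", "transient")
_BRANCH_TIME = 0.4  # branches share a root segment over true_time <= 0.4
_MIN_LOG_FOLD = np.log(2.0)
_MAX_LOG_FOLD = np.log(8.0)


@dataclass
class SimulatedDataset:
    """A simulated cells-by-genes count matrix with ground truth."""

    counts: np.ndarray            # (n_cells, n_genes) int
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    true_time: np.ndarray         # (n_cells,) in [0, 1]
    de_labels: np.ndarray         # (n_genes,) bool
    lineage_id: np.ndarray        # (n_cells,) int branch index
    params: dict
    means: np.ndarray | None = None        # latent NB means (n, m)
    trend_kinds: np.ndarray | None = None  # per-gene trend family
    zi_indicators: np.ndarray | None = None  # dropout Z (1 = kept)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.astype(np.float32),
            obs=pd.DataFrame(
                {"true_time": self.true_time, "lineage_id": self.lineage_id},
                index=self.cell_ids,
            ),
            var=pd.DataFrame({"is_de": self.de_labels}, index=self.gene_ids),
        )
        return adata

    def write(self, outdir: str) -> None:
        """Write counts as MatrixMarket MTX plus TSV identifier/truth files."""
        os.makedirs(outdir, exist_ok=True)
        mmwrite(os.path.join(outdir, "counts.mtx"), csr_matrix(self.counts))
        pd.Series(self.gene_ids).to_csv(
            os.path.join(outdir, "genes.tsv"), sep="\t", index=False, header=False
        )
        pd.Series(self.cell_ids).to_csv(
            os.path.join(outdir, "cells.tsv"), sep="\t", index=False, header=False
        )
        pd.DataFrame(
            {"cell": self.cell_ids, "true_time": self.true_time, "lineage_id": self.lineage_id}
        ).to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
        pd.DataFrame({"gene": self.gene_ids, "is_de": self.de_labels.astype(int)}).to_csv(
            os.path.join(outdir, "gene_truth.tsv"), sep="\t", index=False
        )

    @classmethod
    def read(cls, outdir: str) -> "SimulatedDataset":
        counts = np.asarray(mmread(os.path.join(outdir, "counts.mtx")).todense())
        genes = pd.read_csv(os.path.join(outdir, "genes.tsv"), sep="\t", header=None)[0].to_numpy()
        cells = pd.read_csv(os.path.join(outdir, "cells.tsv"), sep="\t", header=None)[0].to_numpy()
        truth = pd.read_csv(os.path.join(outdir, "truth.tsv"), sep="\t")
        gene_truth = pd.read_csv(os.path.join(outdir, "gene_truth.tsv"), sep="\t")
        return cls(
            counts=counts.astype(np.int64),
            cell_ids=cells,
            gene_ids=genes,
            true_time=truth["true_time"].to_numpy(),
            de_labels=gene_truth["is_de"].to_numpy().astype(bool),
            lineage_id=truth["lineage_id"].to_numpy(),
            params={},
        )


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _random_trend(rng, kind):
    """A random smooth trend function of t in [0, 1] with unit amplitude."""
    sign = rng.choice([-1.0, 1.0])
    if kind == "monotone":
        c = rng.uniform(0.7, 1.5)
        return lambda t: sign * t**c
    if kind == "sigmoid":
        k = rng.uniform(5.0, 15.0)
        t0 = rng.uniform(0.25, 0.75)
        return lambda t: sign * expit(k * (t - t0))
    if kind == "transient":
        t0 = rng.uniform(0.3, 0.7)
        sd = rng.uniform(0.08, 0.2)
        return lambda t: sign * np.exp(-0.5 * ((t - t0) / sd) ** 2)
    raise ValueError(f"unknown trend kind: {kind}")


def _scaled_trend(rng, kind, amplitude):
    """Trend rescaled so max - min of the log-mean equals `amplitude`."""
    f = _random_trend(rng, kind)
    grid = np.linspace(0.0, 1.0, 201)
    vals = f(grid)
    span = vals.max() - vals.min()
    scale = amplitude / span if span > 0 else 0.0
    offset = vals.mean() * scale
    return lambda t: f(t) * scale - offset


def simulate_lineage(
    n_cells: int,
    n_genes: int,
    prop_de: float,
    dispersion_level: str = "medium",
    topology: str = "single",
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate a single-lineage or bifurcating NB count matrix.

    Parameters
    ----------
    n_cells, n_genes : matrix dimensions (n_cells >= 10, n_genes >= 2).
    prop_de : fraction of genes whose mean varies with latent time.
    dispersion_level : 'low' | 'medium' | 'high' NB dispersion tier.
    topology : 'single' or 'bifurcation' (two branches after a shared root).
    seed : RNG seed; output is deterministic given the seed.
    """
    if not (isinstance(n_cells, (int, np.integer)) and isinstance(n_genes, (int, np.integer))):
        raise ValueError("n_cells and n_genes must be integers")
    if n_cells < 10 or n_genes < 2:
        raise ValueError("need n_cells >= 10 and n_genes >= 2")
    if not 0.0 <= prop_de <= 1.0:
        raise ValueError("prop_de must lie in [0, 1]")
    if dispersion_level not in DISPERSION_TIERS:
        raise ValueError(f"dispersion_level must be one of {sorted(DISPERSION_TIERS)}")
    if topology not in ("single", "bifurcation"):
        raise ValueError("topology must be 'single' or 'bifurcation'")

    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, n_cells)
    t = (t - t.min()) / (t.max() - t.min())
    if topology == "bifurcation":
        branch = rng.integers(0, 2, n_cells)
    else:
        branch = np.zeros(n_cells, dtype=int)

    n_de = int(round(prop_de * n_genes))
    de = np.zeros(n_genes, dtype=bool)
    de[:n_de] = True

    lo, hi = DISPERSION_TIERS[dispersion_level]
    phi = np.exp(rng.uniform(np.log(lo), np.log(hi), n_genes))
    base = rng.lognormal(mean=np.log(5.0), sigma=0.8, size=n_genes)

    log_mu = np.tile(np.log(base), (n_cells, 1))
    kinds = np.full(n_genes, "flat", dtype=object)
    for j in range(n_de):
        kind = TREND_KINDS[rng.integers(0, len(TREND_KINDS))]
        kinds[j] = kind
        amp = rng.uniform(_MIN_LOG_FOLD, _MAX_LOG_FOLD)
        f = _scaled_trend(rng, kind, amp)
        if topology == "single":
            log_mu[:, j] += f(t)
        else:
            # branch 0 follows f everywhere; branch 1 follows f up to the
            # split, then a separate smooth departure, continuous at the split
            g_amp = rng.uniform(_MIN_LOG_FOLD, _MAX_LOG_FOLD) * rng.choice([-1.0, 1.0])
            trend = f(np.minimum(t, _BRANCH_TIME))
            after = _smoothstep((t - _BRANCH_TIME) / (1.0 - _BRANCH_TIME))
            trend0 = f(t)
            trend1 = trend + g_amp * after
            log_mu[:, j] += np.where(branch == 0, trend0, trend1)

    mu = np.exp(np.clip(log_mu, -20.0, 20.0))
    counts = rng.negative_binomial(phi[None, :], phi[None, :] / (phi[None, :] + mu))

    return SimulatedDataset(
        counts=counts.astype(np.int64),
        cell_ids=np.array([f"cell_{i}" for i in range(n_cells)]),
        gene_ids=np.array([f"gene_{j}" for j in range(n_genes)]),
        true_time=t,
        de_labels=de,
        lineage_id=branch,
        params={
            "n_cells": int(n_cells),
            "n_genes": int(n_genes),
            "prop_de": float(prop_de),
            "dispersion_level": dispersion_level,
            "topology": topology,
            "seed": int(seed),
        },
        means=mu,
        trend_kinds=np.asarray(kinds),
    )


def simulate_zero_inflation(
    ds: SimulatedDataset, alpha0: float, alpha1: float, seed: int = 0
) -> SimulatedDataset:
    """Overlay logistic dropout on a simulated dataset.

    Each count is kept with probability p_ij where
    logit(p_ij) = alpha0 + alpha1 * log(mu_ij) (mu from the generator);
    dropped entries become zero. The realized keep indicators Z are recorded
    for EM-recovery checks.
    """
    if not (np.isfinite(alpha0) and np.isfinite(alpha1)):
        raise ValueError("alpha0 and alpha1 must be finite")
    if ds.means is None:
        raise ValueError("dataset lacks latent means; regenerate with simulate_lineage")
    rng = np.random.default_rng(seed)
    logit_p = alpha0 + alpha1 * np.log(np.clip(ds.means, 1e-300, None))
    p = expit(logit_p)
    z = rng.random(ds.counts.shape) < p
    new_counts = np.where(z, ds.counts, 0)
    params = dict(ds.params)
    params.update({"zi_alpha0": float(alpha0), "zi_alpha1": float(alpha1), "zi_seed": int(seed)})
    return replace(
        ds,
        counts=new_counts.astype(np.int64),
        params=params,
        zi_indicators=z.astype(np.int8),
    )


def shuffle_null_genes(counts, gene_ids, seed: int = 0):
    """Independently permute the named genes' expression across cells.

    Accepts a SimulatedDataset, an AnnData, or a pandas DataFrame
    (cells x genes); returns an object of the same type with the selected
    columns permuted (per-gene count multisets are preserved exactly).
    """
    rng = np.random.default_rng(seed)
    if isinstance(counts, SimulatedDataset):
        lookup = {g: j for j, g in enumerate(counts.gene_ids)}
        mat = counts.counts.copy()
        for g in gene_ids:
            if g not in lookup:
                raise KeyError(f"unknown gene id: {g}")
            mat[:, lookup[g]] = mat[rng.permutation(mat.shape[0]), lookup[g]]
        return replace(counts, counts=mat)
    if isinstance(counts, pd.DataFrame):
        out = counts.copy()
        for g in gene_ids:
            if g not in out.columns:
                raise KeyError(f"unknown gene id: {g}")
            out[g] = out[g].to_numpy()[rng.permutation(len(out))]
        return out
    # AnnData
    adata = counts.copy()
    var_index = {g: j for j, g in enumerate(adata.var_names)}
    X = np.asarray(adata.X)
    for g in gene_ids:
        if g not in var_index:
            raise KeyError(f"unknown gene id: {g}")
        X[:, var_index[g]] = X[rng.permutation(X.shape[0]), var_index[g]]
    adata.X = X
    return adata
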