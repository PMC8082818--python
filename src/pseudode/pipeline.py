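"""End-to-end pseudotime differential-expression workflow.

Four steps: (1) subsample cells, (2) re-infer pseudotime per subsample and
permute it, (3) fit NB-GAM / ZINB-GAM per gene to the original data and to
every permuted subsample, (4) compute empirical and parametric p-values from
the per-gene permutation null and BH-adjust.

`PseudotimeDE` is the scikit-learn-style front end: configure it, call
`fit(counts)`, read `results_`. `run_pseudotimede` drives it from a
`RunConfig` (file paths in, TSV/JSON out) and backs the command-line
interface.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator

from ._nb import GAMControls, compute_statistics_batch, fit_nb_batch, fit_zinb_batch, wood_test_batch
from ._splines import build_spline_basis
from .pseudotime import (
    PseudotimeDraws,
    PseudotimeVector,
    builtin_pseudotime,
    draw_subsamples,
    infer_subsample_pseudotime,
    load_subsample_pseudotime,
    normalize_pseudotime,
    permute_pseudotime,
    uncertainty_summary,
)
from .testing import (
    ParametricUnavailableError,
    bh_adjust,
    empirical_pvalue,
    fit_parametric_null,
    parametric_pvalue,
)

RESULT_COLUMNS = [
    "gene", "statistic", "rank", "model", "B_used", "p_emp", "p_param",
    "p_asymptotic", "padj_param", "null_model", "gof_p", "converged",
]


@dataclass
class RunConfig:
    """Reproducible configuration of one run; defaults follow the method's
    standard settings (B=1000 subsamples of 80% of cells, 6 spline knots,
    AIC margin 10 for ZINB, LRT level 0.01, >90%-zero gene filter)."""

    counts_path: str | None = None
    pseudotime_source: str = "builtin"      # 'builtin' | path to TSV
    subsample_pseudotime_path: str | None = None
    groups_path: str | None = None
    B: int = 1000
    fraction: float = 0.8
    knots: int = 6
    model: str = "auto"                     # 'auto' | 'nb' | 'zinb'
    aic_delta: float = 10.0
    lrt_alpha: float = 0.01
    zero_filter: float = 0.9
    fixed_mode: bool = False
    min_usable: int = 50
    compute_gof: bool = False
    seed: int = 0
    n_workers: int = 1
    output_dir: str | None = None
    orientation: str = "auto"


def read_counts(path, orientation: str = "auto"):
    """Read a cells-by-genes count matrix.

    Supports MatrixMarket MTX (with sibling `cells.tsv` / `genes.tsv` or
    `barcodes.tsv` / `features.tsv` name files), dense delimited tables with
    row/column labels, and `.h5ad`. Orientation is normalized to
    cells x genes: MTX name files disambiguate exactly; delimited tables are
    taken as cells x genes unless orientation='genes_by_cells'.
    """
    import anndata as ad
    from scipy.io import mmread

    path = str(path)
    if path.endswith(".h5ad"):
        adata = ad.read_h5ad(path)
        counts = np.asarray(adata.X.todense() if hasattr(adata.X, "todense") else adata.X)
        cells, genes = np.asarray(adata.obs_names), np.asarray(adata.var_names)
    elif path.endswith(".mtx"):
        mat = np.asarray(mmread(path).todense())
        d = os.path.dirname(path)
        cells = _read_names(d, ("cells.tsv", "barcodes.tsv"))
        genes = _read_names(d, ("genes.tsv", "features.tsv"))
        if cells is not None and mat.shape[0] != len(cells) and mat.shape[1] == len(cells):
            mat = mat.T
        counts = mat
        if cells is None:
            cells = np.array([f"cell_{i}" for i in range(mat.shape[0])])
        if genes is None:
            genes = np.array([f"gene_{j}" for j in range(mat.shape[1])])
    else:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\r\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise ValueError("duplicate cell or gene identifiers")
        df = pd.read_csv(path, sep=sep, index_col=0)
        counts = df.to_numpy()
        cells, genes = np.asarray(df.index), np.asarray(df.columns)
    if orientation == "genes_by_cells":
        counts = counts.T
        cells, genes = genes, cells
    counts = np.asarray(counts)
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("count matrix must contain non-negative integers")
    if len(set(cells)) != len(cells) or len(set(genes)) != len(genes):
        raise ValueError("duplicate cell or gene identifiers")
    return pd.DataFrame(counts.astype(np.int64), index=cells, columns=genes)


def _read_names(d, candidates):
    for name in candidates:
        p = os.path.join(d, name)
        if os.path.exists(p):
            return pd.read_csv(p, sep="\t", header=None)[0].to_numpy()
    return None


def filter_genes(counts, max_zero_prop: float = 0.9):
    """Drop genes whose zero fraction strictly exceeds `max_zero_prop`."""
    if not 0.0 < max_zero_prop <= 1.0:
        raise ValueError("max_zero_prop must lie in (0, 1]")
    X, cells, genes = _coerce_counts(counts)
    zero_frac = (X == 0).mean(axis=0)
    keep = zero_frac <= max_zero_prop
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    if isinstance(counts, pd.DataFrame):
        return counts.loc[:, keep]
    if hasattr(counts, "var_names"):
        return counts[:, np.flatnonzero(keep)].copy()
    return np.asarray(counts)[:, keep]


def _coerce_counts(counts):
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(float), np.asarray(counts.index), np.asarray(counts.columns)
    if hasattr(counts, "X"):
        X = counts.X
        if hasattr(X, "todense"):
            X = np.asarray(X.todense())
        return np.asarray(X, float), np.asarray(counts.obs_names), np.asarray(counts.var_names)
    if hasattr(counts, "counts"):
        return (
            np.asarray(counts.counts, float),
            np.asarray(counts.cell_ids),
            np.asarray(counts.gene_ids),
        )
    X = np.asarray(counts, float)
    return (
        X,
        np.array([f"cell_{i}" for i in range(X.shape[0])]),
        np.array([f"gene_{j}" for j in range(X.shape[1])]),
    )


class PseudotimeDE(BaseEstimator):
    """Differential-expression test along pseudotime with uncertainty
    propagation.

    Parameters mirror :class:`RunConfig`. `pseudotime_method` is 'builtin'
    (principal-component pseudotime) or any callable mapping a cells-by-genes
    count matrix to one raw pseudotime value per cell; it is re-run on every
    cell subsample. With `fixed=True` the inferred pseudotime is treated as
    fixed and an asymptotic p-value replaces the permutation null.

    After `fit`, `results_` holds the per-gene table (statistic, empirical,
    parametric and/or asymptotic p-values, BH-adjusted p), `draws_` the
    subsample pseudotime realizations, and `uncertainty_` the per-cell
    pseudotime uncertainty summary.
    """

    def __init__(
        self,
        B: int = 1000,
        fraction: float = 0.8,
        knots: int = 6,
        model: str = "auto",
        aic_delta: float = 10.0,
        lrt_alpha: float = 0.01,
        zero_filter: float = 0.9,
        fixed: bool = False,
        pseudotime_method="builtin",
        min_usable: int = 50,
        compute_gof: bool = False,
        seed: int = 0,
        n_workers: int = 1,
    ):
        self.B = B
        self.fraction = fraction
        self.knots = knots
        self.model = model
        self.aic_delta = aic_delta
        self.lrt_alpha = lrt_alpha
        self.zero_filter = zero_filter
        self.fixed = fixed
        self.pseudotime_method = pseudotime_method
        self.min_usable = min_usable
        self.compute_gof = compute_gof
        self.seed = seed
        self.n_workers = n_workers

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None, pseudotime=None, groups=None, draws=None):
        if self.model not in ("auto", "nb", "zinb"):
            raise ValueError("model must be 'auto', 'nb' or 'zinb'")
        Xm, cells, genes = _coerce_counts(X)

        nonzero_cells = Xm.sum(axis=1) > 0
        if not nonzero_cells.all():
            warnings.warn(
                f"dropping {int((~nonzero_cells).sum())} cells with zero total counts",
                stacklevel=2,
            )
            Xm, cells = Xm[nonzero_cells], cells[nonzero_cells]
            if pseudotime is not None:
                pseudotime = np.asarray(pseudotime, float)[nonzero_cells]
            if groups is not None:
                groups = np.asarray(groups)[nonzero_cells]

        zero_frac = (Xm == 0).mean(axis=0)
        keep = zero_frac <= self.zero_filter
        keep &= Xm.sum(axis=0) > 0
        n_dropped = int((~keep).sum())
        if not keep.any():
            raise ValueError("gene filter removed every gene")
        Xm, genes = Xm[:, keep], genes[keep]
        n, G = Xm.shape

        method = builtin_pseudotime if self.pseudotime_method == "builtin" else self.pseudotime_method
        if pseudotime is not None:
            T = normalize_pseudotime(np.asarray(pseudotime, float), cell_ids=cells)
        else:
            if not callable(method):
                raise ValueError("pseudotime_method must be 'builtin' or a callable")
            T = normalize_pseudotime(method(Xm), cell_ids=cells)

        controls = GAMControls(knots=self.knots)
        self.pseudotime_ = T
        self.cell_ids_ = cells
        self.gene_ids_ = genes
        self.n_genes_filtered_ = n_dropped

        if self.fixed:
            res = self._fit_fixed(Xm, T, genes, controls)
            self.draws_ = None
            self.uncertainty_ = None
        else:
            if draws is None:
                if not callable(method):
                    raise ValueError(
                        "subsampling mode needs a pseudotime callable or precomputed draws"
                    )
                index_sets = draw_subsamples(
                    n, self.fraction, self.B, groups=groups, seed=self.seed
                )
                draws = infer_subsample_pseudotime(
                    Xm, index_sets, method, original=T, min_usable=self.min_usable
                )
            if draws.original is None:
                draws.original = T
            draws = permute_pseudotime(draws, seed=self.seed)
            self.draws_ = draws
            res = self._fit_permutation(Xm, T, genes, draws, controls)
            self.uncertainty_ = uncertainty_summary(draws, cell_ids=cells)

        self.results_ = res
        self.manifest_ = self._manifest(n, G)
        return self

    # ------------------------------------------------- observed-data fitting
    def _observed_fits(self, Xm, basis, controls):
        """NB (and, per mode, ZINB) batch fits plus the per-gene selection."""
        n, G = Xm.shape
        nb = fit_nb_batch(Xm, basis, controls)
        flavors = np.full(G, "nb", dtype=object)
        zinb = None
        if self.model in ("auto", "zinb"):
            has_zero = (Xm == 0).any(axis=0)
            idx = np.flatnonzero(has_zero)
            if idx.size:
                sub_nb = _subset_batch(nb, idx)
                zinb = fit_zinb_batch(Xm[:, idx], basis, controls, nb_init=sub_nb)
                if self.model == "zinb":
                    chosen = zinb.converged
                else:
                    chosen = zinb.converged & (nb.aic[idx] - zinb.aic >= self.aic_delta)
                flavors[idx[chosen]] = "zinb"
                self._zinb_idx = idx
            else:
                self._zinb_idx = np.empty(0, int)
        s_nb, r_nb = compute_statistics_batch(nb, basis)
        stat, rank = s_nb.copy(), r_nb.copy()
        conv = nb.converged.copy()
        models = flavors.copy()
        if zinb is not None:
            s_z, r_z = compute_statistics_batch(zinb, basis)
            for k, j in enumerate(self._zinb_idx):
                if flavors[j] == "zinb":
                    stat[j], rank[j], conv[j] = s_z[k], r_z[k], zinb.converged[k]
        return nb, zinb, models, stat, rank, conv

    def _fit_fixed(self, Xm, T, genes, controls):
        from scipy.stats import chi2

        basis = build_spline_basis(T.values, self.knots)
        nb, zinb, models, stat, rank, conv = self._observed_fits(Xm, basis, controls)
        ws, wdf = wood_test_batch(nb, basis)
        if zinb is not None:
            ws_z, wdf_z = wood_test_batch(zinb, basis)
            for k, j in enumerate(self._zinb_idx):
                if models[j] == "zinb":
                    ws[j], wdf[j] = ws_z[k], wdf_z[k]
        p_asym = chi2.sf(ws, np.maximum(wdf, 1.0))
        return pd.DataFrame(
            {
                "gene": genes,
                "statistic": stat,
                "rank": rank,
                "model": models,
                "B_used": 0,
                "p_emp": np.nan,
                "p_param": np.nan,
                "p_asymptotic": p_asym,
                "padj_param": bh_adjust(p_asym),
                "null_model": "asymptotic",
                "gof_p": np.nan,
                "converged": conv,
            }
        )

    def _fit_permutation(self, Xm, T, genes, draws, controls):
        basis = build_spline_basis(T.values, self.knots)
        nb, zinb, models, stat, rank, conv = self._observed_fits(Xm, basis, controls)
        null_mat = _null_matrix(
            Xm, draws, models, controls, n_workers=self.n_workers
        )
        self.null_statistics_ = null_mat
        G = Xm.shape[1]
        p_emp = np.full(G, np.nan)
        p_param = np.full(G, np.nan)
        null_model = np.full(G, "empirical_only", dtype=object)
        gof = np.full(G, np.nan)
        b_used = np.zeros(G, int)
        for j in range(G):
            nulls = null_mat[:, j]
            nulls = nulls[np.isfinite(nulls)]
            b_used[j] = nulls.size
            if nulls.size < min(self.min_usable, null_mat.shape[0]) or not np.isfinite(stat[j]):
                continue
            p_emp[j] = empirical_pvalue(stat[j], nulls)
            nf = fit_parametric_null(
                nulls,
                lrt_alpha=self.lrt_alpha,
                min_values=min(self.min_usable, null_mat.shape[0]),
                compute_gof=self.compute_gof,
                seed=self.seed,
            )
            null_model[j] = nf.chosen
            gof[j] = nf.gof_p
            try:
                p_param[j] = parametric_pvalue(stat[j], nf)
            except ParametricUnavailableError:
                pass
        return pd.DataFrame(
            {
                "gene": genes,
                "statistic": stat,
                "rank": rank,
                "model": models,
                "B_used": b_used,
                "p_emp": p_emp,
                "p_param": p_param,
                "p_asymptotic": np.nan,
                "padj_param": bh_adjust(p_param),
                "null_model": null_model,
                "gof_p": gof,
                "converged": conv,
            }
        )

    def _manifest(self, n, G):
        import pseudode

        return {
            "package_version": getattr(pseudode, "__version__", "0"),
            "numpy_version": np.__version__,
            "params": {k: v for k, v in self.get_params().items() if not callable(v)},
            "n_cells": int(n),
            "n_genes_tested": int(G),
            "n_genes_filtered": int(self.n_genes_filtered_),
            "B_usable": None if self.draws_ is None else int(self.draws_.n_usable),
            "seed": int(self.seed),
        }


def _subset_batch(batch, idx):
    """View of a BatchFit restricted to a gene subset (for ZINB warm starts)."""
    from dataclasses import replace

    return replace(
        batch,
        beta=batch.beta[idx],
        eta=batch.eta[:, idx],
        mu=batch.mu[:, idx],
        phi=batch.phi[idx],
        lam=batch.lam[idx],
        edf=batch.edf[idx],
        edf_smooth=batch.edf_smooth[idx],
        loglik=batch.loglik[idx],
        aic=batch.aic[idx],
        Vb=batch.Vb[idx],
        converged=batch.converged[idx],
    )


def _null_one_subsample(Xm, sub, models, controls):
    """Null statistics for every gene on one permuted subsample."""
    G = Xm.shape[1]
    row = np.full(G, np.nan)
    ysub = Xm[sub.indices]
    basis = build_spline_basis(sub.permuted.values, controls.knots)
    valid = ysub.sum(axis=0) > 0
    is_z = (models == "zinb") & valid & (ysub == 0).any(axis=0)
    is_nb = valid & ~is_z
    for mask, flavor in ((is_nb, "nb"), (is_z, "zinb")):
        idx = np.flatnonzero(mask)
        if not idx.size:
            continue
        try:
            nbfit = fit_nb_batch(ysub[:, idx], basis, controls)
            fit = nbfit if flavor == "nb" else fit_zinb_batch(
                ysub[:, idx], basis, controls, nb_init=nbfit
            )
            s, _ = compute_statistics_batch(fit, basis)
            row[idx] = s
        except Exception:
            pass
    return row


def _null_matrix(Xm, draws, models, controls, n_workers=1):
    usable = draws.usable()
    if n_workers and n_workers > 1:
        rows = Parallel(n_jobs=n_workers)(
            delayed(_null_one_subsample)(Xm, sub, models, controls) for sub in usable
        )
    else:
        rows = [_null_one_subsample(Xm, sub, models, controls) for sub in usable]
    return np.vstack(rows) if rows else np.empty((0, Xm.shape[1]))


def write_results(table: pd.DataFrame, path) -> None:
    """Write the per-gene result table as TSV (missing p-values as 'NA')."""
    if table.empty:
        raise ValueError("refusing to write an empty result table")
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def run_pseudotimede(config: RunConfig) -> pd.DataFrame:
    """Run the full workflow from a RunConfig; write outputs if requested."""
    counts = read_counts(config.counts_path, config.orientation)
    groups = None
    if config.groups_path:
        groups = pd.read_csv(config.groups_path, sep="\t", header=None)[0].to_numpy()

    pseudotime = None
    draws = None
    method = "builtin"
    if config.pseudotime_source != "builtin":
        pt = pd.read_csv(config.pseudotime_source, sep="\t", header=None)
        pseudotime = pt[pt.columns[-1]].to_numpy(float)
    est = PseudotimeDE(
        B=config.B,
        fraction=config.fraction,
        knots=config.knots,
        model=config.model,
        aic_delta=config.aic_delta,
        lrt_alpha=config.lrt_alpha,
        zero_filter=config.zero_filter,
        fixed=config.fixed_mode,
        pseudotime_method=method,
        min_usable=config.min_usable,
        compute_gof=config.compute_gof,
        seed=config.seed,
        n_workers=config.n_workers,
    )
    if config.subsample_pseudotime_path and not config.fixed_mode:
        Xm, cells, _ = _coerce_counts(counts)
        index_sets = draw_subsamples(
            Xm.shape[0], config.fraction, config.B, groups=groups, seed=config.seed
        )
        draws = load_subsample_pseudotime(
            config.subsample_pseudotime_path, index_sets, cells
        )
    est.fit(counts, pseudotime=pseudotime, groups=groups, draws=draws)
    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        write_results(est.results_, os.path.join(config.output_dir, "results.tsv"))
        if est.uncertainty_ is not None:
            est.uncertainty_.to_csv(
                os.path.join(config.output_dir, "uncertainty.tsv"),
                sep="\t", index=False, na_rep="NA",
            )
        with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
            json.dump(est.manifest_, fh, indent=2, default=str)
    return est.results_
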