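"""Cis expression-quantitative-trait-methylation (eQTM) association.

Each CHIP-associated CpG is tested against every transcript whose TSS lies
within a cis window (default 1 Mb, boundary inclusive) on the same
chromosome. Following standard eQTM practice, both expression and
methylation are first residualized on technical/biological covariates
(supplied as precomputed columns — e.g. age, sex, cell counts, expression
and methylation PCs); the association is then a simple regression of the
expression residual on the methylation residual, with a two-sided p-value
from the t distribution on the residual degrees of freedom.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateInputError(ValueError):
    pass


def residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residual of y after least-squares projection onto the covariates.

    The covariate matrix must include an intercept column (or span one)
    and be full rank. Residuals are orthogonal to every covariate column.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateInputError("covariate matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def enumerate_cis_pairs(
    cpgs: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """All (CpG, gene) pairs with |cpg_position − TSS| ≤ window, same
    chromosome.

    ``cpgs`` needs columns probe_id, chromosome, position; ``genes`` needs
    gene_id (or gene_symbol), chromosome, tss. The boundary is inclusive.
    Output is ordered by (chromosome, position, gene_id).
    """
    g = genes.rename(columns={"gene_symbol": "gene_id"}) \
        if "gene_id" not in genes.columns else genes
    merged = cpgs.merge(
        g[["gene_id", "chromosome", "tss"]], on="chromosome", how="inner"
    )
    merged["distance_bp"] = (merged["position"] - merged["tss"]).abs()
    pairs = merged[merged["distance_bp"] <= window_bp]
    return (
        pairs[["probe_id", "gene_id", "chromosome", "position", "distance_bp"]]
        .sort_values(["chromosome", "position", "gene_id"], kind="stable")
        .reset_index(drop=True)
    )


def eqtm_assoc(
    resid_expression: np.ndarray, resid_methylation: np.ndarray
) -> tuple[float, float, float]:
    """Slope, SE and two-sided p of expression residual on methylation
    residual (with intercept). P-values come from the t distribution with
    n − 2 df; a perfect fit is reported with p at the floating-point floor.
    """
    e = np.asarray(resid_expression, dtype=float)
    m = np.asarray(resid_methylation, dtype=float)
    if e.shape != m.shape or e.ndim != 1:
        raise ValueError("expression and methylation must be equal-length vectors")
    if e.size <= 2:
        raise DegenerateInputError("need n > 2 samples")
    if np.ptp(m) == 0:
        raise DegenerateInputError("methylation residual is constant")
    res = stats.linregress(m, e)
    p = res.pvalue if np.isfinite(res.pvalue) else np.nextafter(0, 1)
    return float(res.slope), float(res.stderr), float(max(p, np.nextafter(0, 1)))


def run_eqtm(
    expression: pd.DataFrame,
    methylation: pd.DataFrame,
    covariates: pd.DataFrame,
    cpg_annotations: pd.DataFrame,
    gene_annotations: pd.DataFrame,
    window_bp: int = 1_000_000,
    probe_subset: Optional[set] = None,
) -> pd.DataFrame:
    """Full cis-eQTM scan.

    ``expression`` (samples × genes) and ``methylation`` (samples ×
    probes) must share a sample index with ``covariates``. Returns one row
    per tested cis pair with beta_eqtm, se, p.
    """
    X = np.column_stack(
        [np.ones(len(covariates)), covariates.to_numpy(dtype=float)]
    )
    pairs = enumerate_cis_pairs(cpg_annotations, gene_annotations, window_bp)
    if probe_subset is not None:
        pairs = pairs[pairs["probe_id"].isin(probe_subset)]

    resid_m = {
        pid: residualize(methylation[pid].to_numpy(), X)
        for pid in pairs["probe_id"].unique()
        if pid in methylation.columns
    }
    resid_e = {
        gid: residualize(expression[gid].to_numpy(), X)
        for gid in pairs["gene_id"].unique()
        if gid in expression.columns
    }
    rows = []
    for r in pairs.itertuples():
        if r.probe_id not in resid_m or r.gene_id not in resid_e:
            continue
        beta, se, p = eqtm_assoc(resid_e[r.gene_id], resid_m[r.probe_id])
        rows.append(
            dict(probe_id=r.probe_id, gene_id=r.gene_id,
                 distance_bp=int(r.distance_bp), beta_eqtm=beta, se=se, p=p)
        )
    return pd.DataFrame(rows)
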