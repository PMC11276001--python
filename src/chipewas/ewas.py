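"""Cohort-level EWAS: per-CpG regression of methylation on CHIP status.

Each CpG's methylation beta value (in [0, 1]) is regressed on CHIP carrier
status plus covariates by ordinary least squares. Family relatedness is
handled with an optional cluster-robust (CR1 sandwich) standard error with
cluster = family, a deliberate simplification of a full mixed model that
preserves the fixed-effect estimate. P-values are two-sided from the t
distribution (residual df; cluster-robust uses n_clusters − 1 df).

Genomic-control inflation λ is the median association χ² divided by the
median of the χ²₁ distribution; when λ exceeds a threshold (default 1.5)
each probe's χ² is deflated by λ (equivalently SE × √λ) before
meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CohortEwasRecord, PipelineConfig

# Exact median of the chi-square distribution with 1 df. Commonly quoted
# rounded as 0.456; the exact value makes λ = 1 hold identically when the
# median p is 0.5.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


class DegenerateDesignError(ValueError):
    """The design cannot identify the CHIP effect (no cases/controls, or
    zero residual variance)."""


class CollinearityError(ValueError):
    """The covariate matrix is rank deficient."""


@dataclass
class EwasRunSummary:
    cohort_id: str
    stratum: str
    n_cases: int
    n_controls: int
    n_probes_tested: int
    lambda_gc: float
    gc_applied: bool


def _design_matrix(
    chip_status: np.ndarray, covariates: Optional[np.ndarray]
) -> np.ndarray:
    n = len(chip_status)
    cols = [np.ones(n), np.asarray(chip_status, dtype=float)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(j)
            r = rj
        raise CollinearityError(
            f"design matrix rank deficient; dependent column indices {bad} "
            "(0 = intercept, 1 = chip_status, 2.. = covariates)"
        )
    return X


def _ols_many(
    X: np.ndarray,
    Y: np.ndarray,
    cluster_id: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least squares of each column of Y on X; effect = coefficient of
    column 1 (chip status). Returns (beta, se, p) arrays of length Y.shape[1].
    """
    n, k = X.shape
    if n <= k:
        raise DegenerateDesignError(f"n = {n} <= parameters = {k}")
    XtX_inv = np.linalg.inv(X.T @ X)
    C = XtX_inv @ X.T                      # k × n projection onto coefficients
    B = C @ Y                              # k × P coefficients
    E = Y - X @ B                          # n × P residuals
    beta = B[1]

    if cluster_id is None:
        dof = n - k
        sigma2 = np.einsum("ij,ij->j", E, E) / dof
        se = np.sqrt(XtX_inv[1, 1] * sigma2)
    else:
        cluster_id = np.asarray(cluster_id)
        groups, inv = np.unique(cluster_id, return_inverse=True)
        g = len(groups)
        if g < 2:
            raise DegenerateDesignError("cluster-robust SE needs >= 2 clusters")
        # CR1 sandwich for the chip coefficient: var = Σ_g (c₁ · e_g)²
        # where c₁ is the chip row of (XᵀX)⁻¹Xᵀ, with the usual small-sample
        # scaling g/(g-1) · (n-1)/(n-k).
        U = C[1][:, None] * E              # n × P
        S = np.zeros((g, U.shape[1]))
        np.add.at(S, inv, U)
        scale = (g / (g - 1)) * ((n - 1) / (n - k))
        se = np.sqrt(scale * np.einsum("ij,ij->j", S, S))
        dof = g - 1

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return beta, se, p


def fit_cpg_association(
    methylation: np.ndarray,
    chip_status: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    cluster_id: Optional[np.ndarray] = None,
) -> tuple[float, float, float]:
    """Association of one CpG's methylation with CHIP status.

    Returns (beta, se, p) for the chip_status coefficient of the least
    squares fit of methylation on [intercept, chip_status, covariates].

    Raises
    ------
    DegenerateDesignError
        if there are no cases or no controls, or the fit leaves zero
        residual variance (se would be 0).
    CollinearityError
        if the design is rank deficient.
    """
    y = np.asarray(methylation, dtype=float)
    x = np.asarray(chip_status, dtype=float)
    n_cases = int(np.sum(x == 1))
    if n_cases == 0 or n_cases == len(x):
        raise DegenerateDesignError(
            f"need >= 1 case and >= 1 control, got {n_cases} cases of {len(x)}"
        )
    X = _design_matrix(x, covariates)
    beta, se, p = _ols_many(X, y[:, None], cluster_id)
    if not np.isfinite(se[0]) or se[0] <= 0:
        raise DegenerateDesignError(
            "zero residual variance (perfect fit); se undefined"
        )
    return float(beta[0]), float(se[0]), float(p[0])


def genomic_lambda(
    p_values: np.ndarray, median_const: float = CHI2_1_MEDIAN
) -> float:
    """Genomic-control inflation factor λ.

    λ = median(χ²₁ quantile transform of p) / median(χ²₁). Calibrated
    p-values give λ ≈ 1; λ > 1 signals inflation.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("genomic_lambda: empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("genomic_lambda: p-values must be in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / median_const)


def gc_correct(
    records: Sequence[CohortEwasRecord], lambda_gc: float
) -> list[CohortEwasRecord]:
    """Genomic-control correction: divide each probe's χ² by λ.

    Equivalent to scaling SE by √λ; betas are unchanged and p-values are
    recomputed from the deflated statistic (χ²₁ reference). λ ≤ 1 is a
    no-op (returned unchanged).
    """
    if lambda_gc <= 1:
        return list(records)
    root = np.sqrt(lambda_gc)
    out = []
    for r in records:
        se_new = r.se * root
        chi2_new = (r.beta / se_new) ** 2
        p_new = float(np.clip(stats.chi2.sf(chi2_new, df=1), np.nextafter(0, 1), 1.0))
        out.append(replace(r, se=se_new, p=p_new))
    return out


_DRIVER_EXPOSURES = ("DNMT3A", "TET2", "ASXL1")


def run_ewas(
    methylation: pd.DataFrame,
    phenotypes: pd.DataFrame,
    exposure: str = "any_chip",
    covariate_columns: Optional[Sequence[str]] = None,
    cluster_column: Optional[str] = None,
    config: Optional[PipelineConfig] = None,
    cohort_id: str = "cohort",
    stratum: str = "pooled",
    min_vaf: Optional[float] = None,
) -> tuple[list[CohortEwasRecord], EwasRunSummary]:
    """EWAS of every probe in ``methylation`` against a CHIP exposure.

    Parameters
    ----------
    methylation
        samples × probes DataFrame of beta values, index = sample_id.
    phenotypes
        one row per sample with columns ``sample_id``, ``any_chip``,
        ``driver_gene``, ``vaf`` plus covariates.
    exposure
        ``any_chip`` or one of the driver genes. For a driver-gene
        exposure, cases carry that driver and carriers of other drivers
        are excluded from the controls.
    min_vaf
        if set, CHIP carriers below this VAF are excluded (sensitivity
        analysis mirroring the VAF ≥ 10% re-analysis).
    """
    config = config or PipelineConfig()
    pheno = phenotypes.set_index("sample_id").loc[methylation.index]

    chip = pheno["any_chip"].astype(bool).to_numpy()
    if exposure == "any_chip":
        case = chip
        keep = np.ones(len(pheno), dtype=bool)
    elif exposure in _DRIVER_EXPOSURES:
        driver = pheno["driver_gene"].fillna("").to_numpy()
        case = chip & (driver == exposure)
        keep = case | ~chip           # exclude carriers of other drivers
    else:
        raise ValueError(f"unknown exposure {exposure!r}")
    if min_vaf is not None:
        keep &= ~(case & (pheno["vaf"].to_numpy() < min_vaf))

    case = case[keep]
    n_cases, n_controls = int(case.sum()), int((~case).sum())
    if n_cases < 2:
        raise DegenerateDesignError(
            f"exposure {exposure!r}: {n_cases} case(s) after exclusions; "
            "need >= 2"
        )

    Y = methylation.to_numpy(dtype=float)[keep]
    cov = (
        pheno.loc[keep, list(covariate_columns)].to_numpy(dtype=float)
        if covariate_columns
        else None
    )
    clusters = (
        pheno.loc[keep, cluster_column].to_numpy() if cluster_column else None
    )
    X = _design_matrix(case.astype(float), cov)
    beta, se, p = _ols_many(X, Y, clusters)

    lam = genomic_lambda(p)
    n = int(keep.sum())
    records = [
        CohortEwasRecord(
            probe_id=str(pid), cohort_id=cohort_id, stratum=stratum,
            beta=float(b), se=float(s), p=float(pv), n=n,
        )
        for pid, b, s, pv in zip(methylation.columns, beta, se, p)
    ]
    gc_applied = lam > config.lambda_correction_threshold
    if gc_applied:
        records = gc_correct(records, lam)
    summary = EwasRunSummary(
        cohort_id=cohort_id,
        stratum=stratum,
        n_cases=n_cases,
        n_controls=n_controls,
        n_probes_tested=len(records),
        lambda_gc=lam,
        gc_applied=gc_applied,
    )
    return records, summary
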