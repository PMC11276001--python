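"""Two-sample Mendelian randomization of CpG methylation on outcomes.

Exposures are CHIP-associated CpGs instrumented by cis-mQTLs (SNPs within
1 Mb of the CpG, association p below a stringent ceiling, default 2e-11).
Per CpG, instruments are pruned for linkage disequilibrium by a greedy
best-p-first rule at r² < 0.01; a single surviving instrument gives a Wald
ratio (β_Y/β_X), two or more give the fixed-effect inverse-variance
weighted (IVW) estimate, which equals the precision-weighted mean of the
per-instrument Wald ratios with weights β_Xᵢ²/se_Yᵢ². Instrument validity
is screened with Cochran's Q heterogeneity (≥ 2 IVs) and the MR-Egger
intercept (≥ 3 IVs, a weighted regression of β_Y on β_X whose intercept
captures directional pleiotropy); estimates failing either screen at
p < 0.05 are excluded rather than corrected. Benjamini-Hochberg FDR is
applied within each outcome.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import PipelineConfig
from .meta import bh_fdr


class LdSource:
    """Pairwise LD (r²) lookup from a genotype dosage matrix or a
    precomputed r² table.

    Genotype dialect: DataFrame of diploid dosages {0,1,2}, samples ×
    SNPs; r² is the squared Pearson correlation of dosages. Table
    dialect: DataFrame with columns snp_a, snp_b, r2 (symmetric pairs
    need appear once; missing pairs default to 0).
    """

    def __init__(self, source: pd.DataFrame, kind: str = "genotypes"):
        if kind == "genotypes":
            self._geno = source
            self._table = None
        elif kind == "r2_table":
            self._geno = None
            self._table = {}
            for r in source.itertuples():
                self._table[frozenset((r.snp_a, r.snp_b))] = float(r.r2)
        else:
            raise ValueError(f"unknown LD source kind {kind!r}")

    def __contains__(self, snp_id: str) -> bool:
        if self._geno is not None:
            return snp_id in self._geno.columns
        return any(snp_id in pair for pair in self._table)

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        if self._geno is not None:
            a = self._geno[snp_a].to_numpy(dtype=float)
            b = self._geno[snp_b].to_numpy(dtype=float)
            if np.std(a) == 0 or np.std(b) == 0:
                return 0.0
            return float(np.corrcoef(a, b)[0, 1] ** 2)
        return self._table.get(frozenset((snp_a, snp_b)), 0.0)


def harmonize(
    mqtl: pd.DataFrame, outcome: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Align exposure and outcome summary statistics on shared SNPs.

    When the two sides state different effect alleles the outcome beta's
    sign is flipped; SNPs whose outcome allele matches neither stated
    exposure allele (when an ``other_allele`` column is present) or is
    simply different with no flip possible are dropped. Returns the
    aligned table and the number of dropped SNPs.
    """
    merged = mqtl.merge(
        outcome, on="snp_id", suffixes=("_x_tab", "_y_tab"), how="inner"
    )
    ea_x = merged["effect_allele_x_tab"].str.upper()
    ea_y = merged["effect_allele_y_tab"].str.upper()
    same = ea_x == ea_y
    if "other_allele" in merged.columns:
        flip = merged["other_allele"].str.upper() == ea_y
    else:
        # without the complementary allele stated, any mismatch is a swap
        flip = ~same
    resolvable = same | flip
    n_dropped = int((~resolvable).sum())
    out = merged[resolvable].copy()
    out.loc[flip[resolvable], "beta_y"] = -out.loc[flip[resolvable], "beta_y"]
    out["effect_allele"] = ea_x[resolvable]
    return (
        out[["snp_id", "probe_id", "beta_x", "se_x", "p_x",
             "beta_y", "se_y", "effect_allele"]],
        n_dropped,
    )


def select_ivs(
    mqtls: pd.DataFrame,
    ld_source: LdSource,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Greedy LD pruning of candidate instruments for one CpG.

    Candidates are sorted by ascending mQTL p (ties: larger |beta_x|,
    then snp_id); a SNP is accepted iff its r² with every
    already-accepted SNP is below the threshold (default 0.01), so each
    LD block contributes only its lowest-p variant. SNPs absent from the
    LD source are dropped.
    """
    config = config or PipelineConfig()
    cand = mqtls[mqtls["p_x"] <= config.mqtl_p_max].copy()
    cand["_abs_beta"] = -cand["beta_x"].abs()
    cand = cand.sort_values(["p_x", "_abs_beta", "snp_id"], kind="stable")
    kept: list[int] = []
    kept_ids: list[str] = []
    for idx, snp in zip(cand.index, cand["snp_id"]):
        if snp not in ld_source:
            continue
        if all(ld_source.r2(snp, other) < config.ld_r2_max for other in kept_ids):
            kept.append(idx)
            kept_ids.append(snp)
    return cand.loc[kept].drop(columns="_abs_beta")


def wald_ratio(
    beta_x: float, se_x: float, beta_y: float, se_y: float
) -> tuple[float, float, float]:
    """Single-instrument Wald estimate β_Y/β_X with first-order delta SE
    se_Y/|β_X| and a two-sided normal p-value."""
    del se_x  # first-order approximation ignores exposure uncertainty
    if beta_x == 0:
        raise ZeroDivisionError("wald_ratio: beta_x = 0, ratio undefined")
    beta_mr = beta_y / beta_x
    se_mr = se_y / abs(beta_x)
    z = beta_mr / se_mr
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return beta_mr, se_mr, max(p, np.nextafter(0, 1))


def ivw_mr(ivs: pd.DataFrame) -> tuple[float, float, float]:
    """Fixed-effect IVW estimate over ≥ 2 instruments.

    β_MR = Σ β_Xᵢβ_Yᵢ/se_Yᵢ² / Σ β_Xᵢ²/se_Yᵢ², se = 1/√(Σ β_Xᵢ²/se_Yᵢ²).
    """
    bx = ivs["beta_x"].to_numpy(dtype=float)
    by = ivs["beta_y"].to_numpy(dtype=float)
    sy = ivs["se_y"].to_numpy(dtype=float)
    if len(bx) < 2:
        raise ValueError("ivw_mr: need >= 2 instruments (use wald_ratio)")
    if np.any(sy <= 0):
        raise ValueError("ivw_mr: all se_y must be > 0")
    w = bx**2 / sy**2
    beta_mr = float(np.sum(bx * by / sy**2) / np.sum(w))
    se_mr = float(1.0 / np.sqrt(np.sum(w)))
    z = beta_mr / se_mr
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return beta_mr, se_mr, max(p, np.nextafter(0, 1))


def egger_regression(ivs: pd.DataFrame) -> tuple[float, float, float]:
    """MR-Egger: weighted regression of β_Y on β_X with intercept.

    Instruments are first oriented so every β_X > 0 (flipping β_Y with
    it), the standard Egger convention. Weights are 1/se_Y². Returns
    (intercept, slope, p_intercept), p from t with n_iv − 2 df.
    """
    bx = ivs["beta_x"].to_numpy(dtype=float).copy()
    by = ivs["beta_y"].to_numpy(dtype=float).copy()
    sy = ivs["se_y"].to_numpy(dtype=float)
    if len(bx) < 3:
        raise ValueError("egger_regression: need >= 3 instruments")
    flip = bx < 0
    bx[flip], by[flip] = -bx[flip], -by[flip]
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, WX.T @ by)
    resid = by - X @ coef
    df = len(bx) - 2
    if df == 1 and np.allclose(resid, 0, atol=1e-12):
        sigma2 = 0.0
    else:
        sigma2 = float(np.sum(w * resid**2) / df)
    cov = sigma2 * np.linalg.inv(XtWX)
    se_int = float(np.sqrt(max(cov[0, 0], 0.0)))
    if se_int == 0:
        p_int = 0.0 if coef[0] != 0 else 1.0
    else:
        p_int = float(2.0 * stats.t.sf(abs(coef[0]) / se_int, df=df))
    return float(coef[0]), float(coef[1]), min(max(p_int, np.nextafter(0, 1)), 1.0)


def iv_heterogeneity(ivs: pd.DataFrame, beta_mr: float) -> tuple[float, float]:
    """Cochran's Q over per-instrument Wald ratios with IVW weights
    β_Xᵢ²/se_Yᵢ²; p from χ² with n_iv − 1 df."""
    bx = ivs["beta_x"].to_numpy(dtype=float)
    by = ivs["beta_y"].to_numpy(dtype=float)
    sy = ivs["se_y"].to_numpy(dtype=float)
    ratios = by / bx
    w = bx**2 / sy**2
    q = float(np.sum(w * (ratios - beta_mr) ** 2))
    p = float(stats.chi2.sf(q, df=len(bx) - 1))
    return q, p


def run_mr(
    exposure_cpgs: Sequence[str],
    mqtl_table: pd.DataFrame,
    ld_source: LdSource,
    outcome_tables: dict,
    config: Optional[PipelineConfig] = None,
    fdr_scope: str = "per_outcome",
) -> pd.DataFrame:
    """MR of every exposure CpG against every outcome.

    Per (CpG, outcome): select instruments (cis/p screens + LD pruning),
    harmonize alleles, estimate (Wald for one IV, IVW otherwise), run
    heterogeneity and Egger diagnostics, exclude on diagnostic failure at
    ``config.iv_exclusion_p``, then BH-FDR over retained records (pooled
    per outcome by default, or globally with ``fdr_scope='global'``).
    """
    config = config or PipelineConfig()
    rows = []
    for outcome_name, outcome_tab in outcome_tables.items():
        for cpg in exposure_cpgs:
            cand = mqtl_table[mqtl_table["probe_id"] == cpg]
            record = dict(
                probe_id=cpg, outcome=outcome_name, method=None, n_iv=0,
                beta_mr=np.nan, se_mr=np.nan, p_mr=np.nan,
                p_het=np.nan, p_egger_intercept=np.nan,
                excluded=False, exclusion_reason="",
            )
            ivs = select_ivs(cand, ld_source, config)
            if len(ivs):
                aligned, _ = harmonize(ivs, outcome_tab)
            else:
                aligned = ivs
            if len(aligned) == 0:
                record.update(excluded=True, exclusion_reason="no instruments")
                rows.append(record)
                continue
            record["n_iv"] = len(aligned)
            if len(aligned) == 1:
                r = aligned.iloc[0]
                beta_mr, se_mr, p_mr = wald_ratio(
                    r.beta_x, r.se_x, r.beta_y, r.se_y
                )
                record.update(method="wald", beta_mr=beta_mr, se_mr=se_mr,
                              p_mr=p_mr)
            else:
                beta_mr, se_mr, p_mr = ivw_mr(aligned)
                record.update(method="ivw", beta_mr=beta_mr, se_mr=se_mr,
                              p_mr=p_mr)
                _, p_het = iv_heterogeneity(aligned, beta_mr)
                record["p_het"] = p_het
                if p_het < config.iv_exclusion_p:
                    record.update(excluded=True,
                                  exclusion_reason="heterogeneity p < threshold")
                if len(aligned) >= 3:
                    _, _, p_egger = egger_regression(aligned)
                    record["p_egger_intercept"] = p_egger
                    if p_egger < config.iv_exclusion_p and not record["excluded"]:
                        record.update(
                            excluded=True,
                            exclusion_reason="Egger intercept p < threshold",
                        )
            rows.append(record)

    results = pd.DataFrame(rows)
    results["q_fdr"] = np.nan
    retained = ~results["excluded"] & results["p_mr"].notna()
    if fdr_scope == "global":
        if retained.any():
            results.loc[retained, "q_fdr"] = bh_fdr(
                results.loc[retained, "p_mr"].to_numpy()
            )
    elif fdr_scope == "per_outcome":
        for _, idx in results.loc[retained].groupby("outcome").groups.items():
            results.loc[idx, "q_fdr"] = bh_fdr(
                results.loc[idx, "p_mr"].to_numpy()
            )
    else:
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    results["significant"] = results["q_fdr"] < config.fdr_q
    return results
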