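"""Inverse-variance fixed-effects meta-analysis and result summaries.

Cohort EWAS results are combined per CpG with inverse-variance weights
(wᵢ = 1/seᵢ²), first within race stratum, then across strata (two-stage by
default; one-stage pooling of all cohort results is available). Probes are
restricted to the intersection present in every contributing table.
Summaries reproduce the study's headline descriptive operations: direction
of effect among significant CpGs, cross-set overlap with sign concordance,
cis/trans (proximal/remote) classification around a driver gene, and
sensitivity-analysis re-identification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import PipelineConfig


@dataclass
class OverlapReport:
    set_a_name: str
    set_b_name: str
    n_a: int
    n_b: int
    n_shared: int
    n_concordant_sign: int
    percent_concordant: Optional[float]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (90.5 → 91)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def ivw_fixed_effects(
    betas: np.ndarray, ses: np.ndarray
) -> tuple[float, float, float, float]:
    """Fixed-effects inverse-variance weighted combination.

    te = Σwᵢβᵢ / Σwᵢ with wᵢ = 1/seᵢ², se_te = 1/√Σwᵢ,
    z = te/se_te, p = 2Φ(−|z|).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("ivw_fixed_effects: no studies")
    if np.any(s <= 0):
        raise ValueError("ivw_fixed_effects: all ses must be > 0")
    w = 1.0 / s**2
    te = float(np.sum(w * b) / np.sum(w))
    se_te = float(1.0 / np.sqrt(np.sum(w)))
    z = te / se_te
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return te, se_te, z, max(p, np.nextafter(0, 1))


def cochran_q(
    betas: np.ndarray, ses: np.ndarray, te: float
) -> tuple[float, int, float, float]:
    """Cochran's Q heterogeneity: Q = Σwᵢ(βᵢ − te)², df = k − 1,
    p from the χ²_df upper tail, I² = max(0, (Q − df)/Q)."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("cochran_q: need >= 2 studies")
    w = 1.0 / s**2
    q = float(np.sum(w * (b - te) ** 2))
    df = b.size - 1
    p_het = float(stats.chi2.sf(q, df=df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, df, p_het, i2


def _meta_table(frame: pd.DataFrame, study_order: Sequence[str]) -> pd.DataFrame:
    """IVW meta per probe over the given canonical study ordering.

    ``frame`` has one row per (probe_id, study) with columns probe_id,
    study, beta, se; only probes present in every study are combined.
    """
    counts = frame.groupby("probe_id")["study"].nunique()
    complete = counts.index[counts == len(study_order)]
    sub = frame[frame["probe_id"].isin(complete)].copy()
    sub["study"] = pd.Categorical(sub["study"], categories=study_order, ordered=True)
    sub = sub.sort_values(["probe_id", "study"])

    rows = []
    for pid, grp in sub.groupby("probe_id", sort=True, observed=True):
        b = grp["beta"].to_numpy()
        s = grp["se"].to_numpy()
        te, se_te, z, p = ivw_fixed_effects(b, s)
        if len(b) >= 2:
            q, qdf, _, i2 = cochran_q(b, s, te)
        else:
            q, qdf, i2 = 0.0, 0, 0.0
        direction = "".join("+" if x > 0 else "-" if x < 0 else "?" for x in b)
        rows.append(
            dict(probe_id=pid, te=te, se_te=se_te, z=z, p=p,
                 q_stat=q, q_df=qdf, i2=i2, direction=direction,
                 n_studies=len(b))
        )
    return pd.DataFrame(rows)


def stratified_meta(
    cohort_tables: dict,
    config: Optional[PipelineConfig] = None,
    two_stage: bool = True,
) -> tuple[dict, pd.DataFrame]:
    """Stratified and cross-race IVW meta-analysis.

    Parameters
    ----------
    cohort_tables
        mapping stratum -> {cohort_id -> DataFrame with probe_id, beta, se}.
    two_stage
        if True (default) the cross-race result combines the two
        stratum-level IVW estimates; if False all cohort results are pooled
        in a single IVW stage.

    Returns
    -------
    per_stratum, cross_race
        per-stratum meta tables keyed by stratum, and the cross-race table.
        Study order in direction strings is sorted (stratum, cohort_id).
    """
    del config  # thresholds applied by the summary operations, not here
    per_stratum: dict[str, pd.DataFrame] = {}
    long_frames = []
    for stratum in sorted(cohort_tables):
        cohorts = cohort_tables[stratum]
        frames = []
        for cid in sorted(cohorts):
            t = cohorts[cid][["probe_id", "beta", "se"]].copy()
            t["study"] = f"{stratum}:{cid}"
            frames.append(t)
        long = pd.concat(frames, ignore_index=True)
        long_frames.append(long)
        order = [f"{stratum}:{cid}" for cid in sorted(cohorts)]
        per_stratum[stratum] = _meta_table(long, order)
        if per_stratum[stratum].empty:
            raise ValueError(
                f"stratum {stratum!r}: empty probe intersection; per-cohort "
                f"probe counts: "
                f"{ {cid: len(t) for cid, t in cohorts.items()} }"
            )

    if two_stage:
        frames = []
        for stratum, table in per_stratum.items():
            t = table[["probe_id", "te", "se_te"]].rename(
                columns={"te": "beta", "se_te": "se"}
            )
            t["study"] = stratum
            frames.append(t)
        cross = _meta_table(
            pd.concat(frames, ignore_index=True), sorted(per_stratum)
        )
    else:
        order = sorted(
            f"{stratum}:{cid}"
            for stratum, cohorts in cohort_tables.items()
            for cid in cohorts
        )
        cross = _meta_table(pd.concat(long_frames, ignore_index=True), order)
    if cross.empty:
        raise ValueError(
            "cross-race meta: empty probe intersection; per-stratum probe "
            f"counts: { {s: len(t) for s, t in per_stratum.items()} }"
        )
    return per_stratum, cross


def significance_thresholds(
    config: Optional[PipelineConfig] = None,
) -> tuple[float, float]:
    """Epigenome-wide Bonferroni threshold (α / n_probes) and FDR level."""
    config = config or PipelineConfig()
    return config.bonferroni_p, config.fdr_q


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q(i) = min over j ≥ i (sorted order) of m·p(j)/j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("bh_fdr: p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def direction_summary(
    meta_table: pd.DataFrame, sig_threshold: float
) -> dict:
    """Direction-of-effect counts among significant CpGs (p < threshold).

    Percentages use round-half-away-from-zero; they are None when no CpG
    is significant.
    """
    sig = meta_table[meta_table["p"] < sig_threshold]
    n_sig = len(sig)
    n_neg = int((sig["te"] < 0).sum())
    n_pos = int((sig["te"] > 0).sum())
    return dict(
        n_sig=n_sig,
        n_negative=n_neg,
        n_positive=n_pos,
        percent_negative=round_half_away(100.0 * n_neg / n_sig) if n_sig else None,
        percent_positive=round_half_away(100.0 * n_pos / n_sig) if n_sig else None,
    )


def overlap_concordance(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    sig_threshold: float,
    name_a: str = "A",
    name_b: str = "B",
) -> OverlapReport:
    """Overlap of significant CpG sets with direction concordance."""
    sig_a = table_a[table_a["p"] < sig_threshold].set_index("probe_id")
    sig_b = table_b[table_b["p"] < sig_threshold].set_index("probe_id")
    shared = sig_a.index.intersection(sig_b.index)
    concordant = int(
        (np.sign(sig_a.loc[shared, "te"].to_numpy())
         == np.sign(sig_b.loc[shared, "te"].to_numpy())).sum()
    )
    return OverlapReport(
        set_a_name=name_a,
        set_b_name=name_b,
        n_a=len(sig_a),
        n_b=len(sig_b),
        n_shared=len(shared),
        n_concordant_sign=concordant,
        percent_concordant=(
            round_half_away(100.0 * concordant / len(shared))
            if len(shared) else None
        ),
    )


def cis_trans_classify(
    cpgs: pd.DataFrame, gene, window_bp: int = 1_000_000
) -> pd.Series:
    """Classify each CpG as proximal or remote relative to a driver gene.

    Distance is 0 inside [start, end], else the gap to the nearer gene
    edge; remote iff distance > window (strict) or a different chromosome.
    Returns a Series of {"proximal", "remote"} indexed by probe_id.
    """
    same_chrom = cpgs["chromosome"].to_numpy() == gene.chromosome
    pos = cpgs["position"].to_numpy()
    dist = np.where(
        pos < gene.start, gene.start - pos,
        np.where(pos > gene.end, pos - gene.end, 0),
    )
    remote = ~same_chrom | (dist > window_bp)
    return pd.Series(
        np.where(remote, "remote", "proximal"),
        index=pd.Index(cpgs["probe_id"], name="probe_id"),
    )


def sensitivity_reidentification(
    primary: pd.DataFrame, sensitivity: pd.DataFrame, threshold: float
) -> dict:
    """Compare primary vs sensitivity significant sets.

    Re-identified = significant in both; new = only in sensitivity;
    percent_reidentified is relative to the primary significant set.
    """
    sig_p = set(primary.loc[primary["p"] < threshold, "probe_id"])
    sig_s = set(sensitivity.loc[sensitivity["p"] < threshold, "probe_id"])
    n_re = len(sig_p & sig_s)
    return dict(
        n_primary=len(sig_p),
        n_sensitivity=len(sig_s),
        n_reidentified=n_re,
        n_new=len(sig_s - sig_p),
        percent_reidentified=(
            round_half_away(100.0 * n_re / len(sig_p)) if sig_p else None
        ),
    )
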