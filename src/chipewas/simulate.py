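"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design end to end: case/control cohorts
where CHIP driver mutations shift methylation at a subset of CpGs with
driver-specific direction skew (DNMT3A loss-of-function lowers
methylation, TET2 loss raises it), covariate and cell-fraction
confounding, family clustering; cis-mQTL → methylation → outcome causal
chains with optional horizontal pleiotropy for Mendelian randomization;
and replicate KO-vs-control per-CpG strand-level read counts mimicking
six-base-chemistry sequencing of engineered stem cells.

Methylation is generated on the logit scale and squashed back, so additive
effects never leave [0, 1]; effect sizes are specified in beta units and
rescaled by the local logistic slope so the realized case-control beta
difference approximates the nominal δ. Every dataset is accompanied by a
:class:`~chipewas.datamodel.SyntheticTruth` sufficient to score recovery.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .datamodel import SyntheticTruth

DRIVERS = ("DNMT3A", "TET2", "ASXL1")

# Study-like defaults: overall CHIP prevalence ≈ 5-6% of samples, DNMT3A
# the most common driver; direction skew per driver = fraction of true
# effects that are negative (hypomethylating).
DEFAULT_PREVALENCE = {"DNMT3A": 0.030, "TET2": 0.015, "ASXL1": 0.010}
DEFAULT_DIRECTION_SKEW = {"DNMT3A": 1.0, "TET2": 0.10, "ASXL1": 0.76}


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:06d}" for i in range(n)]


def simulate_cohort(
    n_samples: int = 1000,
    n_cpgs: int = 2000,
    chip_prevalence: Optional[dict] = None,
    effect_size: float = 0.05,
    causal_fraction: float = 0.05,
    direction_skew: Optional[dict] = None,
    n_families: Optional[int] = None,
    family_sd: float = 0.02,
    noise_sd: float = 0.05,
    frac_high_vaf: float = 0.5,
    rng_seed: int = 0,
    truth: Optional[SyntheticTruth] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """One cohort: methylation matrix, phenotype table, ground truth.

    Parameters
    ----------
    chip_prevalence
        driver gene -> fraction of samples carrying that driver
        (mutually exclusive carriers).
    effect_size
        |δ| in methylation-beta units at causal CpGs.
    causal_fraction
        fraction of CpGs causal per driver.
    direction_skew
        driver -> fraction of that driver's causal effects that are
        negative (DNMT3A defaults to 1.0, TET2 to 0.10).
    n_families
        if set, samples are grouped into families sharing a random
        methylation intercept of SD ``family_sd`` (beta units).
    frac_high_vaf
        fraction of carriers with variant allele frequency above 10%
        (the rest fall in [2%, 10%); drives the sensitivity analysis).
    truth
        reuse the causal-CpG assignment of an existing cohort so that
        several cohorts share one ground truth (multi-cohort meta).
    """
    rng = np.random.default_rng(rng_seed)
    prevalence = dict(DEFAULT_PREVALENCE if chip_prevalence is None else chip_prevalence)
    skew = dict(DEFAULT_DIRECTION_SKEW, **(direction_skew or {}))
    if n_families is not None and n_families > n_samples:
        raise ValueError(
            f"n_families ({n_families}) > n_samples ({n_samples})"
        )
    probes = _probe_ids(n_cpgs)

    # carrier assignment, mutually exclusive across drivers
    u = rng.random(n_samples)
    driver = np.full(n_samples, "", dtype=object)
    lo = 0.0
    for d, prev in prevalence.items():
        driver[(u >= lo) & (u < lo + prev)] = d
        lo += prev
    any_chip = driver != ""

    # covariates: age and sex confound (age also raises CHIP odds below),
    # granulocyte fraction varies between samples
    age = rng.normal(60, 10, n_samples)
    # tilt carriers older: swap in high-age non-carriers with prob ∝ age
    order = np.argsort(-(age + rng.normal(0, 20, n_samples)))
    carrier_slots = np.where(any_chip)[0]
    # reassign carriers to an age-biased subset of the same size
    biased = order[: len(carrier_slots) * 3]
    new_slots = rng.choice(biased, size=len(carrier_slots), replace=False)
    driver_new = np.full(n_samples, "", dtype=object)
    driver_new[new_slots] = driver[carrier_slots]
    driver = driver_new
    any_chip = driver != ""

    sex = rng.integers(0, 2, n_samples).astype(float)
    cf_gran = np.clip(rng.normal(0.6, 0.08, n_samples), 0.3, 0.9)
    cf_lymph = np.clip(1 - cf_gran - np.clip(rng.normal(0.1, 0.03, n_samples), 0, 0.3), 0.05, 0.7)

    vaf = np.zeros(n_samples)
    carriers = np.where(any_chip)[0]
    high = rng.random(len(carriers)) < frac_high_vaf
    vaf[carriers[high]] = rng.uniform(0.10, 0.40, high.sum())
    vaf[carriers[~high]] = rng.uniform(0.02, 0.10, (~high).sum())

    if n_families is not None:
        family = rng.integers(0, n_families, n_samples)
        fam_intercept = rng.normal(0, family_sd, n_families)[family]
    else:
        family = np.arange(n_samples)
        fam_intercept = np.zeros(n_samples)

    # ground truth: causal CpG sets with signed δ per driver
    if truth is None:
        truth = SyntheticTruth()
        available = list(range(n_cpgs))
        rng_assign = np.random.default_rng(rng_seed + 1)
        n_causal = int(round(causal_fraction * n_cpgs))
        for d in prevalence:
            if d not in DRIVERS:
                continue
            take = rng_assign.choice(available, size=min(n_causal, len(available)), replace=False)
            available = [i for i in available if i not in set(take)]
            signs = np.where(rng_assign.random(len(take)) < skew.get(d, 0.5), -1.0, 1.0)
            truth.causal_cpgs[d] = {
                probes[j]: float(s * effect_size) for j, s in zip(take, signs)
            }
        truth.confounder_loadings = {
            "age": 0.0008, "sex": 0.004, "cf_gran": 0.03, "cf_lymph": -0.02,
        }

    loads = truth.confounder_loadings
    cov_effect = (
        loads.get("age", 0) * (age - 60)
        + loads.get("sex", 0) * sex
        + loads.get("cf_gran", 0) * (cf_gran - 0.6)
        + loads.get("cf_lymph", 0) * (cf_lymph - 0.3)
    )

    # per-CpG signed effect matrix contribution for carriers
    effect = np.zeros((n_samples, n_cpgs))
    probe_index = {p: j for j, p in enumerate(probes)}
    for d, effects in truth.causal_cpgs.items():
        rows = np.where(driver == d)[0]
        if len(rows) == 0:
            continue
        for pid, delta in effects.items():
            j = probe_index.get(pid)
            if j is not None:
                effect[rows, j] += delta

    # baselines symmetric about 0.5 so logistic curvature cancels on average
    baseline = rng.uniform(0.35, 0.65, n_cpgs)
    slope = baseline * (1 - baseline)  # local logistic derivative
    noise = rng.normal(0, noise_sd, (n_samples, n_cpgs))
    beta_scale = (
        effect
        + cov_effect[:, None]
        + fam_intercept[:, None]
        + noise
    )
    eta = logit(baseline)[None, :] + beta_scale / slope[None, :]
    methylation = pd.DataFrame(
        expit(eta),
        index=pd.Index([f"s{i:05d}" for i in range(n_samples)], name="sample_id"),
        columns=probes,
    )
    phenotypes = pd.DataFrame(
        {
            "sample_id": methylation.index,
            "any_chip": any_chip,
            "driver_gene": np.where(any_chip, driver, None),
            "vaf": vaf,
            "age": age,
            "sex": sex,
            "cf_gran": cf_gran,
            "cf_lymph": cf_lymph,
            "family": family,
        }
    )
    return methylation, phenotypes, truth


def simulate_mqtl_system(
    n_cpgs: int = 20,
    ivs_per_cpg: int = 5,
    maf_range: tuple = (0.1, 0.5),
    beta_xz_range: tuple = (0.1, 0.3),
    n_ref: int = 500,
    n_linked_per_iv: int = 0,
    linked_flip_prob: float = 0.01,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cis-mQTL instruments with an LD reference panel.

    Each CpG gets ``ivs_per_cpg`` independent lead instruments; each lead
    can carry ``n_linked_per_iv`` tightly linked shadow SNPs (haplotype
    copies with per-allele flip probability ``linked_flip_prob``), giving
    within-block r² far above the 0.01 pruning threshold while
    between-block r² stays near zero. mQTL summary statistics are
    internally consistent (p = 2Φ(−|β/se|)) and all designated
    instruments pass the instrument p ceiling.

    Returns (genotypes, mqtl_table, coordinates): diploid dosage matrix
    of the LD reference (n_ref samples × SNPs), the cis-mQTL summary
    table, and SNP/CpG coordinates (all SNPs within 1 Mb of their CpG).
    """
    rng = np.random.default_rng(rng_seed)
    geno_cols: dict[str, np.ndarray] = {}
    mqtl_rows = []
    coord_rows = []
    for c in range(n_cpgs):
        probe = f"cg{c:06d}"
        cpg_pos = 2_000_000 + c * 5_000_000
        coord_rows.append(dict(id=probe, kind="cpg", chromosome="chr1", position=cpg_pos))
        for k in range(ivs_per_cpg):
            lead = f"rs{c:04d}_{k}"
            maf = rng.uniform(*maf_range)
            hap = (rng.random((n_ref, 2)) < maf).astype(float)
            geno_cols[lead] = hap.sum(axis=1)
            beta = rng.uniform(*beta_xz_range) * rng.choice([-1.0, 1.0])
            z = rng.uniform(8.0, 15.0)
            se = abs(beta) / z
            p = float(max(2.0 * stats.norm.sf(z), np.nextafter(0, 1)))
            pos = cpg_pos + int(rng.integers(-900_000, 900_000))
            mqtl_rows.append(
                dict(snp_id=lead, probe_id=probe, beta_x=beta, se_x=se,
                     p_x=p, effect_allele="A", other_allele="G",
                     chromosome="chr1", position=pos)
            )
            coord_rows.append(dict(id=lead, kind="snp", chromosome="chr1", position=pos))
            for m in range(n_linked_per_iv):
                shadow = f"rs{c:04d}_{k}s{m}"
                flips = rng.random(hap.shape) < linked_flip_prob
                shadow_hap = np.where(flips, 1 - hap, hap)
                geno_cols[shadow] = shadow_hap.sum(axis=1)
                z2 = z * rng.uniform(0.7, 0.95)  # linked SNP: weaker p than lead
                beta2 = beta * rng.uniform(0.9, 1.0)
                se2 = abs(beta2) / z2
                p2 = float(max(2.0 * stats.norm.sf(z2), np.nextafter(0, 1)))
                spos = pos + int(rng.integers(1, 5_000))
                mqtl_rows.append(
                    dict(snp_id=shadow, probe_id=probe, beta_x=beta2,
                         se_x=se2, p_x=p2, effect_allele="A",
                         other_allele="G", chromosome="chr1", position=spos)
                )
                coord_rows.append(dict(id=shadow, kind="snp", chromosome="chr1", position=spos))
    genotypes = pd.DataFrame(geno_cols)
    return genotypes, pd.DataFrame(mqtl_rows), pd.DataFrame(coord_rows)


def simulate_outcome_gwas(
    mqtl_table: pd.DataFrame,
    mr_theta,
    pleiotropy_alpha=0.0,
    se_y: float = 0.02,
    outcome: str = "trait",
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Outcome GWAS summary statistics from the standard two-sample MR
    generating model β_Y = θ·β_X + α + Normal(0, se_y).

    ``mr_theta`` is a scalar applied to every CpG or a mapping
    probe_id -> θ; ``pleiotropy_alpha`` a scalar or mapping snp_id -> α.
    Every instrument in the mQTL table appears in the output, with its
    SE stored exactly.
    """
    rng = np.random.default_rng(rng_seed)
    theta_of = (
        (lambda pid: float(mr_theta.get(pid, 0.0)))
        if isinstance(mr_theta, dict) else (lambda pid: float(mr_theta))
    )
    alpha_of = (
        (lambda snp: float(pleiotropy_alpha.get(snp, 0.0)))
        if isinstance(pleiotropy_alpha, dict) else (lambda snp: float(pleiotropy_alpha))
    )
    rows = []
    truth = SyntheticTruth()
    for r in mqtl_table.itertuples():
        theta = theta_of(r.probe_id)
        alpha = alpha_of(r.snp_id)
        truth.mr_theta[(r.probe_id, outcome)] = theta
        truth.pleiotropy_alpha[r.snp_id] = alpha
        beta_y = theta * r.beta_x + alpha + (rng.normal(0, se_y) if se_y > 0 else 0.0)
        se_store = se_y if se_y > 0 else 1e-12
        z = beta_y / se_store
        p_y = float(max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1)))
        rows.append(
            dict(snp_id=r.snp_id, outcome=outcome, beta_y=beta_y,
                 se_y=se_store, p_y=min(p_y, 1.0), effect_allele=r.effect_allele)
        )
    return pd.DataFrame(rows), truth


def simulate_evoc_counts(
    n_cpgs: int = 100,
    depth: int = 50,
    control_mc: Optional[np.ndarray] = None,
    ko_delta: float = 0.2,
    n_replicates: int = 4,
    ko_condition: str = "DNMT3A_KO",
    ewas_te: Optional[pd.Series] = None,
    sign_match_fraction: float = 1.0,
    affected_fraction: float = 1.0,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate KO-vs-control per-CpG strand-level read counts.

    Per CpG, strand, replicate and condition, mC reads are
    Binomial(depth, fraction), unmodified-C reads make up the remainder,
    and a small Poisson count of other-base reads is added (it never
    enters the mC fraction). In the KO condition an affected fraction of
    CpGs is shifted by |ko_delta|, with the shift's sign matching the
    supplied EWAS effect for a configurable fraction of affected CpGs
    (``sign_match_fraction``); without an EWAS table the sign is
    ``sign(ko_delta)`` everywhere.

    Returns (counts, site_truth) where site_truth records each CpG's
    control fraction and true KO shift.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(rng_seed)
    probes = _probe_ids(n_cpgs)
    if control_mc is None:
        base = rng.uniform(0.25, 0.75, n_cpgs)
    else:
        base = np.broadcast_to(np.asarray(control_mc, dtype=float), (n_cpgs,)).copy()
    if np.any((base < 0) | (base > 1)):
        raise ValueError("control_mc must lie in [0, 1]")

    affected = rng.random(n_cpgs) < affected_fraction
    if ewas_te is not None:
        te_signs = np.sign(ewas_te.reindex(probes).fillna(0.0).to_numpy())
        match = rng.random(n_cpgs) < sign_match_fraction
        signs = np.where(match, te_signs, -te_signs)
        signs = np.where(signs == 0, 1.0, signs)
        shift = np.where(affected, signs * abs(ko_delta), 0.0)
    else:
        shift = np.where(affected, np.sign(ko_delta) * abs(ko_delta), 0.0)
    ko_frac = np.clip(base + shift, 0.0, 1.0)
    if np.any((base + shift < 0) | (base + shift > 1)) and control_mc is not None:
        raise ValueError("control_mc + ko_delta leaves [0, 1]")

    rows = []
    for cond, frac in (("control", base), (ko_condition, ko_frac)):
        for rep in range(1, n_replicates + 1):
            for strand in ("+", "-"):
                mc = rng.binomial(depth, frac)
                other = rng.poisson(0.02 * depth, n_cpgs)
                for j, pid in enumerate(probes):
                    rows.append(
                        dict(probe_id=pid, strand=strand, condition=cond,
                             replicate=rep, reads_mc=int(mc[j]),
                             reads_c=int(depth - mc[j]),
                             reads_other=int(other[j]))
                    )
    site_truth = pd.DataFrame(
        dict(probe_id=probes, control_fraction=base, true_ko_shift=shift)
    )
    return pd.DataFrame(rows), site_truth


def simulate_multi_cohort(
    n_cohorts_per_stratum: int = 3,
    strata: Sequence[str] = ("White", "Black"),
    n_samples: int = 600,
    n_cpgs: int = 1000,
    rng_seed: int = 0,
    **cohort_kwargs,
) -> tuple[dict, SyntheticTruth]:
    """A stratified multi-cohort system sharing one ground truth.

    Returns (cohort_data, truth) where cohort_data maps
    stratum -> {cohort_id -> (methylation, phenotypes)} and every cohort
    was generated from the same causal-CpG assignment.
    """
    truth: Optional[SyntheticTruth] = None
    out: dict = {}
    seed = rng_seed
    for stratum in strata:
        out[stratum] = {}
        for c in range(n_cohorts_per_stratum):
            seed += 1
            meth, pheno, t = simulate_cohort(
                n_samples=n_samples, n_cpgs=n_cpgs, rng_seed=seed,
                truth=truth, **cohort_kwargs,
            )
            truth = truth or t
            out[stratum][f"{stratum[0]}{c + 1}"] = (meth, pheno)
    return out, truth
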