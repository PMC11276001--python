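"""Engineered-cell (CRISPR KO) concordance validation of EWAS effects.

Six-base-chemistry sequencing of edited hematopoietic stem cells yields,
per CpG and strand, counts of reads supporting modified (mC) vs unmodified
cytosine. Strand counts are summed, the mC fraction is
reads_mc / (reads_mc + reads_c) — reads calling A/T/G never enter — and
the KO effect at a CpG is the difference in mean mC fraction between KO
and control replicates, screened with a Welch t-test. Concordance with
EWAS is then a one-sided exact binomial test on the number of CpGs whose
KO methylation shift shares the sign of the meta-EWAS effect (the
"top-right / bottom-left quadrant" count), against a null of 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


MISSING_FRACTION = np.nan  # sentinel for zero informative reads


@dataclass
class QuadrantTestResult:
    n_tested: int
    n_concordant: int
    p_binomial: float
    direction: str  # enriched | depleted | none


def collapse_strands(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum forward and reverse strand read counts per CpG.

    ``counts`` has columns probe_id, strand, condition, replicate,
    reads_mc, reads_c, reads_other. Read totals are conserved.
    """
    return (
        counts.groupby(["probe_id", "condition", "replicate"], as_index=False)[
            ["reads_mc", "reads_c", "reads_other"]
        ].sum()
    )


def mc_fraction(reads_mc, reads_c):
    """Modified-cytosine fraction: mC / (mC + C); other bases excluded.

    A zero denominator yields NaN and the site is excluded downstream.
    """
    mc = np.asarray(reads_mc, dtype=float)
    c = np.asarray(reads_c, dtype=float)
    total = mc + c
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mc / np.where(total > 0, total, 1), MISSING_FRACTION)
    return frac if frac.ndim else float(frac)


def ko_effect(
    ko_fractions: np.ndarray, control_fractions: np.ndarray
) -> tuple[float, float]:
    """KO-minus-control mean mC fraction difference with a Welch t-test p.

    Zero variance in both groups gives p = 1 when the means are equal and
    p = NaN otherwise (flagged; such sites fail the screen downstream is
    the caller's decision — run_validation keeps p = NaN out).
    """
    ko = np.asarray(ko_fractions, dtype=float)
    ctrl = np.asarray(control_fractions, dtype=float)
    if ko.size < 2 or ctrl.size < 2:
        raise ValueError("need >= 2 replicates per group")
    delta = float(ko.mean() - ctrl.mean())
    if np.var(ko) == 0 and np.var(ctrl) == 0:
        p = 1.0 if delta == 0 else float("nan")
    else:
        p = float(stats.ttest_ind(ko, ctrl, equal_var=False).pvalue)
    return delta, p


def quadrant_binomial(
    deltas: np.ndarray,
    ewas_te: np.ndarray,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> QuadrantTestResult:
    """Sign-concordance binomial test between KO shifts and EWAS effects.

    Concordant pairs satisfy delta·te > 0; ties (either value exactly 0)
    are excluded from the count. The default test is the one-sided exact
    upper tail P(X ≥ k | Binomial(n, ½)) for enrichment; ``two_sided``
    switches to the exact two-sided test.
    """
    d = np.asarray(deltas, dtype=float)
    t = np.asarray(ewas_te, dtype=float)
    if d.shape != t.shape:
        raise ValueError("deltas and ewas_te must be paired vectors")
    informative = (d != 0) & (t != 0) & np.isfinite(d) & np.isfinite(t)
    d, t = d[informative], t[informative]
    n = d.size
    if n == 0:
        raise ValueError("quadrant_binomial: no informative pairs")
    k = int(np.sum(d * t > 0))
    if two_sided:
        p = float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
    else:
        p = float(stats.binom.sf(k - 1, n, 0.5))
    if k > n / 2 and p < alpha:
        direction = "enriched"
    elif k < n / 2 and float(stats.binom.cdf(k, n, 0.5)) < alpha:
        direction = "depleted"
    else:
        direction = "none"
    return QuadrantTestResult(
        n_tested=n, n_concordant=k, p_binomial=max(p, np.nextafter(0, 1)),
        direction=direction,
    )


def validate_against_ewas(
    evoc_counts: pd.DataFrame,
    meta_table: pd.DataFrame,
    ko_condition: str,
    control_condition: str = "control",
    alpha_filter: float = 0.05,
    alpha_quadrant: float = 0.05,
) -> tuple[QuadrantTestResult, pd.DataFrame]:
    """Full engineered-cell validation for one KO against one meta-EWAS.

    Pipeline: restrict to probes shared between the (pre-filtered to
    significance) meta table and the count table → collapse strands →
    per-CpG KO effect with Welch screen at ``alpha_filter`` → quadrant
    binomial test of sign concordance with the EWAS TE.

    Returns the test result and a per-site table (probe_id, delta,
    p_welch, te, passed_filter).
    """
    collapsed = collapse_strands(evoc_counts)
    collapsed["frac"] = mc_fraction(collapsed["reads_mc"], collapsed["reads_c"])
    shared = set(collapsed["probe_id"]) & set(meta_table["probe_id"])
    if not shared:
        raise ValueError("no probes shared between EvoC counts and EWAS table")
    te = meta_table.set_index("probe_id")["te"]

    rows = []
    for pid, grp in collapsed[collapsed["probe_id"].isin(shared)].groupby("probe_id"):
        ko = grp.loc[grp["condition"] == ko_condition, "frac"].dropna().to_numpy()
        ctrl = grp.loc[grp["condition"] == control_condition, "frac"].dropna().to_numpy()
        if ko.size < 2 or ctrl.size < 2:
            continue
        delta, p_welch = ko_effect(ko, ctrl)
        rows.append(
            dict(probe_id=pid, delta=delta, p_welch=p_welch,
                 te=float(te.loc[pid]),
                 passed_filter=bool(np.isfinite(p_welch) and p_welch < alpha_filter))
        )
    site_table = pd.DataFrame(rows)
    passed = site_table[site_table["passed_filter"]]
    if passed.empty:
        raise ValueError("no CpG passed the Welch-test screen")
    result = quadrant_binomial(
        passed["delta"].to_numpy(), passed["te"].to_numpy(),
        alpha=alpha_quadrant,
    )
    return result, site_table
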