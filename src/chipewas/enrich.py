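"""Trait-set enrichment of CHIP-associated CpG sets.

Each catalog trait (a set of probe IDs, e.g. smoking-associated CpGs from
an EWAS catalog export) is tested for over-representation in a query set
via the two-sided Fisher exact test on the 2×2 membership table within a
declared universe. A catalog scan applies a Bonferroni threshold α/k over
the k traits tested.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .meta import round_half_away


def fisher_enrichment(
    query: set, catalog: set, universe: set
) -> tuple[float, float, tuple[int, int, int, int]]:
    """Fisher exact enrichment of ``query`` against ``catalog``.

    Returns (odds_ratio, p_two_sided, (a, b, c, d)) where a = in both,
    b = query only, c = catalog only, d = neither. When a table cell is
    zero the odds ratio uses the Haldane–Anscombe 0.5 correction (the
    p-value is always the exact uncorrected one); a fully nested maximal
    overlap reports odds_ratio = inf.
    """
    if not query <= universe or not catalog <= universe:
        raise ValueError("query and catalog must be subsets of the universe")
    a = len(query & catalog)
    b = len(query - catalog)
    c = len(catalog - query)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        if b == 0 and c == 0 and a > 0:
            odds = math.inf
        else:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p), (a, b, c, d)


def catalog_scan(
    query: set,
    catalog: dict,
    universe: set,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Scan a query CpG set against every trait set in a catalog.

    ``catalog`` maps trait_name -> set of member IDs. Significance uses
    the Bonferroni threshold α/k (strict), with k = number of traits.
    The overlap percentage is 100·|query ∩ trait| / |query|, rounded
    half away from zero. Rows are ranked by ascending p.
    """
    if not query:
        raise ValueError("catalog_scan: empty query set")
    if not catalog:
        raise ValueError("catalog_scan: empty catalog")
    k = len(catalog)
    threshold = alpha / k
    rows = []
    for trait, members in catalog.items():
        odds, p, table = fisher_enrichment(query, members & universe, universe)
        n_overlap = table[0]
        rows.append(
            dict(
                trait_name=trait,
                n_overlap=n_overlap,
                n_trait=len(members & universe),
                odds_ratio=odds,
                p=p,
                significant=p < threshold,
                percent_of_query=round_half_away(100.0 * n_overlap / len(query)),
            )
        )
    out = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    out.attrs["bonferroni_threshold"] = threshold
    return out


def read_catalog(path, fmt: Optional[str] = None) -> dict:
    """Read a trait catalog from two-column TSV (trait_name, member_id)
    or GMT (trait, description, members...)."""
    fmt = fmt or ("gmt" if str(path).endswith(".gmt") else "tsv")
    catalog: dict[str, set] = {}
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: catalog TSV needs 2 columns")
        name_col, member_col = df.columns[:2]
        for trait, grp in df.groupby(name_col):
            catalog[str(trait)] = set(grp[member_col].astype(str))
    elif fmt == "gmt":
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    continue
                catalog[fields[0]] = set(fields[2:])
    else:
        raise ValueError(f"unknown catalog format {fmt!r}")
    return catalog
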