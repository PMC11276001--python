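"""Readers and writers for the pipeline's tabular dialects.

All tables are plain tab-separated text with a header row. BED files use the
standard 0-based half-open convention on disk and are converted to the
internal 1-based inclusive convention at this boundary: internal
``start = bed_start + 1``, ``end = bed_end``; a point coordinate (a CpG) is
a length-1 BED interval ``(pos - 1, pos)``. The conversion is a bijection on
valid intervals, so write→read round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datamodel import (
    SUMMARY_STATS_COLUMNS,
    CohortEwasRecord,
    CpGAnnotation,
    GeneRegion,
)


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class EmptyInputError(ValueError):
    """An input file holds no data rows."""


class BedFormatError(ValueError):
    """A BED line violates the interval contract (e.g. end < start)."""


@dataclass
class ReadReport:
    """What a reader kept and dropped."""

    n_read: int
    n_kept: int
    n_dropped: int


DEFAULT_SCHEMA = {c: c for c in SUMMARY_STATS_COLUMNS}


def read_summary_stats(
    path: Union[str, Path],
    schema: Optional[dict] = None,
) -> tuple[list[CohortEwasRecord], ReadReport]:
    """Read a cohort EWAS summary-statistics TSV.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    schema
        Mapping from canonical column names (``probe_id``, ``cohort``,
        ``stratum``, ``beta``, ``se``, ``p``, ``n``) to the file's column
        names. Defaults to the identity mapping.

    Returns
    -------
    records, report
        Rows with non-finite ``beta``/``se``/``p`` are dropped and counted
        in the report rather than raising.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, sep="\t", dtype={schema["probe_id"]: str})
    missing = [c for c in SUMMARY_STATS_COLUMNS if schema[c] not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s) "
            f"{[schema[c] for c in missing]}"
        )
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    df = df.rename(columns={v: k for k, v in schema.items()})
    numeric = df[["beta", "se", "p"]].apply(pd.to_numeric, errors="coerce")
    keep = np.isfinite(numeric).all(axis=1)
    kept = df.loc[keep]
    records = [
        CohortEwasRecord(
            probe_id=str(r.probe_id),
            cohort_id=str(r.cohort),
            stratum=str(r.stratum),
            beta=float(r.beta),
            se=float(r.se),
            p=float(r.p),
            n=int(r.n),
        )
        for r in kept.itertuples()
    ]
    report = ReadReport(
        n_read=len(df), n_kept=len(records), n_dropped=int((~keep).sum())
    )
    return records, report


def write_summary_stats(
    records: Sequence[CohortEwasRecord], path: Union[str, Path]
) -> None:
    """Write records as TSV with full float precision (round-trip safe)."""
    df = pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "cohort": [r.cohort_id for r in records],
            "stratum": [r.stratum for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "p": [r.p for r in records],
            "n": [r.n for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def summary_stats_frame(records: Sequence[CohortEwasRecord]) -> pd.DataFrame:
    """Records as the tabular view used by the meta module."""
    return pd.DataFrame(
        [
            {
                "probe_id": r.probe_id,
                "cohort": r.cohort_id,
                "stratum": r.stratum,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "n": r.n,
            }
            for r in records
        ]
    )


def read_bed_annotation(
    path: Union[str, Path],
) -> list[Union[CpGAnnotation, GeneRegion]]:
    """Read CpG or gene annotations from a BED file.

    A record whose name looks like an array probe (``cg``/``ch`` prefix) or
    whose interval has length 1 is returned as a :class:`CpGAnnotation`
    (position = BED end, i.e. the 1-based point); anything else becomes a
    :class:`GeneRegion`. Gene lines may carry the TSS in column 7
    (thickStart, 0-based); otherwise the strand-aware interval edge is used
    (column 6; ``-`` strand → end).
    """
    out: list[Union[CpGAnnotation, GeneRegion]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedFormatError(
                    f"{path}:{lineno}: expected >= 4 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            start0, end0 = int(start_s), int(end_s)
            if end0 < start0:
                raise BedFormatError(
                    f"{path}:{lineno}: end {end0} < start {start0}"
                )
            start1, end1 = start0 + 1, end0
            if end0 - start0 == 1 or name.startswith(("cg", "ch")):
                out.append(
                    CpGAnnotation(
                        probe_id=name,
                        chromosome=chrom,
                        position=end1,
                        gene_symbol=fields[4] if len(fields) > 4 and fields[4] not in (".", "") else None,
                    )
                )
            else:
                strand = fields[5] if len(fields) > 5 else "+"
                if len(fields) > 6 and fields[6] not in (".", ""):
                    tss = int(fields[6]) + 1
                else:
                    tss = end1 if strand == "-" else start1
                out.append(
                    GeneRegion(
                        gene_symbol=name,
                        chromosome=chrom,
                        start=start1,
                        end=end1,
                        tss=tss,
                    )
                )
    return out


def write_bed_annotation(
    annotations: Sequence[Union[CpGAnnotation, GeneRegion]],
    path: Union[str, Path],
) -> None:
    """Write annotations as BED (inverse of :func:`read_bed_annotation`)."""
    with open(path, "w") as fh:
        for a in annotations:
            if isinstance(a, CpGAnnotation):
                gene = a.gene_symbol if a.gene_symbol else "."
                fh.write(
                    f"{a.chromosome}\t{a.position - 1}\t{a.position}"
                    f"\t{a.probe_id}\t{gene}\n"
                )
            else:
                fh.write(
                    f"{a.chromosome}\t{a.start - 1}\t{a.end}"
                    f"\t{a.gene_symbol}\t.\t+\t{a.tss - 1}\n"
                )


def annotations_frame(
    annotations: Sequence[Union[CpGAnnotation, GeneRegion]]
) -> pd.DataFrame:
    """CpG annotations as a DataFrame (probe_id, chromosome, position)."""
    cpgs = [a for a in annotations if isinstance(a, CpGAnnotation)]
    return pd.DataFrame(
        {
            "probe_id": [a.probe_id for a in cpgs],
            "chromosome": [a.chromosome for a in cpgs],
            "position": [a.position for a in cpgs],
            "gene_symbol": [a.gene_symbol for a in cpgs],
        }
    )


def read_tsv(path: Union[str, Path], required: Sequence[str] = ()) -> pd.DataFrame:
    """Generic TSV reader with mandatory-column checking."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
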