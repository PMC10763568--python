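"""Readers and writers for the cohort table dialect, BED, and summary TSV.

The cohort table is UTF-8 TSV with one row per carrier and the columns listed
in :data:`COHORT_COLUMNS`. Coordinates in the dialect are 1-based inclusive as
printed in case reports; BED output converts to the 0-based half-open
convention at the file boundary and nowhere else.
"""

from __future__ import annotations

import csv
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .types import (
    CaseRecord,
    ClinicalStatus,
    EvidenceRecord,
    GenomicInterval,
    Inheritance,
    Sex,
    Shape,
)

logger = logging.getLogger(__name__)

__all__ = [
    "COHORT_COLUMNS",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "read_evidence",
    "write_bed",
    "read_bed",
    "load_packaged_cohort",
    "PACKAGED_FIXTURES",
]

COHORT_COLUMNS = [
    "case_id",
    "karyotype_text",
    "sex",
    "clinical_status",
    "shapes",
    "mosaic",
    "clone_counts",
    "inheritance",
    "groups",
    "interval_chrom",
    "interval_start",
    "interval_end",
    "build",
    "modalities",
    "phenotype_terms",
    "arm_class",
    "source_table",
]

MANDATORY_COLUMNS = ("case_id", "karyotype_text", "clinical_status")

PACKAGED_FIXTURES = ("table1", "table2", "table3", "table4", "table5", "evidence")

_SHAPE_TOKENS = {"min": Shape.min, "r": Shape.r, "inv dup": Shape.inv_dup,
                 "invdup": Shape.inv_dup, "unknown": Shape.unknown}
_INHERIT_TOKENS = {
    "maternal": Inheritance.maternal,
    "paternal": Inheritance.paternal,
    "de novo": Inheritance.de_novo,
    "unknown": Inheritance.unknown,
    "": Inheritance.unknown,
}


class SchemaError(ValueError):
    pass


def _split(field: str) -> list[str]:
    return [t.strip() for t in field.split(";") if t.strip()]


def _row_to_record(row: dict) -> CaseRecord:
    interval: Optional[GenomicInterval] = None
    chrom, start, end = (row.get(k, "").strip() for k in
                         ("interval_chrom", "interval_start", "interval_end"))
    build = row.get("build", "").strip() or "GRCh37"
    if chrom and start and end:
        try:
            interval = GenomicInterval(
                chrom, int(start.replace(",", "")), int(end.replace(",", "")), build
            )
        except ValueError as exc:
            logger.warning(
                "case %s: unparseable interval (%s); record kept without interval",
                row.get("case_id"), exc,
            )
    sex_tok = (row.get("sex", "") or "unknown").strip().lower()
    sex = {"male": Sex.male, "female": Sex.female}.get(sex_tok, Sex.unknown)
    status = {"normal": ClinicalStatus.normal, "abnormal": ClinicalStatus.abnormal}.get(
        (row.get("clinical_status", "") or "").strip().lower(), ClinicalStatus.unknown
    )
    shapes = [_SHAPE_TOKENS.get(t.lower(), Shape.unknown) for t in _split(row.get("shapes", ""))]
    counts = []
    for tok in _split(row.get("clone_counts", "")):
        if tok.isdigit():
            counts.append(int(tok))
    return CaseRecord(
        case_id=row["case_id"].strip(),
        karyotype_text=row.get("karyotype_text", "").strip(),
        sex=sex,
        clinical_status=status,
        shape_calls=shapes,
        mosaic=(row.get("mosaic", "").strip().lower() in ("true", "1", "yes")),
        clone_counts=counts,
        inheritance=_INHERIT_TOKENS.get(
            (row.get("inheritance", "") or "").strip().lower(), Inheritance.unknown
        ),
        group_labels=set(_split(row.get("groups", ""))),
        trisomy_interval=interval if (interval and interval.build == "GRCh37") else None,
        evidence_modalities=set(_split(row.get("modalities", ""))),
        phenotype_terms=_split(row.get("phenotype_terms", "")),
        arm_class=(row.get("arm_class", "").strip() or None),
        source_table=row.get("source_table", "").strip(),
    )


def read_cohort(path, dialect: str = "tsv") -> list[CaseRecord]:
    """Read a cohort table; one :class:`CaseRecord` per data row.

    Unparseable coordinate fields yield ``trisomy_interval=None`` with a logged
    warning, not a failure. Missing mandatory columns raise :class:`SchemaError`
    naming the column.
    """
    if dialect == "json":
        df = pd.read_json(path, dtype=str).fillna("")
        rows = df.to_dict(orient="records")
        header = list(df.columns)
    elif dialect == "tsv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(
                (line for line in fh if not line.startswith("#")), delimiter="\t"
            )
            header = reader.fieldnames or []
            rows = list(reader)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in MANDATORY_COLUMNS:
        if col not in header:
            raise SchemaError(f"cohort table is missing mandatory column {col!r}")
    return [_row_to_record({k: (v or "") for k, v in row.items()}) for row in rows]


def _record_to_row(rec: CaseRecord) -> dict:
    iv = rec.trisomy_interval
    return {
        "case_id": rec.case_id,
        "karyotype_text": rec.karyotype_text,
        "sex": rec.sex.value,
        "clinical_status": rec.clinical_status.value,
        "shapes": ";".join(s.value for s in rec.shape_calls),
        "mosaic": "true" if rec.mosaic else "false",
        "clone_counts": ";".join(str(c) for c in rec.clone_counts),
        "inheritance": rec.inheritance.value,
        "groups": ";".join(sorted(rec.group_labels)),
        "interval_chrom": iv.chrom if iv else "",
        "interval_start": str(iv.start) if iv else "",
        "interval_end": str(iv.end) if iv else "",
        "build": iv.build if iv else "",
        "modalities": ";".join(sorted(rec.evidence_modalities)),
        "phenotype_terms": ";".join(rec.phenotype_terms),
        "arm_class": rec.arm_class or "",
        "source_table": rec.source_table,
    }


def write_cohort(records: Sequence[CaseRecord], path, dialect: str = "tsv") -> None:
    rows = [_record_to_row(r) for r in records]
    if dialect == "json":
        pd.DataFrame(rows, columns=COHORT_COLUMNS).to_json(path, orient="records")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=COHORT_COLUMNS, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def read_evidence(path) -> list[EvidenceRecord]:
    """Read benign/pathogenic evidence records from TSV."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            out.append(
                EvidenceRecord(
                    record_id=row["record_id"].strip(),
                    classification=row["classification"].strip(),
                    interval=GenomicInterval(
                        row["chrom"].strip(),
                        int(row["start"].replace(",", "")),
                        int(row["end"].replace(",", "")),
                        row.get("build", "GRCh37").strip() or "GRCh37",
                    ),
                    flank_only=row.get("flank_only", "").strip().lower()
                    in ("true", "1", "yes"),
                )
            )
    return out


# ----------------------------------------------------------------------
# BED
# ----------------------------------------------------------------------

def write_bed(regions: Iterable[tuple[GenomicInterval, str]], path) -> None:
    """Write labeled intervals as 4-column BED.

    1-based inclusive [s, e] maps to BED's 0-based half-open [s-1, e); output
    is ordered deterministically by (chrom, start). All intervals must share
    one genome build.
    """
    regions = list(regions)
    builds = {iv.build for iv, _ in regions}
    if len(builds) > 1:
        raise ValueError(f"mixed genome builds in BED output: {sorted(builds)}")
    build = builds.pop() if builds else "GRCh37"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# build={build}; coordinates are 0-based half-open\n")
        for iv, label in sorted(regions, key=lambda r: (r[0].chrom, r[0].start, r[0].end)):
            fh.write(f"chr{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{label}\n")


def read_bed(path, build: str = "GRCh37") -> list[tuple[GenomicInterval, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                if line.startswith("# build="):
                    build = line.split("build=")[1].split(";")[0]
                continue
            chrom, start, end, *rest = line.split("\t")
            label = rest[0] if rest else ""
            out.append(
                (
                    GenomicInterval(chrom.removeprefix("chr"), int(start) + 1, int(end), build),
                    label,
                )
            )
    return out


# ----------------------------------------------------------------------
# packaged fixtures
# ----------------------------------------------------------------------

def _packaged(name: str):
    return resources.files("ssmc11.data").joinpath(name)


def load_packaged_cohort(
    name: str,
) -> Union[list[CaseRecord], list[EvidenceRecord], pd.DataFrame]:
    """Load one of the packaged case tables.

    table1/table2/table3/table4 return case records; ``evidence`` returns the
    benign/pathogenic refinement records; ``table5`` returns the arm-wise
    phenotype annotation table as a DataFrame.
    """
    if name not in PACKAGED_FIXTURES:
        raise LookupError(
            f"unknown fixture {name!r}; available: {', '.join(PACKAGED_FIXTURES)}"
        )
    ref = _packaged(f"{name}.tsv")
    with resources.as_file(ref) as p:
        if name == "evidence":
            return read_evidence(p)
        if name == "table5":
            return pd.read_csv(p, sep="\t", comment="#", dtype=str).fillna("")
        return read_cohort(p)


def load_full_cohort() -> list[CaseRecord]:
    """The 57 sSMC(11) carriers plus the 8 sSMC-like duplication carriers."""
    return load_packaged_cohort("table1") + load_packaged_cohort("table2")
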