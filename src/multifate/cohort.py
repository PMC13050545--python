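"""Somatic FOXA1 mutation cohort: parsing, subgrouping and summarization.

Reads a MAF-like TSV of FOXA1 mutations, classifies each record into the
missense / inframe-indel / nonsense / frameshift / other subgroups from the
annotation column, localizes protein changes onto FOXA1 domains (Wing2,
Forkhead, C-terminus) and summarizes counts and fractions by tumor site for
lollipop-style reporting.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBGROUPS = ("missense", "inframe_indel", "nonsense", "frameshift", "other")

#: Annotation vocabulary -> subgroup.  Classification uses the annotation
#: column of the table, never the protein-change string.
_CLASS_MAP = {
    "missense_mutation": "missense",
    "missense": "missense",
    "missense_variant": "missense",
    "in_frame_del": "inframe_indel",
    "in_frame_ins": "inframe_indel",
    "inframe_deletion": "inframe_indel",
    "inframe_insertion": "inframe_indel",
    "inframe_indel": "inframe_indel",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "stop_gained": "nonsense",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "frameshift_variant": "frameshift",
    "frameshift": "frameshift",
}

DEFAULT_COLUMNS = {
    "patient_id": "Patient_ID",
    "sample_id": "Sample_ID",
    "sample_type": "Sample_Type",
    "variant_class": "Variant_Classification",
    "protein_change": "HGVSp_Short",
}


@dataclass(frozen=True)
class MutationRecord:
    patient_id: str
    sample_id: str
    sample_type: str  # primary | metastasis
    variant_class: str  # one of SUBGROUPS
    protein_change: str
    residue_start: int | None = None
    residue_end: int | None = None


@dataclass(frozen=True)
class DomainMap:
    """Named closed residue intervals on the FOXA1 protein.

    Intervals are matched in declaration order, so more specific nested
    intervals (Wing2 inside the Forkhead domain) are declared first.
    """

    intervals: tuple[tuple[str, int, int], ...] = (
        ("Wing2", 247, 269),
        ("Forkhead", 168, 269),
        ("C-terminus", 270, 472),
    )

    def __post_init__(self) -> None:
        labels = [lab for lab, _, _ in self.intervals]
        if len(set(labels)) != len(labels):
            raise ValueError("domain labels must be unique")
        for lab, s, e in self.intervals:
            if s > e:
                raise ValueError(f"domain {lab} has start > end")


DEFAULT_DOMAINS = DomainMap()


def classify_variant(raw_class: str) -> str:
    """Map an annotation token (e.g. ``Missense_Mutation``) to a subgroup."""
    return _CLASS_MAP.get(str(raw_class).strip().lower(), "other")


# HGVS-p-ish dialects: p.H247Y, H247Y, M253_F254del, E255fs, G275*, G275X
_RANGE_RE = re.compile(r"^(?:p\.)?\(?([A-Z])(\d+)_(?:([A-Z])?(\d+))(?:[A-Za-z*]*)\)?$")
_SINGLE_RE = re.compile(r"^(?:p\.)?\(?([A-Z*])(\d+)(?:[A-Za-z*]*)\)?$")


def parse_protein_change(s: str) -> tuple[int | None, int | None]:
    """Extract (residue_start, residue_end) from an HGVS-p-like string.

    Unparseable strings return ``(None, None)`` with a logged warning;
    parsing never raises.
    """
    if s is None or (isinstance(s, float) and np.isnan(s)):
        return None, None
    s = str(s).strip()
    if not s:
        return None, None
    m = _RANGE_RE.match(s)
    if m:
        start, end = int(m.group(2)), int(m.group(4))
        if end >= start >= 1:
            return start, end
    m = _SINGLE_RE.match(s)
    if m:
        pos = int(m.group(2))
        if pos >= 1:
            return pos, pos
    logger.warning("unparseable protein change: %r", s)
    return None, None


def assign_domain(residue: int, domains: DomainMap = DEFAULT_DOMAINS) -> str:
    """Label of the first domain interval containing ``residue``, else 'outside'."""
    if residue < 1:
        raise ValueError("residue must be >= 1")
    for label, start, end in domains.intervals:
        if start <= residue <= end:
            return label
    return "outside"


def parse_maf(path: str | Path, column_map: dict[str, str] | None = None
              ) -> list[MutationRecord]:
    """Parse a MAF-like TSV into :class:`MutationRecord` rows.

    ``column_map`` overrides the default column names (keys: patient_id,
    sample_id, sample_type, variant_class, protein_change).  A missing
    required column raises ``ValueError`` naming it; an empty or
    header-only file yields an empty list.
    """
    cols = dict(DEFAULT_COLUMNS)
    cols.update(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype=str)
    for key, col in cols.items():
        if col not in df.columns:
            raise ValueError(f"required column {col!r} ({key}) not found in {path}")
    records = []
    for _, row in df.iterrows():
        pchange = row[cols["protein_change"]]
        pchange = "" if pd.isna(pchange) else str(pchange)
        start, end = parse_protein_change(pchange)
        site = str(row[cols["sample_type"]]).strip().lower()
        if site not in ("primary", "metastasis"):
            site = "metastasis" if site.startswith("met") else "primary"
        records.append(
            MutationRecord(
                patient_id=str(row[cols["patient_id"]]),
                sample_id=str(row[cols["sample_id"]]),
                sample_type=site,
                variant_class=classify_variant(row[cols["variant_class"]]),
                protein_change=pchange,
                residue_start=start,
                residue_end=end,
            )
        )
    return records


@dataclass
class CohortSummary:
    counts: pd.DataFrame  # subgroup x sample_type
    residue_histogram: pd.DataFrame  # residue, subgroup, count
    total_mutations: int
    total_cases: int
    total_patients: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_mutations": self.total_mutations,
                "total_cases": self.total_cases,
                "total_patients": self.total_patients,
                "counts": {
                    sg: {st: int(self.counts.loc[sg, st]) for st in self.counts.columns}
                    for sg in self.counts.index
                },
            },
            indent=2,
        )


def summarize_cohort(records: list[MutationRecord]) -> CohortSummary:
    """Counts per subgroup x site, residue histogram, and de-duplicated totals."""
    sites = ("primary", "metastasis")
    counts = pd.DataFrame(0, index=list(SUBGROUPS), columns=list(sites))
    hist: dict[tuple[int, str], int] = {}
    cases, patients = set(), set()
    for r in records:
        counts.loc[r.variant_class, r.sample_type] += 1
        cases.add(r.sample_id)
        patients.add(r.patient_id)
        if r.residue_start is not None:
            key = (r.residue_start, r.variant_class)
            hist[key] = hist.get(key, 0) + 1
    hist_df = pd.DataFrame(
        [(res, sg, n) for (res, sg), n in sorted(hist.items())],
        columns=["residue", "subgroup", "count"],
    )
    return CohortSummary(
        counts=counts,
        residue_histogram=hist_df,
        total_mutations=len(records),
        total_cases=len(cases),
        total_patients=len(patients),
    )


def subgroup_fractions(summary: CohortSummary) -> dict[str, float]:
    """Subgroup shares on the 0-100 percent scale; sums to 100."""
    if summary.total_mutations == 0:
        raise ValueError("cannot compute fractions of an empty cohort")
    totals = summary.counts.sum(axis=1)
    return {
        sg: 100.0 * totals[sg] / summary.total_mutations for sg in summary.counts.index
    }


def indel_hotspot_fraction(records: list[MutationRecord],
                           residues: tuple[int, ...] = (253, 254)) -> float:
    """Fraction of inframe indels whose start residue lies at a hotspot.

    Reported descriptively; the cohort literature gives conflicting hotspot
    shares, so this module measures and takes no side.
    """
    indels = [r for r in records if r.variant_class == "inframe_indel"]
    if not indels:
        return float("nan")
    hit = sum(1 for r in indels if r.residue_start in residues)
    return hit / len(indels)


def write_records_tsv(path: str | Path, records: list[MutationRecord],
                      column_map: dict[str, str] | None = None) -> None:
    """Write records back to a MAF-like TSV that :func:`parse_maf` round-trips."""
    cols = dict(DEFAULT_COLUMNS)
    cols.update(column_map or {})
    token = {
        "missense": "Missense_Mutation",
        "inframe_indel": "In_Frame_Del",
        "nonsense": "Nonsense_Mutation",
        "frameshift": "Frame_Shift_Del",
        "other": "Splice_Site",
    }
    df = pd.DataFrame(
        {
            cols["patient_id"]: [r.patient_id for r in records],
            cols["sample_id"]: [r.sample_id for r in records],
            cols["sample_type"]: [r.sample_type for r in records],
            cols["variant_class"]: [token[r.variant_class] for r in records],
            cols["protein_change"]: [r.protein_change for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
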