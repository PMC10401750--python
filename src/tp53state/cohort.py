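"""Patient/mutation data model and tabular + VCF I/O.

The cohort table is long-format: one row per TP53 variant, with patient-level
columns (cytogenetics, survival, subtype) repeated on every row.  A patient
without any TP53 mutation appears as a single row with an empty ``variant_id``.

VAFs are stored internally as fractions in [0, 1].  Input values greater than 1
are interpreted as percentages and divided by 100 (clinical reports typically
print "VAF 33%"); each such conversion is logged once per file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONSEQUENCES = ("missense", "truncating", "splice", "other")

#: column order of the cohort TSV dialect
COHORT_COLUMNS = [
    "patient_id", "subtype", "blast_pct", "os_time_months", "os_event",
    "del17p", "del17p_clonality", "complex_karyotype", "tp53_upd",
    "upd_clonality", "variant_id", "protein_change", "consequence",
    "vaf", "depth",
]

SUBTYPES = ("pAML", "sAML", "HR_MDS", "LR_MDS", "MDS_MPN", "other")


class CohortFormatError(ValueError):
    """Raised when an input table violates the documented dialect."""


@dataclass
class MutationCall:
    """A single TP53 variant in one patient."""

    variant_id: str
    vaf: float
    protein_change: str = ""
    aa_position: Optional[int] = None
    consequence: str = "other"
    depth: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be a fraction in [0,1], got {self.vaf}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")


@dataclass
class CytogeneticsProfile:
    del17p: bool = False
    del17p_clonality: Optional[float] = None
    complex_karyotype: bool = False
    tp53_upd: bool = False
    upd_clonality: Optional[float] = None

    def __post_init__(self) -> None:
        if self.del17p_clonality is not None and not self.del17p:
            raise ValueError("del17p_clonality given but del17p is False")
        if self.upd_clonality is not None and not self.tp53_upd:
            raise ValueError("upd_clonality given but tp53_upd is False")


@dataclass
class PatientRecord:
    patient_id: str
    os_time: float
    os_event: bool
    subtype: str = "other"
    blast_pct: Optional[float] = None
    mutations: list[MutationCall] = field(default_factory=list)
    cytogenetics: CytogeneticsProfile = field(default_factory=CytogeneticsProfile)

    def __post_init__(self) -> None:
        if not math.isfinite(self.os_time) or self.os_time < 0:
            raise ValueError(f"os_time must be finite and >= 0, got {self.os_time}")

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


@dataclass
class Cohort:
    patients: list[PatientRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


def _normalize_vaf(value: float) -> tuple[float, bool]:
    """Return (fraction, was_percent). Values > 1 are read as percent."""
    if value > 1.0:
        return value / 100.0, True
    return value, False


def _parse_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "y"}
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return bool(int(value))


def _opt_float(value) -> Optional[float]:
    if value is None or value == "":
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f


def read_cohort_tsv(path, sep: str = "\t") -> Cohort:
    """Read a long-format cohort table into a :class:`Cohort`.

    Required columns: ``patient_id``, ``os_time_months``, ``os_event``;
    mutation rows additionally require ``vaf``.  VAF values > 1 are treated
    as percentages.  Raises :class:`CohortFormatError` on a missing column,
    a duplicated (patient_id, variant_id) pair, a negative survival time, or
    a mutation row lacking its VAF.
    """
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str, "variant_id": str})
    for col in ("patient_id", "os_time_months", "os_event"):
        if col not in df.columns:
            raise CohortFormatError(f"required column missing: {col!r}")
    if "variant_id" not in df.columns:
        df["variant_id"] = ""
    df["variant_id"] = df["variant_id"].fillna("")

    dup = df[df["variant_id"] != ""].duplicated(subset=["patient_id", "variant_id"])
    if dup.any():
        pair = df.loc[dup[dup].index[0], ["patient_id", "variant_id"]].tolist()
        raise CohortFormatError(f"duplicate (patient_id, variant_id): {tuple(pair)}")

    n_percent = 0
    patients: list[PatientRecord] = []
    for pid, rows in df.groupby("patient_id", sort=False):
        first = rows.iloc[0]
        os_time = float(first["os_time_months"])
        if os_time < 0:
            raise CohortFormatError(f"negative os_time_months for patient {pid}")
        cyto = CytogeneticsProfile(
            del17p=_parse_bool(first.get("del17p")),
            del17p_clonality=_opt_float(first.get("del17p_clonality")),
            complex_karyotype=_parse_bool(first.get("complex_karyotype")),
            tp53_upd=_parse_bool(first.get("tp53_upd")),
            upd_clonality=_opt_float(first.get("upd_clonality")),
        )
        mutations = []
        for _, row in rows.iterrows():
            if row["variant_id"] == "":
                continue
            raw_vaf = _opt_float(row.get("vaf"))
            if raw_vaf is None:
                raise CohortFormatError(
                    f"mutation row for patient {pid}, variant "
                    f"{row['variant_id']!r} has no VAF"
                )
            vaf, was_pct = _normalize_vaf(raw_vaf)
            n_percent += was_pct
            depth = _opt_float(row.get("depth"))
            aa = _opt_float(row.get("aa_position"))
            cons = row.get("consequence")
            mutations.append(MutationCall(
                variant_id=str(row["variant_id"]),
                vaf=vaf,
                protein_change=str(row.get("protein_change") or "")
                if not pd.isna(row.get("protein_change")) else "",
                aa_position=int(aa) if aa is not None else None,
                consequence=cons if cons in CONSEQUENCES else "other",
                depth=int(depth) if depth is not None else None,
            ))
        subtype = first.get("subtype")
        patients.append(PatientRecord(
            patient_id=str(pid),
            os_time=os_time,
            os_event=_parse_bool(first["os_event"]),
            subtype=subtype if subtype in SUBTYPES else "other",
            blast_pct=_opt_float(first.get("blast_pct")),
            mutations=mutations,
            cytogenetics=cyto,
        ))
    if n_percent:
        logger.info("interpreted %d VAF values > 1 as percentages", n_percent)
    return Cohort(patients=patients, provenance=str(path))


def write_cohort_tsv(cohort: Cohort, path, sep: str = "\t") -> None:
    """Write a :class:`Cohort` in the long-format dialect read back by
    :func:`read_cohort_tsv` (round-trip safe up to float formatting)."""
    rows = []
    for p in cohort:
        base = {
            "patient_id": p.patient_id,
            "subtype": p.subtype,
            "blast_pct": p.blast_pct,
            "os_time_months": round(p.os_time, 4),
            "os_event": int(p.os_event),
            "del17p": int(p.cytogenetics.del17p),
            "del17p_clonality": p.cytogenetics.del17p_clonality,
            "complex_karyotype": int(p.cytogenetics.complex_karyotype),
            "tp53_upd": int(p.cytogenetics.tp53_upd),
            "upd_clonality": p.cytogenetics.upd_clonality,
        }
        if not p.mutations:
            rows.append({**base, "variant_id": "", "protein_change": "",
                         "consequence": "", "vaf": None, "depth": None})
        for m in p.mutations:
            rows.append({**base,
                         "variant_id": m.variant_id,
                         "protein_change": m.protein_change,
                         "consequence": m.consequence,
                         "aa_position": m.aa_position,
                         "vaf": round(m.vaf, 4),
                         "depth": m.depth})
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS + ["aa_position"])
    df.to_csv(path, sep=sep, index=False, float_format="%.4f")


def read_tp53_vcf(path) -> list[tuple[str, MutationCall]]:
    """Import TP53 variant calls from a VCF with per-sample genotypes.

    VAF comes from the per-sample ``AF`` FORMAT field if present, otherwise
    from ``AD`` allele depths as alt/(ref+alt).  Records for which neither is
    available are skipped with a warning.  Consequence is taken from an
    ``ANN``/``CSQ``-style INFO annotation when one can be recognized, else
    ``other``.  Returns ``(sample_name, MutationCall)`` pairs.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: list[tuple[str, MutationCall]] = []
    for rec in vcf:
        vid = f"{rec.CHROM}:{rec.POS}:{rec.REF}>{rec.ALT[0] if rec.ALT else '.'}"
        consequence = _consequence_from_info(rec)
        af = rec.format("AF")
        ad = rec.format("AD")
        for i, sample in enumerate(samples):
            vaf = None
            if af is not None:
                v = float(np.ravel(af[i])[0])
                if not math.isnan(v) and v >= 0:
                    vaf = v
            if vaf is None and ad is not None:
                depths = np.ravel(ad[i]).astype(float)
                if depths.size >= 2 and np.all(depths[:2] >= 0):
                    total = depths[0] + depths[1]
                    if total > 0:
                        vaf = depths[1] / total
            if vaf is None:
                logger.warning("no AF or usable AD for %s sample %s; skipped",
                               vid, sample)
                continue
            depth = None
            if ad is not None:
                depths = np.ravel(ad[i]).astype(float)
                if depths.size >= 2 and np.all(depths[:2] >= 0):
                    depth = int(depths[0] + depths[1])
            calls.append((sample, MutationCall(
                variant_id=vid, vaf=min(float(vaf), 1.0),
                consequence=consequence, depth=depth)))
    return calls


def _consequence_from_info(rec) -> str:
    ann = rec.INFO.get("ANN") or rec.INFO.get("CSQ")
    if not ann:
        return "other"
    text = str(ann).lower()
    if "missense" in text:
        return "missense"
    if "stop_gained" in text or "frameshift" in text:
        return "truncating"
    if "splice" in text:
        return "splice"
    return "other"


def write_classified_tsv(cohort: Cohort, calls, path, sep: str = "\t") -> None:
    """Write one row per patient with its allelic-state call (stable column
    order, floats at 4 decimals).  ``calls`` must align with the cohort."""
    if len(calls) != len(cohort):
        raise ValueError(
            f"{len(calls)} calls for {len(cohort)} patients; one call "
            "per patient is required")
    rows = []
    for p, c in zip(cohort, calls):
        rows.append({
            "patient_id": p.patient_id,
            "subtype": p.subtype,
            "n_mutations": p.n_mutations,
            "state": c.state,
            "rule": c.rule,
            "combined_vaf": round(c.combined_vaf, 4),
            "cutoff_used": round(c.cutoff_used, 4),
        })
    pd.DataFrame(rows, columns=[
        "patient_id", "subtype", "n_mutations", "state", "rule",
        "combined_vaf", "cutoff_used",
    ]).to_csv(path, sep=sep, index=False, float_format="%.4f")
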