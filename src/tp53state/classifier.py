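"""TP53 allelic-state classification.

Two schemes are implemented:

* the traditional hit count (wild type / single hit / double hit), where a
  hit is any TP53 mutation, a 17p deletion, or TP53-locus UPD accompanying a
  mutation; and

* the three-group allelic-state algorithm, which first resolves cases that
  are *obligatory biallelic* by bulk arithmetic —

    (i)   a single mutation with VAF > 50%,
    (ii)  two or more mutations with combined VAF > 50%,
    (iii) mutation VAF + del(17p) clonality > 50%, or
    (iv)  a mutation with documented TP53-locus UPD (demonstrated LOH)

  — and then splits the remaining ambiguous cases (combined VAF <= 50%) into
  *probable biallelic* vs *probable monoallelic* at a combined-VAF cutoff
  (default 23%, the survival-optimized value; see :mod:`tp53state.cutoff`).

Rationale for rule (iii) using the *maximum* single-mutation VAF: mutation
and deletion are presumed in trans within one clone; summing all mutations
with the deletion would double-count mosaic clones.  A combined VAF equal to
the cutoff is assigned to probable biallelic (the higher-risk class).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .cohort import Cohort, PatientRecord

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.23
OBLIGATORY_THRESHOLD = 0.5

STATES = ("wild_type", "obligatory_biallelic", "probable_biallelic",
          "probable_monoallelic", "del17p_only")

#: rule codes that imply the obligatory_biallelic state
OBLIGATORY_RULES = ("single_vaf_gt50", "combined_vaf_gt50",
                    "vaf_plus_del17p_gt50", "mutation_with_upd")

SEVERITY_ORDER = {"probable_monoallelic": 0, "probable_biallelic": 1,
                  "obligatory_biallelic": 2}


@dataclass(frozen=True)
class HitClass:
    label: str                      # wild_type | single_hit | double_hit
    basis: tuple[str, ...] = ()     # reason codes

    def __post_init__(self) -> None:
        n = len(self.basis)
        expected = "wild_type" if n == 0 else ("single_hit" if n == 1
                                               else "double_hit")
        if self.label != expected:
            raise ValueError(f"label {self.label} inconsistent with "
                             f"{n} basis codes")


@dataclass(frozen=True)
class AllelicStateCall:
    state: str
    rule: str
    combined_vaf: float
    cutoff_used: float


def combined_vaf(patient: PatientRecord) -> float:
    """Sum of VAFs over all TP53 mutations, capped at 1.0 (with a warning
    when the raw sum exceeds 1; VAFs of distinct variants can overlap only
    through copy-number effects, so a sum above 1 indicates inconsistent
    input).  Zero for a patient without mutations."""
    total = sum(m.vaf for m in patient.mutations)
    if total > 1.0:
        logger.warning("combined VAF %.3f > 1 for patient %s; capped",
                       total, patient.patient_id)
        return 1.0
    return total


def classify_traditional(patient: PatientRecord) -> HitClass:
    """Traditional single/double-hit count.

    Each distinct mutation is a hit; del(17p) is a hit (with or without a
    mutation); TP53-locus UPD counts only when at least one mutation is
    present (UPD of a wild-type locus inactivates nothing).
    """
    basis: list[str] = []
    n_mut = patient.n_mutations
    if n_mut >= 1:
        basis.append("mutation")
        basis.extend(["second_mutation"] * (n_mut - 1))
    if patient.cytogenetics.del17p:
        basis.append("del17p")
    if patient.cytogenetics.tp53_upd and n_mut >= 1:
        basis.append("upd")
    label = ("wild_type" if not basis
             else "single_hit" if len(basis) == 1 else "double_hit")
    return HitClass(label=label, basis=tuple(basis))


def classify_novel(patient: PatientRecord,
                   cutoff: float = DEFAULT_CUTOFF) -> AllelicStateCall:
    """Three-group allelic-state call for one patient (see module docstring
    for the decision order).  Patients with isolated del(17p) and no
    mutation are returned as ``del17p_only`` — the three-group scheme is
    defined for TP53-mutant cases only.  del(17p) with unknown clonality
    disables rule (iii) alone (logged)."""
    if not 0 < cutoff < OBLIGATORY_THRESHOLD:
        raise ValueError(f"cutoff must lie in (0, 0.5), got {cutoff}")
    cyto = patient.cytogenetics
    cv = combined_vaf(patient)

    if patient.n_mutations == 0:
        if cyto.del17p:
            return AllelicStateCall("del17p_only", "no_mutation_del17p", 0.0, cutoff)
        return AllelicStateCall("wild_type", "no_mutation", 0.0, cutoff)

    vafs = [m.vaf for m in patient.mutations]
    if len(vafs) == 1 and vafs[0] > OBLIGATORY_THRESHOLD:
        return AllelicStateCall("obligatory_biallelic", "single_vaf_gt50",
                                cv, cutoff)
    if len(vafs) >= 2 and cv > OBLIGATORY_THRESHOLD:
        return AllelicStateCall("obligatory_biallelic", "combined_vaf_gt50",
                                cv, cutoff)
    if cyto.del17p:
        if cyto.del17p_clonality is None:
            logger.info("patient %s: del(17p) clonality unknown; "
                        "VAF+clonality rule skipped", patient.patient_id)
        elif max(vafs) + cyto.del17p_clonality > OBLIGATORY_THRESHOLD:
            return AllelicStateCall("obligatory_biallelic",
                                    "vaf_plus_del17p_gt50", cv, cutoff)
    if cyto.tp53_upd:
        return AllelicStateCall("obligatory_biallelic", "mutation_with_upd",
                                cv, cutoff)
    if cv >= cutoff:
        return AllelicStateCall("probable_biallelic", "combined_vaf_ge_cutoff",
                                cv, cutoff)
    return AllelicStateCall("probable_monoallelic", "combined_vaf_lt_cutoff",
                            cv, cutoff)


def classify_cohort(cohort: Cohort, cutoff: float = DEFAULT_CUTOFF
                    ) -> tuple[list[AllelicStateCall], dict]:
    """Classify every patient; return the calls plus a summary with counts
    per state, integer percentage shares among TP53-mutant patients, and
    per-subtype state counts."""
    calls = [classify_novel(p, cutoff) for p in cohort]
    counts = Counter(c.state for c in calls)
    n_mutant = sum(1 for p in cohort if p.n_mutations >= 1)
    shares = {}
    for state in ("obligatory_biallelic", "probable_biallelic",
                  "probable_monoallelic"):
        shares[state] = (round(100.0 * counts.get(state, 0) / n_mutant)
                         if n_mutant else 0)
    by_subtype: dict[str, Counter] = {}
    for p, c in zip(cohort, calls):
        by_subtype.setdefault(p.subtype, Counter())[c.state] += 1
    summary = {
        "n_patients": len(cohort),
        "n_tp53_mutant": n_mutant,
        "counts": dict(counts),
        "mutant_share_pct": shares,
        "by_subtype": {k: dict(v) for k, v in sorted(by_subtype.items())},
        "cutoff": cutoff,
    }
    return calls, summary


def reclassification_table(traditional: list[HitClass],
                           novel: list[AllelicStateCall]) -> dict:
    """Cross-tabulate traditional hit classes against the three-group states
    and report the reclassification shares.

    ``upstaged_share_pct`` is the percentage of traditional single-hit cases
    moved into probable biallelic (one decimal); single-hit cases resolved
    as obligatory biallelic are tabulated separately since they are proven,
    not probabilistic, upgrades.  ``downstaged_share_pct`` is the share of
    double-hit cases called probable monoallelic.
    """
    if len(traditional) != len(novel):
        raise ValueError(f"length mismatch: {len(traditional)} traditional "
                         f"vs {len(novel)} novel calls")
    df = pd.DataFrame({"traditional": [t.label for t in traditional],
                       "novel": [c.state for c in novel]})
    df = df[df["traditional"].isin(["single_hit", "double_hit"])
            & df["novel"].isin(["obligatory_biallelic", "probable_biallelic",
                                "probable_monoallelic"])]
    table = pd.crosstab(df["traditional"], df["novel"]).reindex(
        index=["single_hit", "double_hit"],
        columns=["obligatory_biallelic", "probable_biallelic",
                 "probable_monoallelic"], fill_value=0)
    n_single = int(table.loc["single_hit"].sum())
    n_double = int(table.loc["double_hit"].sum())
    up = int(table.loc["single_hit", "probable_biallelic"])
    up_obl = int(table.loc["single_hit", "obligatory_biallelic"])
    down = int(table.loc["double_hit", "probable_monoallelic"])
    return {
        "table": table,
        "n_single_hit": n_single,
        "n_double_hit": n_double,
        "upstaged_to_probable_biallelic": up,
        "upstaged_to_obligatory": up_obl,
        "downstaged_to_probable_monoallelic": down,
        "upstaged_share_pct": round(100.0 * up / n_single, 1) if n_single else 0.0,
        "downstaged_share_pct": round(100.0 * down / n_double, 1) if n_double else 0.0,
    }
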