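"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from tp53state.cohort import (CytogeneticsProfile, MutationCall,
                              PatientRecord)


def make_patient(pid="P1", vafs=(), del17p=False, del17p_clonality=None,
                 upd=False, upd_clonality=None, os_time=24.0, os_event=True,
                 subtype="other", complex_karyotype=False, blast_pct=None):
    """Terse PatientRecord builder used across test modules."""
    muts = [MutationCall(variant_id=f"{pid}_v{i}", vaf=float(v))
            for i, v in enumerate(vafs)]
    cyto = CytogeneticsProfile(
        del17p=del17p, del17p_clonality=del17p_clonality,
        complex_karyotype=complex_karyotype,
        tp53_upd=upd, upd_clonality=upd_clonality)
    return PatientRecord(patient_id=pid, os_time=os_time, os_event=os_event,
                         subtype=subtype, blast_pct=blast_pct,
                         mutations=muts, cytogenetics=cyto)


def random_patient(rng: np.random.Generator, pid: str) -> PatientRecord:
    """Random record spanning the classifier's whole input space."""
    n_mut = int(rng.integers(0, 4))
    vafs = rng.uniform(0.0, 0.7, size=n_mut)
    # keep the combined VAF a legal fraction
    if vafs.sum() > 1:
        vafs = vafs / vafs.sum()
    del17p = bool(rng.random() < 0.3)
    clon = (float(rng.uniform(0, 1)) if del17p and rng.random() < 0.7
            else None)
    upd = bool(rng.random() < 0.15)
    return make_patient(
        pid=pid, vafs=tuple(vafs), del17p=del17p, del17p_clonality=clon,
        upd=upd, upd_clonality=float(rng.uniform(0, 1)) if upd and
        rng.random() < 0.5 else None,
        os_time=float(rng.exponential(30)), os_event=bool(rng.random() < 0.7))


def oracle_traditional(p: PatientRecord) -> str:
    """Brute-force re-statement of the traditional hit count, coded
    independently of the implementation: every mutation is a hit, del(17p)
    is a hit, UPD is a hit only alongside a mutation."""
    hits = len(p.mutations)
    if p.cytogenetics.del17p:
        hits += 1
    if p.cytogenetics.tp53_upd and len(p.mutations) > 0:
        hits += 1
    if hits == 0:
        return "wild_type"
    return "single_hit" if hits == 1 else "double_hit"


def oracle_novel(p: PatientRecord, cutoff: float = 0.23) -> str:
    """Independent re-statement of the three-group decision list."""
    vafs = [m.vaf for m in p.mutations]
    total = min(sum(vafs), 1.0)
    if not vafs:
        return "del17p_only" if p.cytogenetics.del17p else "wild_type"
    if len(vafs) == 1 and vafs[0] > 0.5:
        return "obligatory_biallelic"
    if len(vafs) >= 2 and total > 0.5:
        return "obligatory_biallelic"
    if (p.cytogenetics.del17p and p.cytogenetics.del17p_clonality is not None
            and max(vafs) + p.cytogenetics.del17p_clonality > 0.5):
        return "obligatory_biallelic"
    if p.cytogenetics.tp53_upd:
        return "obligatory_biallelic"
    return "probable_biallelic" if total >= cutoff else "probable_monoallelic"


@pytest.fixture
def rng():
    return np.random.default_rng(20230803)
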