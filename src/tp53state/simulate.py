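"""Clonal-architecture simulator for TP53 allelic configurations.

Generates cohorts with *known* allelic ground truth so that every pipeline
stage — bulk classification, cutoff optimization, single-cell analysis —
can be validated without patient data.  Three layers:

1. **Architectures**: sets of clones over a diploid TP53 locus, each clone a
   cell fraction with a genotype per allele (wild type, one of two point
   mutations, or deleted).  Supported configurations: heterozygous
   monoallelic, hemizygous (mutation + 17p deletion in cis-clone), UPD
   homozygous, compound heterozygous, two-clone monoallelic mosaicism, and a
   nested biallelic subclone inside a heterozygous parent (the "cryptic
   clone" scenario).

2. **Bulk readout**: the expected VAF of variant v is

       VAF(v) = sum_c f_c m_c(v) / (sum_c f_c k_c + (1 - sum_c f_c) * 2)

   with m_c mutant copies and k_c locus copy number (1 when an allele is
   deleted) in clone c; observed VAFs add binomial read sampling at a
   negative-binomially distributed depth.  del(17p) and UPD become visible
   to cytogenetics only when the carrying clone reaches the detection limit
   (default 20%, the sensitivity floor of array-based clonality calls), with
   truncated-Gaussian noise on the reported clonality.

3. **Outcome and single cells**: overall survival is exponential with the
   hazard elevated when a biallelic clone larger than ``tau`` is present
   (censoring uniform over the follow-up horizon); single-cell genotype
   matrices sample cells multinomially from the clone mix, apply per-allele
   dropout (a heterozygous cell with its mutant allele dropped reads WT,
   with its wild-type allele dropped reads HOM_or_HEMI), then flip genotypes
   at a small error rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort, CytogeneticsProfile, MutationCall, PatientRecord

ALLELES = ("wt", "mutA", "mutB", "deleted")
VARIANTS = ("mutA", "mutB")

CONFIG_LABELS = ("het_mono", "hemizygous", "upd_hom", "compound_het",
                 "mosaic_two_mono", "nested_biallelic_subclone")

#: single-cell genotype codes; HOM means homozygous-or-hemizygous mutant
GT_WT, GT_HET, GT_HOM, GT_MISSING = "WT", "HET", "HOM", "MISSING"
GENOTYPE_CODES = (GT_WT, GT_HET, GT_HOM, GT_MISSING)


@dataclass(frozen=True)
class Clone:
    fraction: float
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError(f"clone fraction must be in (0,1], got {self.fraction}")
        for a in (self.allele_a, self.allele_b):
            if a not in ALLELES:
                raise ValueError(f"unknown allele state {a!r}")
        if self.allele_a == self.allele_b == "deleted":
            raise ValueError("biallelic deletion not modeled")

    @property
    def copy_number(self) -> int:
        return 2 - (self.allele_a == "deleted") - (self.allele_b == "deleted")

    def mut_copies(self, variant: str) -> int:
        return (self.allele_a == variant) + (self.allele_b == variant)

    @property
    def is_biallelic(self) -> bool:
        """Both alleles hit (mutated or deleted) — no functional copy left."""
        return self.allele_a != "wt" and self.allele_b != "wt"

    @property
    def has_deletion(self) -> bool:
        return "deleted" in (self.allele_a, self.allele_b)

    @property
    def is_upd_hom(self) -> bool:
        return self.allele_a == self.allele_b and self.allele_a in VARIANTS


@dataclass(frozen=True)
class ClonalArchitecture:
    clones: tuple[Clone, ...]
    config_label: str

    def __post_init__(self) -> None:
        if self.config_label not in CONFIG_LABELS:
            raise ValueError(f"unknown config label {self.config_label!r}")
        if self.total_fraction > 1 + 1e-12:
            raise ValueError("clone fractions sum above 1")

    @property
    def total_fraction(self) -> float:
        return sum(c.fraction for c in self.clones)

    @property
    def variants(self) -> tuple[str, ...]:
        present = [v for v in VARIANTS
                   if any(c.mut_copies(v) for c in self.clones)]
        return tuple(present)

    @property
    def biallelic_fraction(self) -> float:
        return sum(c.fraction for c in self.clones if c.is_biallelic)

    @property
    def del17p_fraction(self) -> float:
        return sum(c.fraction for c in self.clones if c.has_deletion)

    @property
    def upd_fraction(self) -> float:
        return sum(c.fraction for c in self.clones if c.is_upd_hom)


def make_architecture(label: str, fraction: float,
                      fraction2: Optional[float] = None,
                      child_type: str = "second_mutation"
                      ) -> ClonalArchitecture:
    """Build a named configuration.

    ``fraction2`` is the second clone fraction (mosaic) or the nested child
    fraction (must not exceed ``fraction``).  ``child_type`` for the nested
    configuration is one of second_mutation | upd | deletion.
    """
    f = fraction
    if label == "het_mono":
        clones = (Clone(f, "mutA", "wt"),)
    elif label == "hemizygous":
        clones = (Clone(f, "mutA", "deleted"),)
    elif label == "upd_hom":
        clones = (Clone(f, "mutA", "mutA"),)
    elif label == "compound_het":
        clones = (Clone(f, "mutA", "mutB"),)
    elif label == "mosaic_two_mono":
        if fraction2 is None or f + fraction2 > 1:
            raise ValueError("mosaic needs two fractions summing to <= 1")
        clones = (Clone(f, "mutA", "wt"), Clone(fraction2, "mutB", "wt"))
    elif label == "nested_biallelic_subclone":
        if fraction2 is None or fraction2 > f:
            raise ValueError("nested child fraction must not exceed parent")
        child_alleles = {"second_mutation": ("mutA", "mutB"),
                         "upd": ("mutA", "mutA"),
                         "deletion": ("mutA", "deleted")}[child_type]
        parent_rest = f - fraction2
        clones = tuple(
            ([Clone(parent_rest, "mutA", "wt")] if parent_rest > 1e-12 else [])
            + [Clone(fraction2, *child_alleles)])
    else:
        raise ValueError(f"unknown config label {label!r}")
    return ClonalArchitecture(clones=clones, config_label=label)


def expected_vaf(arch: ClonalArchitecture, variant: str) -> float:
    """Expected bulk VAF of ``variant`` under the copy-number-aware mixture
    formula (module docstring)."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    num = sum(c.fraction * c.mut_copies(variant) for c in arch.clones)
    den = (sum(c.fraction * c.copy_number for c in arch.clones)
           + (1.0 - arch.total_fraction) * 2.0)
    return num / den


def combined_expected_vaf(arch: ClonalArchitecture) -> float:
    return sum(expected_vaf(arch, v) for v in arch.variants)


def bulk_decision_stat(arch: ClonalArchitecture) -> float:
    """The bulk arithmetic the classifier compares to 50%: summed expected
    VAF plus del(17p) clonality when a deletion-bearing clone exists."""
    return combined_expected_vaf(arch) + arch.del17p_fraction


def sample_bulk_vaf(true_vaf: float, depth: int,
                    rng: np.random.Generator) -> float:
    """Observed VAF under binomial read sampling at the given depth."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return float(rng.binomial(depth, true_vaf)) / depth


@dataclass
class SimulationParams:
    """Cohort-level generator settings.

    Defaults emulate the target setting: ~1000 TP53-mutant patients plus a
    wild-type background, exponential survival with median 42 months for
    patients without a biallelic clone and 14 months with one (hazard ratio
    3), uniform censoring over a 10-year horizon, sequencing depth around
    500x, and array-grade detectability of del(17p)/UPD clonality.
    """

    n_patients: int = 1000
    wt_share: float = 0.30
    mixture: dict = field(default_factory=lambda: {
        "het_mono": 0.30, "hemizygous": 0.15, "upd_hom": 0.15,
        "compound_het": 0.25, "mosaic_two_mono": 0.10,
        "nested_biallelic_subclone": 0.05})
    clone_fraction_beta: tuple[float, float] = (2.0, 2.0)
    #: biallelic clones sweep: fraction distribution for configurations
    #: whose clone already carries both hits (hemizygous, UPD-homozygous,
    #: compound heterozygous); monoallelic and nested-parent clones use
    #: clone_fraction_beta
    biallelic_fraction_beta: tuple[float, float] = (5.0, 2.0)
    #: probability that a detected del(17p) comes with a usable clonality
    #: estimate, and that the TP53 locus was assayed for UPD at all —
    #: clonality and CN-LOH data are not available for every sample in
    #: routine practice
    p_clonality_available: float = 0.5
    p_upd_tested: float = 0.3
    depth_mean: float = 500.0
    depth_dispersion: float = 5.0
    depth_fixed: Optional[int] = None
    lambda_low: float = math.log(2) / 42.0    # per month; median 42 mo
    lambda_high: float = math.log(2) / 14.0   # per month; median 14 mo
    tau: float = 0.0
    horizon: float = 120.0
    dropout: float = 0.10
    genotype_error: float = 0.01
    clonality_noise_sd: float = 0.02
    detection_limit: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lambda_high >= self.lambda_low > 0:
            raise ValueError("need lambda_high >= lambda_low > 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 <= self.tau <= 1:
            raise ValueError("tau must be in (0, 1]")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            self.mixture = {k: v / total for k, v in self.mixture.items()}


def simulate_survival(has_biallelic_clone: bool, params: SimulationParams,
                      rng: np.random.Generator) -> tuple[float, bool]:
    """Exponential event time at the flag-dependent hazard, censored
    uniformly on (0, horizon); returns (observed time, event observed)."""
    lam = params.lambda_high if has_biallelic_clone else params.lambda_low
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.uniform(0.0, params.horizon) if params.horizon > 0 else 0.0
    return (min(t_event, t_censor), t_event <= t_censor)


_SUBTYPE_PROBS = {"pAML": 0.31, "sAML": 0.11, "HR_MDS": 0.23,
                  "LR_MDS": 0.24, "MDS_MPN": 0.10, "other": 0.01}
_RESIDUES = "ARNDCQEGHILKMFPSTWYV"
_HOTSPOTS = (175, 220, 237, 248, 273, 282)


def _draw_fraction(params: SimulationParams, rng,
                   biallelic: bool = False) -> float:
    a, b = (params.biallelic_fraction_beta if biallelic
            else params.clone_fraction_beta)
    return float(np.clip(rng.beta(a, b), 0.02, 0.98))


def _draw_depth(params: SimulationParams, rng) -> int:
    if params.depth_fixed is not None:
        return int(params.depth_fixed)
    r = params.depth_dispersion
    p = r / (r + params.depth_mean)
    return int(max(30, rng.negative_binomial(r, p)))


def _draw_protein_change(rng) -> tuple[str, int, str]:
    """Random (hgvs_p, position, consequence) with hotspot enrichment."""
    u = rng.random()
    if u < 0.75:  # missense, mostly canonical
        if rng.random() < 0.69:
            pos = int(rng.choice(_HOTSPOTS)) + int(rng.integers(-5, 6))
            pos = int(np.clip(pos, 1, 393))
        else:
            pos = int(rng.integers(100, 351))
        ref, alt = rng.choice(list(_RESIDUES), size=2, replace=False)
        return f"p.{ref}{pos}{alt}", pos, "missense"
    if u < 0.95:  # truncating
        pos = int(rng.integers(20, 380))
        ref = rng.choice(list(_RESIDUES))
        suffix = "*" if rng.random() < 0.5 else "fs"
        return f"p.{ref}{pos}{suffix}", pos, "truncating"
    return "splice", 0, "splice"


def draw_architecture(label: str, params: SimulationParams,
                      rng: np.random.Generator) -> ClonalArchitecture:
    """Draw clone fractions for one configuration label."""
    if label == "mosaic_two_mono":
        fa, fb = _draw_fraction(params, rng), _draw_fraction(params, rng)
        if fa + fb >= 0.98:
            scale = 0.95 / (fa + fb)
            fa, fb = fa * scale, fb * scale
        return make_architecture(label, fa, fb)
    if label == "nested_biallelic_subclone":
        fp = _draw_fraction(params, rng)
        fc = fp * rng.uniform(0.1, 0.9)
        child = rng.choice(["second_mutation", "upd", "deletion"])
        return make_architecture(label, fp, fc, child_type=str(child))
    biallelic = label in ("hemizygous", "upd_hom", "compound_het")
    return make_architecture(label, _draw_fraction(params, rng, biallelic))


def generate_cohort(params: SimulationParams
                    ) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort plus its ground-truth table.

    The truth table has one row per patient: configuration label, biallelic
    clone fraction, the hazard flag actually used, and the noise-free
    combined VAF.  All randomness flows from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    labels = list(params.mixture)
    probs = np.array([params.mixture[k] for k in labels])
    subtype_names = list(_SUBTYPE_PROBS)
    subtype_p = np.array(list(_SUBTYPE_PROBS.values()))
    subtype_p = subtype_p / subtype_p.sum()

    patients: list[PatientRecord] = []
    truth_rows = []
    for i in range(params.n_patients):
        pid = f"SIM{i:05d}"
        is_wt = rng.random() < params.wt_share
        subtype = str(rng.choice(subtype_names, p=subtype_p))
        blast = {"pAML": rng.uniform(20, 90), "sAML": rng.uniform(20, 90),
                 "HR_MDS": rng.uniform(5, 19), "LR_MDS": rng.uniform(0, 4.9),
                 "MDS_MPN": rng.uniform(0, 19), "other": rng.uniform(0, 30),
                 }[subtype]
        if is_wt:
            os_time, os_event = simulate_survival(False, params, rng)
            patients.append(PatientRecord(
                patient_id=pid, os_time=os_time, os_event=os_event,
                subtype=subtype, blast_pct=round(blast, 1),
                cytogenetics=CytogeneticsProfile(
                    complex_karyotype=bool(rng.random() < 0.10))))
            truth_rows.append({"patient_id": pid, "config_label": "wild_type",
                               "biallelic_fraction": 0.0,
                               "has_biallelic": False,
                               "true_combined_vaf": 0.0})
            continue

        label = str(rng.choice(labels, p=probs))
        arch = draw_architecture(label, params, rng)
        mutations = []
        for j, v in enumerate(arch.variants):
            tv = expected_vaf(arch, v)
            depth = _draw_depth(params, rng)
            obs = sample_bulk_vaf(tv, depth, rng)
            hgvs, pos, cons = _draw_protein_change(rng)
            mutations.append(MutationCall(
                variant_id=f"{pid}_{v}", vaf=obs, protein_change=hgvs,
                aa_position=pos or None, consequence=cons, depth=depth))

        del_frac = arch.del17p_fraction
        upd_frac = arch.upd_fraction
        del17p = del_frac >= params.detection_limit
        clonality_known = del17p and rng.random() < params.p_clonality_available
        tp53_upd = (upd_frac >= params.detection_limit
                    and rng.random() < params.p_upd_tested)
        noise = params.clonality_noise_sd
        cyto = CytogeneticsProfile(
            del17p=bool(del17p),
            del17p_clonality=float(np.clip(
                del_frac + rng.normal(0, noise), 0, 1))
            if clonality_known else None,
            complex_karyotype=bool(
                rng.random() < (0.72 if arch.biallelic_fraction > 0 else 0.30)),
            tp53_upd=bool(tp53_upd),
            upd_clonality=float(np.clip(
                upd_frac + rng.normal(0, noise), 0, 1)) if tp53_upd else None,
        )
        has_biallelic = arch.biallelic_fraction > params.tau
        os_time, os_event = simulate_survival(has_biallelic, params, rng)
        patients.append(PatientRecord(
            patient_id=pid, os_time=os_time, os_event=os_event,
            subtype=subtype, blast_pct=round(blast, 1),
            mutations=mutations, cytogenetics=cyto))
        truth_rows.append({
            "patient_id": pid, "config_label": label,
            "biallelic_fraction": arch.biallelic_fraction,
            "has_biallelic": has_biallelic,
            "true_combined_vaf": combined_expected_vaf(arch),
        })
    truth = pd.DataFrame(truth_rows)
    cohort = Cohort(patients=patients,
                    provenance=f"simulated(seed={params.seed})")
    return cohort, truth


def generate_single_cell_matrix(arch: ClonalArchitecture, n_cells: int,
                                dropout: float, error: float,
                                rng: np.random.Generator
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a cells x variants genotype matrix from an architecture.

    Returns (observed, truth) DataFrames with one column per variant plus
    ``cn17p``.  Cells are multinomial over the clone mix (remainder =
    wild-type diploid cells).  Observation model: each physical allele is
    independently unobserved with probability ``dropout``; the call is made
    from the observed alleles only (no observed allele -> MISSING, all
    observed alleles mutant -> HOM_or_HEMI, mixed -> HET, none mutant ->
    WT); finally the call flips to a uniformly random different non-MISSING
    code with probability ``error``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    variants = arch.variants or ("mutA",)
    fractions = [c.fraction for c in arch.clones]
    wt_frac = 1.0 - arch.total_fraction
    probs = np.array(fractions + [max(wt_frac, 0.0)])
    probs = probs / probs.sum()
    clone_idx = rng.choice(len(probs), size=n_cells, p=probs)
    wt_index = len(arch.clones)

    cn = np.array([c.copy_number for c in arch.clones] + [2])
    cn17p = cn[clone_idx]

    obs_cols, truth_cols = {}, {}
    codes = np.array([GT_WT, GT_HET, GT_HOM, GT_MISSING])
    for v in variants:
        m = np.array([c.mut_copies(v) for c in arch.clones] + [0])
        k = cn
        m_cell, k_cell = m[clone_idx], k[clone_idx]
        truth_cols[v] = np.where(
            m_cell == 0, GT_WT,
            np.where(m_cell == k_cell, GT_HOM, GT_HET))
        m_obs = rng.binomial(m_cell, 1.0 - dropout)
        w_obs = rng.binomial(k_cell - m_cell, 1.0 - dropout)
        tot = m_obs + w_obs
        call = np.where(
            tot == 0, GT_MISSING,
            np.where(m_obs == 0, GT_WT,
                     np.where(m_obs == tot, GT_HOM, GT_HET)))
        if error > 0:
            flip = (rng.random(n_cells) < error) & (call != GT_MISSING)
            if flip.any():
                current = call[flip]
                choice = np.empty(current.size, dtype=object)
                alt = np.array([GT_WT, GT_HET, GT_HOM])
                for idx in range(current.size):
                    others = alt[alt != current[idx]]
                    choice[idx] = rng.choice(others)
                call = call.copy()
                call[flip] = choice
        obs_cols[v] = call
    cells = [f"cell{i:05d}" for i in range(n_cells)]
    observed = pd.DataFrame(obs_cols, index=cells)
    observed["cn17p"] = cn17p
    truth = pd.DataFrame(truth_cols, index=cells)
    truth["cn17p"] = cn17p
    truth["clone"] = np.where(clone_idx == wt_index, "wt_background",
                              [f"clone{j}" for j in clone_idx])
    return observed, truth
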