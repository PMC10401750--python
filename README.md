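# tp53state

Resolve the allelic configuration of *TP53* mutations in myeloid neoplasia
from routine bulk sequencing.

## The problem

*TP53* is inactivated in diverse genomic configurations — a single point
mutation, two mutations, mutation plus 17p deletion, or copy-neutral LOH
(uniparental disomy, UPD).  Prognosis hinges on whether *both* alleles are
knocked out within one clone (biallelic inactivation), but bulk NGS reports
only a VAF per variant: two mutations may sit in trans in one clone
(compound heterozygous, biallelic) or in two separate monoallelic clones
(subclonal mosaicism), and a seemingly monoallelic case may hide a cryptic
biallelic subclone.  `tp53state` implements a clinically applicable scheme
that imputes allelic state from bulk arithmetic and a survival-calibrated
VAF cutoff, plus the simulation and single-cell machinery to validate it.

## The classification scheme

For a patient with mutations at VAFs v₁ ≥ v₂ ≥ …, combined VAF
V = Σᵢ vᵢ, and del(17p) clonality d where known:

**Obligatory biallelic** (provable from arithmetic), any of
- one mutation with v₁ > 0.5 (more mutant alleles than cells ⇒ LOH),
- ≥ 2 mutations with V > 0.5,
- v₁ + d > 0.5 (mutation and deletion must overlap in some cells),
- a mutation with documented *TP53*-locus UPD.

**Ambiguous zone** (V ≤ 0.5): split at a combined-VAF cutoff c into
**probable biallelic** (V ≥ c) and **probable monoallelic** (V < c).
Patients with isolated del(17p) and no mutation are reported separately;
the traditional single/double-hit counting is also provided for
comparison.

The cutoff c is not arbitrary: because biallelic clones drive mortality,
`tp53state.cutoff` selects it by scanning a candidate grid (default
5–50% in 1% steps, minimum node size 15) with repeated 80/20
train/test splits, scoring each candidate by Harrell's concordance index
on the held-out fold over 30 runs.  The default c = 0.23 is the optimum
this procedure produces on cohorts whose hazard jumps at 23% combined VAF.

The clonal simulator generates cohorts from explicit clone architectures
(heterozygous, hemizygous, UPD-homozygous, compound heterozygous, two-clone
mosaic, nested cryptic biallelic subclone), with expected VAF

    VAF(v) = Σ_c f_c·m_c(v) / (Σ_c f_c·k_c + (1 − Σ_c f_c)·2)

(f_c clone fraction, m_c mutant copies, k_c locus copy number), binomial
read noise, exponential survival whose hazard depends on the presence of a
biallelic clone, and single-cell genotype matrices with per-allele dropout.

## Worked example

```sh
tp53state report --seed 7 --outdir demo_out
```

or equivalently from Python:

```python
from tp53state.report import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="demo_out")
cfg.sim.n_patients = 400
cfg.sim.seed = 7
summary = run_pipeline(cfg)
```

On this simulated 400-patient cohort (30% *TP53* wild type) the pipeline
prints group shares among mutant patients of

```
{"obligatory_biallelic": 50, "probable_biallelic": 34, "probable_monoallelic": 15}
```

and `demo_out/summary.json` contains, per state, the size and
Kaplan–Meier median overall survival:

| state                | n   | KM median (months) |
|----------------------|-----|--------------------|
| obligatory biallelic | 141 | 14.9               |
| probable biallelic   |  96 | 30.1               |
| probable monoallelic |  43 | 24.5               |
| wild type            | 120 | 43.0               |

The obligatory group dies fastest (its hazard is driven by dominant
biallelic clones), the probable-biallelic group is intermediate, and the
probable-monoallelic group is statistically indistinguishable from wild
type (unadjusted log-rank p = 0.155 here) — the qualitative pattern the
scheme is designed to produce.  Its median can sit below the
probable-biallelic one in a single small cohort, as here (n = 43), and the
default mixture deliberately plants cryptic biallelic subclones below the
cutoff.  The report also cross-tabulates against traditional hit counting:
45.7% of the 116 traditional single-hit cases are upstaged to probable
biallelic.

Other entry points: `tp53state simulate`, `tp53state classify`,
`tp53state optimize-cutoff`, `tp53state sc-analyze` (see `--help`).

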