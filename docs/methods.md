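# Methods

## Allelic-state model

The unit of classification is a patient with a set of TP53 mutation VAFs,
cytogenetics flags (del(17p) with optional clonality, TP53-locus UPD) and
overall survival.  The decision variable is the combined VAF, the sum of
VAFs over all TP53 mutations, capped at 1.

The obligatory-biallelic rules are pigeonhole arguments on bulk allele
counts.  With one mutation at VAF v in a diploid locus, v > 0.5 means more
mutant alleles than cells, so some cells carry two mutant copies (UPD) or
have lost the wild-type allele.  With two mutations summing above 0.5,
some cell must carry both.  With a deletion of clonality d, v + d > 0.5
forces mutation and deletion to co-occur in some cells; the rule uses the
*maximum* single-mutation VAF rather than the sum, because summing distinct
mutations against one deletion would double-count mosaic clones.
Documented UPD together with any mutation demonstrates LOH directly and is
treated as obligatory even at low VAF.  All three thresholds are strict
(> 0.5).  The rules are one-sided: they prove biallelic involvement but
their failure proves nothing, which is why the remainder of the mutant
cohort (combined VAF ≤ 0.5) is split probabilistically at the cutoff.

Boundary conventions: combined VAF exactly at the cutoff is assigned to
probable biallelic (the higher-risk class); isolated del(17p) without a
mutation is reported as `del17p_only` and excluded from the three groups
(the scheme is defined for mutation carriers), while the traditional
classifier still counts it as a single hit; UPD without any mutation is
not a hit.  del(17p) with unknown clonality disables only the
VAF-plus-clonality rule.

## Cutoff selection

The survival-calibrated cutoff search treats outcome as a surrogate label
for allelic state.  Two components:

- `propose_splits`: all midpoints between consecutive distinct combined
  VAFs that leave ≥ `min_node` (default 15) subjects per side, scored by
  the two-group log-rank chi-square.  With a single covariate this is
  exactly the split criterion of a survival tree, so an ensemble of such
  trees adds nothing but resampling noise; the explicit scan replaces it.
- `cross_validate`: every cutoff on a fixed grid (default 0.05–0.50 by
  0.01) is evaluated on `n_runs` = 30 random 80/20 train/test splits.  On
  the training fold the risk orientation is learned (the side of the
  cutoff with the lower Kaplan–Meier median is high-risk; if neither side
  reaches its median the high-VAF side is assumed high-risk); the test
  fold is scored with Harrell's C on the induced binary risks.  Degenerate
  splits (one side empty, or no comparable pair) yield NaN and are dropped
  from that cutoff's mean, with the count reported.  The selected cutoff
  maximizes the mean held-out C, ties to the smaller cutoff.  The whole
  procedure is a pure function of (data, seed).

Split sampling is unstratified by default, with an optional
event-stratified mode (`stratify_events=True`).

## Survival machinery

Kaplan–Meier, the k-sample log-rank test and the concordance index are
direct numpy implementations (the optimizer calls them ~10⁵ times per
search); they are verified against lifelines to 1e-6 in the test suite.
The Cox model delegates to lifelines (Efron tie handling, 95% Wald
intervals) — ties are common in month-resolution data.  The KM median is
the first event time where S(t) ≤ 0.5 (right-continuous step function).

Concordance convention: a pair is comparable iff the strictly shorter
observed time belongs to a subject with an observed event; equal observed
times are never comparable (including event-vs-censored at the same time);
risk ties count 1/2.  The negation identity C(r) + C(−r) = 1 and
invariance under strictly monotone risk transforms follow and are tested.

## The simulator as study stand-in

Because the motivating cohort is not public, every quantitative claim is
validated on simulated cohorts with known truth.  Defaults (one place:
`SimulationParams`):

| parameter | default | rationale |
|---|---|---|
| n_patients | 1000 | cohort of ~1000 TP53-mutant patients |
| wt_share | 0.30 | wild-type comparison arm without simulating 6× excess |
| mixture | het 30 / hemi 15 / UPD 15 / compound 25 / mosaic 10 / nested 5 % | spans every configuration class incl. cryptic subclones |
| clone_fraction_beta | Beta(2,2) | diffuse monoallelic clone sizes |
| biallelic_fraction_beta | Beta(5,2) | biallelic second hits are typically sweeping, large clones |
| depth | NegBin(mean 500, disp 5), floor 30 | clinical panel depths |
| λ_low, λ_high | ln2/42, ln2/14 per month | median OS 42 mo without vs 14 mo with a biallelic clone (HR 3), matching the reported wild-type-like and biallelic medians |
| horizon | 120 mo | uniform censoring over 10-year follow-up |
| τ | 0 | any biallelic clone elevates hazard; the critical clone size is unknown, so the most pessimistic convention is the default and τ is exposed for sensitivity analyses |
| detection_limit | 0.20 | array-based clonality calls miss clones under ~20% |
| p_clonality_available / p_upd_tested | 0.5 / 0.3 | clonality and CN-LOH assays are not available for every sample in routine data |
| dropout / genotype_error | 0.10 / 0.01 | plausible single-cell platform rates; no published values exist, free parameters |
| clonality_noise_sd | 0.02 | array clonality estimates are noisy |

Expected VAF uses the copy-number-aware mixture formula; closed forms for
single-clone architectures are f/2 (heterozygous), f/(2−f) (hemizygous),
f (UPD-homozygous), f/2 per variant for compound heterozygous.  The bulk
decision statistic (summed expected VAF plus del(17p) clonality) obeys the
dichotomy the classifier relies on: a biallelic clone above half the cells
forces it above 50%, and purely monoallelic architectures stay strictly
below 50%.  The converse does not hold in general — a hemizygous clone at
35% or a small biallelic subclone under a large heterozygous parent can
push the statistic above 50% without a dominant biallelic clone — which is
precisely why the sub-50% zone needs the probabilistic split.

Single-cell observation model: each physical allele drops out
independently with probability d; the genotype call uses observed alleles
only (none → MISSING; all observed mutant → HOM_or_HEMI; mixed → HET;
none mutant → WT), then flips to a random different code with the error
probability.  Consequences: a homozygous cell reads MISSING with
probability d² and HOM otherwise; a heterozygous cell reads WT (mutant
allele dropped) or HOM (wild-type allele dropped) with probability d(1−d)
each.  Per-cell allele counting in `reconcile_bulk` therefore undercounts
mutant alleles by the factor (1−d²) in diploid cells — the HET→HOM
miscalls exactly offset the HET→WT ones — and the dropout-corrected
estimate divides by it.

What the simulator does **not** model: tumor purity, sequencing error
beyond binomial sampling and the genotype flip, biallelic deletion of both
17p copies, co-mutations in other genes, doublets, non-exponential or
covariate-dependent baseline hazards.  Passing tests therefore show the
pipeline is correct under its own generative assumptions, not that the
23% cutoff or the survival contrasts transfer to any particular clinical
cohort.

## Single-cell analysis choices

A cell is biallelic iff it carries ≥ 2 distinct mutant variants, any
HOM_or_HEMI call, or any mutant call with a single 17p copy.  MISSING is
treated as WT, so raw biallelic cell fractions undercall under dropout;
this conservative convention matches how per-case cell percentages are
usually reported, and the dropout-corrected bulk reconciliation is
reported alongside.  Mosaic-vs-biallelic verdicts use a one-sided Fisher
exact test on the 2×2 mutant co-occurrence table (α = 0.01) plus a
co-mutant floor of 1% of cells; fewer than 20 informative cells →
indeterminate.  HOM_or_HEMI is read as hemizygous when cn17p = 1 and as
UPD-homozygous otherwise.

## Numerical and testing notes

- All randomness flows through `numpy.random.default_rng` seeded per call;
  nothing touches global state.  Identical seeds give bit-identical
  cohorts, search results and reports (config hash + seed stamped in every
  artifact).
- VAFs are fractions internally; table readers treat values > 1 as
  percentages.
- The KM-ordering check (obligatory ≤ probable biallelic ≤ probable
  monoallelic, and probable monoallelic ≈ wild type) is asserted over 20
  replicates at n = 2000 under the dominant-clone mixture *without* the
  nested-cryptic-subclone configuration: a hidden biallelic child clone
  raises the hazard while staying invisible to bulk arithmetic, so
  including it degrades the probable-monoallelic group's survival by
  construction — the phenomenon the probabilistic tiers exist to flag.
  Under the full default mixture the ordering still holds in most but not
  all replicates.
- Test problem sizes (10⁴ records for rule-oracle equivalence, 5×10³
  architectures for the dichotomy, 800 patients × 20 repetitions for
  cutoff recovery, 500 cells × 200 replicates per class for verdict
  accuracy) were chosen so the whole suite runs in about a minute on one
  CPU while keeping Monte-Carlo margins far from the asserted thresholds.
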