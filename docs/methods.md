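# Methods

This note documents the models, rules and numerical conventions the package
implements, the assumptions behind the synthetic-data generator, and the
design decisions taken where several readings were defensible.

## Variant model

Variants are named on the primary translation product of transcript
NM_001005742, whose first 39 residues are the signal peptide.  Mature-protein
numbering (used by the GCase crystal structures and the legacy Gaucher
literature) is `full − 39`; positions 1–39 have no mature image and are
reported as *unmapped signal peptide*, a status rather than an error, because
variants there (e.g. p.K13R) are still valid sequence variants.

Severity follows the PD-field convention with the total order
`SEVERE > MILD > RISK > VUS > BENIGN`; synonymous variants outside splice
regions are carried as `SYNONYMOUS_UNCLASSIFIED`, below the order.  The
packaged catalog (`data/known_variants.tsv`) lists the classes of the
variants observed in the study cohort plus the structural anchor variants
(p.C62W, p.V433L, p.W432R, p.N435T); rows with unknown classes are rejected
at load.  Classification of a variant proceeds: catalog hit → cataloged
class; otherwise exonic/splice variants annotated pathogenic in ClinVar →
severe (fallback source recorded); otherwise VUS; synonymous non-splice →
unclassified.  A catalog hit always overrides the ClinVar fallback.

A recombinant (complex) allele is named only when *all* of its components
occur on one phased haplotype; single-amplicon long reads make phase
knowable, so unphased multi-variant samples trigger a warning and no named
call.  A strict component subset — e.g. p.A495P + p.V499V without p.L483P —
is reported as co-occurring variants, never as the named allele, and keeps
the components' own classes (both observed carriers of that pair are
handled as VUS co-occurrence; the literature assigns no class to the partial
recombinant).  Carrier-level class is the maximum severity over a person's
variants (order- and duplication-invariant; homozygosity does not raise the
class), which reproduces the published handling of multi-variant carriers
such as p.N409S + p.L483P (severe).

## Concordance

The unit of comparison is the **carrier event**: (sample, variant) or
(sample, named recombinant).  Components of a phased recombinant collapse to
one event before scoring, so a platform reporting the named allele and one
reporting three phased components earn the same counts.  TP/FP/FN are set
intersections/differences against the Sanger-validated gold standard;
TPR = TP/(TP+FN), callset FDR = FP/(TP+FP); an empty gold standard leaves
TPR undefined (`None`), never 0 or 1.

Filtering predicates (applied before scoring, order preserved, one audit
count per predicate): QUAL strictly > 30; gnomAD non-Finnish-European MAF
strictly < 1%; study-wide carrier frequency strictly < 1% (guarding against
pseudogene-driven over-calls on arrays); coordinates inside the target
region chr1:155,232,501–155,241,415 (GRCh38, 1-based inclusive).

Formatting conventions differ by table family in the source material and
are both provided: concordance rates and odds ratios *truncate* to one
decimal (1/6 → "16.6%", 1.6957 → "1.6"), carrier-frequency percentages
*round* (77/637 → "12.1%").  The full-cohort comparison reports 135
validated carriers; the printed TPR "(36/133)" is inconsistent with that
count and is treated as a typo — this package uses 36/135.

## Exclusion cascade

Steps run in the order the study narrative describes: (1) carriers of
pathogenic point mutations or CNVs in other PD genes; (2) one proband per
family — among case members the earliest age at onset wins, ties broken by
smallest id, control-only families keep the smallest id, and a mixed family
keeps a case by default (the source only specifies the case rule; retaining
the case maximizes case information and is configurable); (3) healthy
controls with a first-degree PD relative and age at assessment strictly
below 60; (4) ancestry outliers, |PC − mean| > 3 SD on PC1 or PC2, with
mean/SD computed once on the table as supplied (the PCA itself is an input).
The audit conserves counts at every step and the cascade is idempotent.
Whether the published exclusions overlapped is not stated; the packaged
fixture is built non-overlapping so each step removes exactly the printed
count (14, 64, 74, 6 from 1568 → 1410).  The published group split of the
six ancestry outliers is not printed; 3 patients + 3 controls is forced by
the remaining margins (735 patients, 675 HC).

## VUS triage rules

Evidence channels: carrier context (patients vs controls; any carrier with
age at onset ≤ 45 counts as early-onset — the methods text says "equal to or
younger than 45", the demographics table is labeled "< 45"; the inclusive
reading is the default and a strict switch exists), categorical
deleterious/tolerated calls from REVEL and CADD (numeric fallbacks
REVEL ≥ 0.5, CADD-phred ≥ 20 are a documented extrapolation — the study
works from D/T calls), the dbscSNV splice flag (ada ≥ 0.6 or rf ≥ 0.6,
contributing one D/T call for splice-region variants), and HGMD/ClinVar
labels.

Rule order: (1) patients-only AND (all present calls deleterious OR any
early-onset carrier) → probably severe; (2) carriers in both arms OR
disagreeing calls OR HGMD "PD susceptibility" → probably risk; (3)
patients-only AND all calls tolerated → probably mild; (4) controls-only →
probably benign.  The disagreeing-calls branch deliberately outranks the
tolerated-consensus branch (this is what places p.R78C and p.E427K at
risk).  Database labels feed only the risk rule; the all-deleterious test
uses numeric predictors.  Zero carriers (or no usable evidence) raise an
explicit unclassifiable error rather than guessing.

Structural proximity hits are appended to the rationale as supporting
evidence and never change the base verdict, with one opt-in exception: a
tolerated-consensus, patients-only variant sitting in an isolated coil with
no proximity hits may be downgraded to probably benign.  The override is
off by default because it contradicts the controls-only semantics of the
base benign rule; it is exactly what the published subclassification applies
to p.A97G, so the packaged 12-VUS run enables it.

Carrier z-scores standardize one carrier's clinical score against a
reference group, `(x − mean)/SD`, using the sample SD (ddof = 1) or
published summary values; a zero SD is an error.

## Structural proximity

The Cα model is parsed from standard PDB text (any GCase structure in
mature numbering, e.g. accession 1ogs, works; no structure ships with the
package).  Alternate locations resolve to the highest occupancy, first
listed on ties; residues lacking a Cα are recorded as gaps; insertion codes
are rejected.  A VUS is proximal to a known pathogenic variant when the
sites are ≤ 2 residue positions apart in sequence — the threshold is read as
*residue* positions since the entities compared are amino-acid variants —
or their Cα atoms are strictly < 5.0 Å apart.  The sequence rule is
evaluated on full-translation numbering (distances are identical in mature
numbering) and therefore covers signal-peptide variants; the spatial rule
needs both mature positions present in the model.  The relation is
symmetric and monotone in both thresholds, and matches an exhaustive
all-pairs oracle on toy structures.

## Association statistics

Unadjusted odds ratios use the cross-product ad/bc with the Woolf interval
`exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))` and the Haldane–Anscombe +0.5 on all
cells whenever one is zero; zero margins are errors.  Both Fisher-exact and
Wald p values are attached, since the significance test behind the
published frequency-table p values is unspecified; neither is asserted
against print.  Genotype–phenotype models are OLS (continuous scales) or
binomial GLM (binary symptoms) of the outcome on carrier status adjusted
for sex, age at assessment and disease duration, with listwise deletion per
outcome and explicit degenerate-fit errors (constant outcome/predictor,
unstable standard errors).  Three comparison families run on PD patients
with VUS-only and synonymous-only carriers excluded from every arm:
pathogenic vs non-carrier, each class vs non-carrier, severe vs mild+risk.
Benjamini–Hochberg (step-up with monotonicity, statsmodels backend) is
applied within each family.

The BH worked examples reproduce the published adjusted values from the
published unadjusted columns.  One reconstruction was needed: the
severe-vs-non-carrier column prints 35 p values, but every printed adjusted
value implies a 36-test family (0.0099·36/2 = 0.1782, 0.0405·36/3 = 0.486,
0.1991·36/14 = 0.5119, 0.4922·36/25 = 0.7088, 0.914·36/34 = 0.9678) with
the unprinted member between 0.1115 and 0.1991; the packaged vector
completes the family with 0.15, which leaves every printed value unchanged.

The published *adjusted* regression coefficients are not reproducible
without the restricted cohort data; they are covered instead by
parameter-recovery properties on synthetic cohorts (below).

## Synthetic cohorts

Defaults encode the study conditions: 660 PD / 100 atypical parkinsonism /
808 HC; age at onset ~ Normal(63, 11.5) truncated to [18, 90]; disease
duration ~ Normal(5, 5) truncated to [0, 30] with age at assessment =
onset + duration; HC assessment age ~ Normal(61, 11.5) truncated to
[30, 95] (truncation bounds are an implementation choice); 66.4% male
patients, 52.7% male controls; carrier-class frequencies per arm at the
observed post-exclusion rates (e.g. pathogenic 67/637 in PD, 29/675 in HC)
with per-class variant pools; two-person family clusters that never span
the case/control boundary unless configured; ancestry PCs ~ Normal(0, 0.01)
with rare 1.0-shifted outliers.  Continuous outcomes are linear in carrier
class, sex, centered assessment age and duration plus Gaussian noise;
binary outcomes use a logistic link; missingness is completely at random at
roughly the observed per-outcome rates.  Default effect sizes place the
published direction of severe-carrier burden (e.g. +4 points on the
non-motor experiences scale, +1.2 log-odds of hallucinations) and zero
effects elsewhere.

Randomness is split into named substreams (structure, genotype, clinical,
missingness) spawned from one mandatory seed; re-seeding the clinical
stream never changes genotypes, and equal seeds give byte-identical
cohorts.  Platform error models drop each true carrier event independently
(false-negative rate) and inject false calls per sample from a configurable
pool (e.g. the array profile calibrated to 36/135 recovered and 11 false
calls over 1568 samples).

What the generator does **not** emulate: linkage/haplotype structure,
read-level errors, pedigrees beyond first-degree flags, informative
missingness, or correlated clinical scales.  Passing recovery tests
therefore demonstrate the estimators' correctness under the assumed
generating model, not robustness to real-data violations of it.

In-package fixtures (`gba1pd.fixtures`) are hand-built, seedless tables
reproducing the published counts cell by cell; they are data, not samples.

## Verification scales

The test suite and `scripts/acceptance.py` run everything at desk scale:
printed-count fixtures (72, 1410 and 1568 rows), toy structures of ≤ 50
residues, and 200 seeded replicates of 1200-participant cohorts for the
CI-coverage properties (nominal 95%, accepted within ±3 binomial SE).
These sizes were chosen to make every check exact or statistically sharp
while keeping a full run to seconds.

## Known limitations

* Severity classes cover the variants observed in this cohort plus
  structural anchors, not the full mutation literature; unknown variants
  fall back to ClinVar or VUS.
* Genotype-level (het/hom) and phasing-accuracy concordance are out of
  scope; carrier events are the unit throughout.
* The published frequency-table confidence intervals come from adjusted
  regressions on restricted data; this package's unadjusted Woolf intervals
  are close but not identical (e.g. severe: [2.7, 49.1] vs printed
  [2.6, 49]).
* The discrepancy between the published text ("family history OR = 0.74")
  and table ("OR = 1.74") for the same comparison is reproduced in the
  table's direction (25/67 vs 141/554 → 1.74) and otherwise left as-is.
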