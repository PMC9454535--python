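# Methods

This note documents the models, decision rules and numerical choices
behind `llskit`, and what its synthetic cohorts do and do not emulate.

## Variant model and input normalization

A variant call is a single `(patient, chrom, pos, ref, alt)` record with
its annotations: gene symbol, transcript, coding/protein HGVS, a
consequence class, read depth and variant allele fraction (VAF),
per-database population allele frequencies, ClinVar/InterVar assertions,
REVEL and M-CAP scores, and a binary splice-impact verdict. Annotations
are consumed, never computed: the pipeline starts downstream of variant
calling and annotation.

On ingest, multi-allelic VCF records are split one variant per alternate
allele, with the per-allele VAF taken from a `VAF` FORMAT field or
computed as `AD[alt]/DP` (falling back to `sum(AD)` when `DP` is absent).
Indels are reduced to minimal representation by trimming shared
suffix/prefix bases. Full left-alignment would additionally require the
reference genome, which is not an input of this package; inputs are
expected to come from a normalizer (e.g. `bcftools norm`) when ambiguous
placements matter. INFO keys are remappable through a dialect config so
annotation output from different tools can be ingested without renaming.

VCF floats are stored by htslib in 32-bit precision; the reader
renormalizes them to 6 significant digits, which makes write→read
round-trips exact for annotation values printed with up to six
significant figures (all score and frequency annotations used here).

The HGVS parser covers only the subset needed for coding-level variant
fixtures — substitutions (including intronic offsets such as
`c.1375-2A>G`), deletions, duplications and delins — and refuses anything
else explicitly rather than misparsing. Parsing and rendering are
mutually inverse on this subset.

## Prioritization cascade

Filters are applied per variant in a fixed order, so each removed variant
carries a single reason (`low_depth`, `low_vaf`, `common`, `off_panel`,
`no_route`):

| Filter | Keep when | Default |
|---|---|---|
| depth | `depth >= min_depth` | 30 reads |
| VAF | `vaf >= min_vaf` | 0.25 |
| population MAF | `af <= max_maf` in *every* declared database | 0.01 |
| panel | case-normalized gene symbol in panel | — |

Boundary semantics are the literal reading of the documented thresholds:
"fewer than 30 reads" removes depth ≤ 29; "below 25 %" removes VAF <
0.25; "MAF > 1 %" removes anything strictly above 0.01. A variant absent
from all population databases is treated as rare; the removal rule is
"any declared database exceeds the bound". In-silico thresholds are
strict: REVEL > 0.7, M-CAP > 0.025; missing scores never satisfy a
threshold.

Survivors route to manual classification with precedence
`reported_pathogenic` (ClinVar or InterVar pathogenic/likely pathogenic —
conflicting assertions do not count) → `lof` (nonsense, frameshift,
canonical splice donor/acceptor) → `insilico_missense` →
`insilico_splice` (splice-impact verdict on a non-LoF consequence). The
precedence affects only the route label, not membership of the selected
set; it is chosen so the most actionable evidence names the route.
Because all filters are pure per-variant predicates, the selected set is
invariant under permutation of the filter order (verified by a property
test), so whether the panel restriction runs before or after QC is
immaterial.

In-frame indels are not counted as LoF; they can still be selected via a
reported-pathogenic assertion. The upstream visual review (IGV) and
Sanger confirmation steps of a clinical workflow are represented by a
per-variant `manual_review` flag carried into reports, defaulting to
not-reviewed.

## ACMG classification

Evidence codes split into automatically assignable and manual-only.
Auto codes, computed from the annotations:

- **PVS1** — LoF consequence in a gene flagged (via config) as having LoF
  as an established disease mechanism;
- **PM2** — frequency < 1e-4 in every declared database, or absent from
  all (the 1e-4 bound is a package default, configurable; the guideline
  gives no number);
- **PP3** — REVEL > 0.7, M-CAP > 0.025, or a splice-impact verdict;
- **BP4** — all present scores at/below threshold *and* an explicit
  no-impact splice verdict;
- **BA1** — any frequency ≥ 0.05 (guideline stand-alone bound);
- **BS1** — any frequency > 0.01 (configurable disease-frequency bound).

Everything requiring literature, segregation, functional or case-level
data (PS1–4, PM1/3–6, PP1/2/4/5, BS2–4, other BPs) enters through a
curation TSV with per-code provenance. Codes are combined per the 2015
ACMG/AMP combining rules with fixed code strengths (no PVS1 downgrades or
strength modulation). Satisfying both a pathogenic-side and a benign-side
rule, or neither, yields VUS; BA1 is stand-alone benign. The combiner is
checked exhaustively against an independently transcribed rule table over
all 512 subsets of a representative nine-code vocabulary, plus random
subsets of the full vocabulary.

Tiers map bijectively to the clinical Roman numerals: benign I, likely
benign II, VUS III, likely pathogenic IV, pathogenic V.

The shipped eight-variant fixture reproduces a published table of class
IV/V findings. Its HGVS strings, REVEL scores, gnomAD frequencies, tumor
contexts and final classes are published values; the genomic coordinates,
consequence/splice annotations and the manual curation codes are
reconstructions consistent with the per-variant prose (the source reports
final classes only). Four of the eight reach their printed class from
automatic evidence alone (PVS1 + PM2 ± PP3); the other four need two to
four curated codes.

## Triage

Decision table over IHC loss × BRAF × MSI (methylation never blocks
testing):

- loss includes MLH1 → test if BRAF V600E wild-type **or** inconclusive
  (an inconclusive assay does not demonstrate the sporadic-origin
  mutation, matching clinical practice of including such cases); no test
  if mutant; explicit `needs_braf` if untested — never a silent default;
- loss of PMS2/MSH2/MSH6 without MLH1 → test, no BRAF gate;
- no IHC loss → test only if MSI-positive (MSI without protein loss does
  occur and is eligible), otherwise excluded.

The function is total over all combinations (enumeration-tested).

## Statistics

- **Fisher's exact test** (2×2, two-sided) uses the probability-mass
  method: the p-value sums hypergeometric probabilities, over all tables
  with the observed margins, not exceeding the observed table's
  probability (relative tie tolerance 1e-7). Implemented via
  `scipy.stats.fisher_exact` and verified against a full-enumeration
  oracle with exact binomial coefficients to 1e-12. Zero-margin tables
  return p = 1 with a warning.
- **Chi-square** is Pearson's statistic without continuity correction by
  default (flag available), df = 1; zero expected counts raise an error
  directing to Fisher. The pipeline's selection policy — Fisher whenever
  any expected count < 5, else chi-square — is a package convention.
- **One-way ANOVA** is the classical between/within decomposition; for
  two groups the p-value equals the pooled two-sample t-test (property-
  tested to 1e-10). Constant data with equal means returns F = 0, p = 1.
- **Kruskal–Wallis** uses tie-corrected ranks with the chi-square
  approximation, verified against the direct rank formula under heavy
  ties.
- Percentages are reported to one decimal with half-up rounding, which is
  what reproduces 33.5 / 63.9 / 2.5 from counts 107/204/8 of 319.
- A *carrier* is a patient with at least one class IV/V variant.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes:
20 patients by default; first-diagnosis ages Normal(48.2, 7.7) truncated
at 18; first-tumor sites colorectal/endometrium/ovary/stomach at
0.75/0.10/0.10/0.05; 60 % female (gynecologic tumors forced female);
about a quarter of patients with a later second tumor; clinical criteria
mixed 25 % Amsterdam / 40 % Bethesda / 35 % revised Bethesda. Half the
cohort is MLH1/PMS2-deficient with 60 % of those *MLH1*-methylated (one
BRAF-inconclusive case, the rest wild-type); the remainder cycles
MSH2/MSH6-type losses and one MSI-positive case without IHC loss.

The carrier fraction (0.35) is applied exactly — `round(0.35·n)` patients
receive one planted class-IV/V-capable variant (alternating
reported-pathogenic nonsense and rare LoF in a LoF-mechanism gene, both
of which reach tier IV/V from automatic evidence alone). All other
planted categories are drawn per patient at fixed counts (3 common,
2 low-depth, 2 low-VAF, 2 off-panel, 3 unsupported VUS, 1 high-score
missense, 1 splice-impact): pool sizes are a package choice, exposed in
config, since no per-patient pre-filter counts are available to emulate.
Category definitions guarantee the branch each category targets (e.g.
common ⇒ MAF > 1 %, low-depth ⇒ < 30 reads), so planted-recovery tests
have exact expectations: retainable categories must all be selected,
removable ones all removed. In synthetic cohorts every panel gene is
treated as LoF-mechanism for PVS1 purposes.

What the simulator does **not** emulate: linkage/haplotype structure,
realistic per-gene mutation rates, pedigrees (family history is a tumor
count only), mosaicism or low-level somatic contamination, and real
annotation noise (e.g. discordant ClinVar/InterVar assertions, score
disagreement). Passing recovery tests therefore demonstrates the
correctness of the decision logic under the stated annotation semantics,
not the clinical sensitivity of the thresholds on real exomes.

Generation is deterministic given the seed (NumPy PCG64); writing the
same cohort twice produces byte-identical files.

## Problem sizes and tolerances

Default verification sizes: oracle-equivalence over 1000 random variants
spanning all threshold boundaries; a 4·3·3·4·4 adversarial boundary grid;
500 random contingency tables (total ≤ 40) against the Fisher
enumeration oracle; 2000 null simulations (two groups of 15) for the
ANOVA type-I calibration at α = 0.05 with acceptance band 0.05 ± 0.01;
10,000 ages for the CLT check of the age model. Exact comparisons use
1e-12 (Fisher vs enumeration) and 1e-10 (rank/t-test identities).

## Known limitations

- The HGVS subset excludes UTR (`c.-…`, `c.*…`) coordinates, inversions
  and protein-level syntax.
- PVS1 depends on a user-supplied LoF-mechanism gene list; no ClinGen
  gene-specific rule specifications are applied.
- Evidence strengths are fixed; later ACMG refinements (PVS1 decision
  trees, PP3/BP4 calibration) are out of scope.
- Population-frequency reasoning uses overall AFs; no subpopulation
  maxima or allele-number filters.
- The statistics module performs no multiple-testing correction, matching
  its descriptive use on small cohorts.
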