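# Methods

## Scope and data model

The package analyzes annotated variant-call tables (MAF-like TSV or VCF
text with a CSQ-style INFO field), fusion-call tables, clinical tables and
a background somatic-mutation catalogue. It does not align reads, call
variants, detect fusions/ITDs from reads, or annotate consequences —
those live upstream; their outputs are this package's inputs. Internal
tandem duplications and the CBL exon 8/9 focal deletion are consumed as
annotated events (they are detected by specialized split-read tools
upstream) and enter the driver set without further testing.

Conventions: genomic and protein positions are 1-based; indel alleles are
VCF-style left-aligned; a missing optional annotation (COSMIC count,
population frequency, SIFT/PolyPhen, ClinVar) is represented as absent,
never zero-filled — an absent 1000 Genomes frequency means "not observed
in 1000 Genomes", which several rules treat as evidence.

## Variant triage

Five exclusions (Ig/TCR locus, mutant reads < 3 or depth < 8, 1000
Genomes frequency > 0.001, consequence outside the protein-altering
vocabulary, artifact-blacklist membership) are evaluated as a set, so the
fired set is order-independent. Thresholds are inclusive on the keep
side: depth 8 with 3 mutant reads passes; 1000G frequency exactly 0.001
passes.

Levels: L1 on any of five criteria (c1 COSMIC ≥ 3 tumors and VAF ≥ 0.1;
c2 prior pediatric-cancer report; c3 loss-of-function consequence in a
known tumor suppressor; c4 ClinVar Pathogenic/Likely Pathogenic; c5
VAF > 0.1, SIFT deleterious, PolyPhen damaging, cancer-gene-census
membership, absent from 1000 Genomes); else L2 when COSMIC ≥ 3 and
(VAF ≤ 0.1 or absent from 1000 Genomes); else L3. Design choices where
the protocol sentence is ambiguous:

* The L2 clause is read as `recurrent AND (subclonal OR absent-from-1000G)`.
  The alternative reading (`(recurrent AND subclonal) OR absent`) would
  grade nearly every novel variant L2, which defeats the tiering.
* VAF exactly 0.1 satisfies both the L1 "≥ 0.1" and the L2 "≤ 0.1"
  clauses; L1 wins by precedence. This makes the level monotone in VAF
  and COSMIC count (a property test asserts it).
* The PolyPhen damaging set is {possibly_damaging, probably_damaging}:
  the stronger call must not fail a criterion the weaker one passes.
* Tumor-suppressor and cancer-gene-census memberships are input
  flags/lists, not live database queries.

The artifact blacklist is either supplied or derived from the cohort:
sites called in more than 5% of samples (default) are blacklisted unless
whitelisted as known hotspots. Recurrence-based derivation is a
documented, parameterized stand-in for manual curation; the fraction and
whitelist are config.

Ig/TCR intervals ship as editable BED-style config (IGH/IGK/IGL/TRB/TRA
on GRCh37); any interval set can be substituted.

## Driver nomination

A candidate is nominated when it carries a gold pathogenicity medal
(input annotation) or clusters within published somatic mutations. The
cluster statistic: window probability π = min(1, (2W+1)/L_g) under a
uniform-over-coding-sequence null, exact binomial upper tail
P(X ≥ x | N_g, π) on the background count x within ±W amino acids of the
candidate, W = 5 by default, BH adjustment globally across the candidate
batch, significance q < 0.05. Two deliberate properties:

* The candidate's own occurrence is *not* counted in x — the catalogue is
  external background, so a singleton novel variant cannot inflate its
  own evidence.
* A gene absent from the catalogue yields an undefined p flagged
  "no background" rather than a default value; such candidates can only
  be nominated by medal.

The null and W are the simplest defensible choices for positional
clustering and are config-exposed. Operating characteristics are
verified empirically: on uniform backgrounds the q < 0.05 fraction stays
within the binomial band around 5% (FDR control), and with half of
N_g = 50 background mutations inside one 11-aa window of a 500-aa gene,
detection exceeds 80%.

## Landscape statistics

Hotspot definitions are data: explicit amino-acid ranges (FLT3-TKD
835–836, FLT3-AL 829–858, KRAS-PL 10–17, CSF3R-CY 651–831) or exons
resolved through a bundled exon→aa table (KIT exon 8 = 417–448, exon 17 =
788–828 on the canonical transcript NM_000222; users pinning a different
transcript edit the table, not the code). Overlapping hotspots each
label the mutation (FLT3 aa 835 is both TKD and AL) and the gene-level
feature is always retained; downstream analyses select features
explicitly.

Cross-cohort comparison: per-feature two-sided Fisher exact tests on
mutated × cohort 2×2 tables, overall and within age strata < 3 y and
3–14 y (exactly 3.0 falls in the older stratum), BH-adjusted within each
stratum. Pairwise co-occurrence uses the same exact test over all
unordered feature pairs, FAB groups included as pseudo-features; the
direction comes from the 2×2 cross-product; constant features are
skipped; pairs joined by a shared gene symbol or fusion partnership are
flagged so they can be set aside from the analytic pair count (the
significance convention is raw two-sided p < 0.05, with BH q reported
alongside as the stricter option). Pathway rollup is the fraction of
samples with ≥ 1 event in each of six pathways (OR semantics; a sample
with two lesions in one pathway counts once).

## Survival

Endpoints: EFS events are relapse, induction failure, death, treatment
abandonment, second malignancy or transfer, taken at the first
occurrence; OS events are deaths, except that abandonment is an OS event
dated at last follow-up (in this treatment setting abandonment
overwhelmingly follows relapse or refractory disease, so censoring it
would bias OS upward); everyone else is censored at last contact.

Estimation goes through lifelines: Kaplan–Meier (log-log / exponential
Greenwood 95% CI — the default when no method is reported with published
CIs), the unweighted log-rank test, and Cox partial likelihood with
Efron tie handling and Wald CIs. Greenwood variance of S(t) is computed
alongside and is what "within 3 SE" means in the recovery tests.
Five-year rates are read from the step function as the last value at
t ≤ 5. Degenerate inputs (everyone censored at 0) are flagged on the
curve rather than silently returned.

## Risk stratification

Both models are rule tables over a closed lesion vocabulary (driver
features, `kary:` karyotype flags, derived composites such as
`FLT3-ITD-without-NPM1` and `RUNX1-mut`), applied in precedence order
with a total default rule; every assignment records the rule that fired.

* ELN baseline: adverse lesions (TP53, ASXL1, RUNX1 mutation, FLT3-ITD
  without NPM1, DEK-NUP214, KMT2A rearrangement, complex/monosomal
  karyotype, −7, −17, del(5q)) → HR; favorable (RUNX1-RUNX1T1,
  CBFB-MYH11, NPM1 without FLT3-ITD, CEBPA) → LR; default IR.
* SCMC-pAML: (1) high-risk lesions — the ELN adverse set minus KMT2A-r,
  plus FUS-ERG, CBFA2T3-GLIS2, NUP98-KDM5A, NUP98-NSD1; (2)
  RUNX1-RUNX1T1 subdivision — no CR1 → HR, CR1 with both CSF3R and
  KIT-E17 mutations → HR, CR1 otherwise → LR; (3) KMT2A-r → IR; (4)
  favorable mutations CEBPA/NPM1/GATA2 and the CBFB-MYH11 fusion → LR;
  (5) default by CR1 (CR1 → IR, otherwise HR). Unknown CR1 follows a
  configurable policy (default: the CR1-achieved path, flagged in the
  rule trace). FLT3-ITD co-occurring with NPM1 is deliberately not
  high-risk; UBTF is not in the default table (available as an optional
  rule) because it is confounded with FLT3-ITD.

The precedence HR > RUNX1-RUNX1T1 subdivision > IR > LR > default
resolves conflicting simultaneous lesions toward the higher risk. Flow
tables between the two models are 3×3 counts whose marginals equal each
model's group sizes — a conservation law asserted on every cohort.

## Synthetic cohort generator

The generator's defaults are the study conditions: fusion-category
multinomial (RUNX1-RUNX1T1 0.281, KMT2A-r 0.154, NUP98 fusions,
CBFB-MYH11, CBFA2T3-GLIS2, FUS-ERG, …, summing to 0.685 fusion-positive),
per-gene driver-mutation Bernoullis (FLT3 0.192, KIT 0.185, NRAS 0.178,
KRAS 0.092, CEBPA 0.082, CSF3R 0.051, …), FLT3-ITD 0.073, CBL exon 8/9
deletion 0.041, and 5-year EFS targets 0.849/0.745/0.182 per risk group.
Pieces the source data do not specify are chosen once as field-realistic
and documented here:

* **VAF ~ Beta(4, 6), depth = 10 + NegBin(r = 4, mean = 120)** — clonal
  leukemic fractions centered near 0.4 with overdispersed RNA-seq
  coverage; mutant reads are the rounded product and VAF is re-derived
  from the integer counts, so the count invariant holds exactly.
* **Co-occurrence** is planted by solving the 2×2 odds-ratio equation
  for the joint probability given both marginals (unique admissible root
  of the quadratic; OR = 1 gives independence); default CSF3R × KIT at
  OR = 5. A gene may join at most one planted pair.
* **Hotspot allocation**: 80% of driver positions fall in the gene's
  hotspot windows, the rest uniform over the coding length. Planted
  drivers carry a gold medal with probability 0.9 and a
  prior-pediatric-report flag with probability 0.5, emulating an
  upstream medal annotation with high but imperfect sensitivity; both
  nomination routes (medal, cluster) stay exercised.
* **Decoy rows** (Poisson mean 3 per patient) deliberately hit every
  triage branch: synonymous consequence, weak read support, population
  polymorphism, Ig/TCR position, and clean passengers that grade L3.
* **CR1 and survival**: CR1 feeds the SCMC rules and the rules define the
  survival group, a circularity the generator breaks by classifying once
  with CR1 assumed achieved, sampling CR1 with that provisional group's
  probability (defaults 0.95/0.85/0.55 for LR/IR/HR), then classifying
  finally with the sampled CR1. EFS event times are exponential with
  λ = −ln(S₅)/5 for the final group; censoring is Uniform(2, 12) years
  of administrative follow-up. Abandonment is attributed as the *cause*
  of 25% of adverse events (it predominantly follows relapse or poor
  response), so it maps to an event for both endpoints without adding
  hazard on top of the calibrated group rate; 15% of events are deaths
  (OS event at the same time), the rest relapses with a subsequent
  Exp(1) post-event death time. EFS ≤ OS holds by construction.
* The synthetic background catalogue (`simulate_background`) concentrates
  80% of 150–400 per-gene background mutations in the same hotspot
  windows — a synthetic stand-in for a published-mutation catalogue.

What the generator does **not** emulate: sequence context and read-level
errors, copy-number aberrations, expression-dependent detectability of
RNA-seq calls, linkage beyond the configured pairwise odds ratios, and
non-proportional or non-exponential hazards. Passing tests therefore
demonstrate internal consistency of the pipeline under the planted
statistical structure, not performance on real sequencing data.

## Problem sizes and numerics

The test suite runs its statistical checks at the smallest sizes with
adequate power: a shared 400-patient cohort for structural checks,
n = 5000 for the end-to-end recovery of planted frequencies / odds ratio /
group-wise 5-year EFS (each within 3 SE of its planted value), 500
uniform-background genes for FDR control, 200 planted-cluster genes for
power, n = 2000 exponential arms for Cox recovery, and a 5000-shuffle
permutation oracle for the log-rank p on a 20-patient fixture. Exact
binomial tails are validated against direct pmf summation for small
N_g; the Cox coefficient on an 8-subject fixture is validated to 1e-6
against a directly maximized partial likelihood; BH q-values are checked
against a hand-computed step-up. All simulations are seeded; hypothesis
property tests are derandomized.

## Known limitations

* The cluster test's uniform null ignores codon-level mutability and
  trinucleotide context; a context-aware null would sharpen specificity
  on real catalogues.
* The artifact-list derivation is recurrence-only; the original curation
  it stands in for also used manual review.
* Cox fitting supports Efron ties only (the lifelines implementation);
  the ties method is recorded on the result for transparency.
* The risk rule tables are reconstructed from published results text, not
  from a machine-readable rule sheet; they ship as config precisely so a
  published sheet can be pinned when available.
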