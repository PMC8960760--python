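# pedaml

Driver-landscape analysis for pediatric acute myeloid leukemia (AML), built
for cohorts profiled by tumor-only RNA-seq. The package covers the full
analysis chain a leukemia genomics group runs after variant calling and
annotation:

1. **Variant triage** — tumor-only RNA-seq calls mix somatic drivers with
   germline polymorphisms and artifacts. Hard exclusions remove calls in
   Ig/TCR loci, with weak read support (mutant reads < 3 or depth < 8),
   with 1000 Genomes frequency > 0.001, with non-protein-altering
   consequences, or on a cohort-recurrence artifact blacklist. Survivors
   are graded **L1** (strong somatic/cancer evidence: COSMIC-recurrent at
   VAF ≥ 0.1, previously reported in pediatric cancer genomics,
   loss-of-function in a tumor suppressor, ClinVar (Likely) Pathogenic, or
   clonal + in-silico damaging + cancer-census gene + absent from 1000
   Genomes), **L2** (COSMIC-recurrent but subclonal), or **L3** (other).
2. **Driver nomination** — a triaged mutation is a potential driver if it
   carries a *gold* pathogenicity medal (an input annotation from an
   upstream classifier) **or** clusters significantly within published
   somatic mutations: with `N_g` background mutations in a gene of `L_g`
   codons, the count `x` within ±W residues of the candidate is tested
   against `Binomial(N_g, π)`, `π = min(1, (2W+1)/L_g)`, p = P(X ≥ x)
   (exact upper tail), Benjamini–Hochberg q < 0.05 across candidates.
3. **Landscape statistics** — hotspot labelling (KIT exon 8/17, FLT3
   TKD/activation loop, KRAS P-loop, CSF3R cytoplasmic domain), recurrence
   tables, six-pathway rollups, cross-cohort recurrence comparison with
   age strata (< 3 y vs 3–14 y; two-sided Fisher exact, BH-adjusted), and
   pairwise co-occurrence / mutual-exclusivity testing with FAB groups as
   pseudo-features.
4. **Survival** — EFS/OS endpoint construction (abandonment counts as an
   event for both endpoints, dated at last follow-up), Kaplan–Meier with
   Greenwood variance and log-log CIs, log-rank tests, and Cox
   proportional-hazards regression (via lifelines).
5. **Risk stratification** — rule engines for an ELN-2017-derived genetic
   baseline and the revised SCMC-pAML model (high-risk fusions FUS-ERG,
   CBFA2T3-GLIS2, NUP98-KDM5A/NSD1; KMT2A rearrangements intermediate;
   RUNX1-RUNX1T1 subdivided by first-induction remission and CSF3R +
   KIT-exon-17 co-mutation), plus 3×3 re-stratification flow tables.
6. **Synthetic cohorts** — a generator that plants fusion/mutation
   frequencies, co-occurrence odds ratios, hotspot allocation, VAF/depth
   distributions, CR1 rates and risk-group-specific exponential survival,
   so the entire chain is testable without controlled-access patient data.

## Worked example

```python
from pedaml import (SimConfig, generate, triage_cohort, build_cohort_matrix,
                    stratify_cohort, events_from_calls, km_estimate,
                    pairwise_correlation, group_sizes)
from pedaml.config import DEFAULT_IGTCR_REGIONS

cohort = generate(SimConfig(n_patients=300), seed=1)
traces = triage_cohort(cohort.variants, igtcr_regions=DEFAULT_IGTCR_REGIONS)
drivers = [t.variant for t in traces if t.level in ("L1", "L2")]
matrix = build_cohort_matrix(drivers, cohort.fusions, cohort.itds,
                             cohort.deletions,
                             samples=[p.sample_id for p in cohort.patients])
print(matrix.recurrence_fractions().sort_values(ascending=False).head(3))
events = events_from_calls(drivers, cohort.fusions, cohort.itds, cohort.deletions)
asg = stratify_cohort(cohort.patients, events)
print(group_sizes(a.scmc_group for a in asg))
```

prints

```
RUNX1-RUNX1T1    0.290000
KIT              0.183333
FLT3             0.176667
dtype: float64
LR     97
IR    107
HR     96
dtype: int64
```

i.e. the most recurrent lesions in the simulated cohort are the
RUNX1-RUNX1T1 fusion (29% of patients; planted marginal 28.1%) and KIT /
FLT3 driver mutations (18.3% / 17.7%; planted 18.5% / 19.2%), and the
SCMC-pAML rule engine splits the 300 patients into low / intermediate /
high-risk groups of 97 / 107 / 96. Survival for each patient was generated
from its risk group's exponential hazard calibrated to 5-year EFS of
0.849 / 0.745 / 0.182, so Kaplan–Meier curves by group reproduce that
ordering.

The same stages are available from the shell:

```
pedaml simulate --n 300 --seed 1 --out-dir sim/
pedaml triage --variants sim/variants.tsv --out triaged.tsv
pedaml stratify --clinical sim/clinical.csv --variants sim/variants.tsv \
    --fusions sim/fusions.tsv --out risk.tsv
```

Each subcommand writes a TSV plus a `<out>.json` run summary and echoes
its parameters to stderr.

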