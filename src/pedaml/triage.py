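"""Tumor-only RNA-seq variant triage.

Candidate calls from tumor-only RNA-seq carry germline polymorphisms and
sequencing artifacts alongside somatic drivers.  The triage engine first
drops calls failing any hard exclusion (Ig/TCR locus, weak read support,
population polymorphism, non-protein-altering consequence, recurrent
cohort artifact), then grades survivors into three confidence levels:

* L1 — somatic / cancer-associated by strong evidence: a COSMIC-recurrent
  change at clonal VAF, a change previously reported in pediatric cancer
  genomics, loss of function in a known tumor suppressor, a ClinVar
  (Likely) Pathogenic call, or a clonal in-silico-damaging change in a
  cancer-census gene absent from population databases.
* L2 — COSMIC-recurrent but subclonal, or recurrent and absent from the
  1000 Genomes population panel.
* L3 — everything else (retained for audit, not treated as somatic).

Every decision is returned with a :class:`TriageRuleTrace` so the call's
level can be re-derived from the fired rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .config import (
    ALLOWED_CONSEQUENCES,
    CLINVAR_PATHOGENIC,
    LOF_CONSEQUENCES,
    POLYPHEN_DAMAGING,
)
from .cohort import VariantCall

EXCLUSION_RULES = ("igtcr", "read_support", "kg_freq", "consequence", "artifact")
L1_CRITERIA = ("c1", "c2", "c3", "c4", "c5")

# thresholds from the triage protocol
MIN_MUTANT_READS = 3
MIN_DEPTH = 8
MAX_KG_FREQ = 0.001
COSMIC_RECURRENT = 3
CLONAL_VAF = 0.1


@dataclass(frozen=True)
class ArtifactList:
    """Set of blacklisted sites (chrom, pos, ref, alt)."""

    sites: frozenset
    provenance: str = "supplied_file"       # or "cohort_derived"
    min_sample_fraction: Optional[float] = None

    def __contains__(self, key) -> bool:
        return key in self.sites


EMPTY_ARTIFACTS = ArtifactList(frozenset())


@dataclass
class TriageRuleTrace:
    variant: VariantCall
    fired_exclusions: tuple = ()
    level: str = ""
    l1_criteria_met: frozenset = frozenset()
    l2_met: bool = False


def _in_regions(v: VariantCall, regions: Sequence[tuple]) -> bool:
    # regions are BED-style (chrom, start0, end) half-open intervals
    return any(c == v.chrom and s < v.pos <= e for c, s, e in regions)


def apply_exclusions(variant: VariantCall,
                     artifact_list: ArtifactList = EMPTY_ARTIFACTS,
                     igtcr_regions: Sequence[tuple] = (),
                     allowed_consequences: frozenset = ALLOWED_CONSEQUENCES,
                     ) -> tuple[str, ...]:
    """Return every fired exclusion rule id (order-independent set semantics).

    Rules: ``igtcr`` (call inside an Ig/TCR locus), ``read_support``
    (mutant reads <3 or depth <8), ``kg_freq`` (1000 Genomes frequency
    >0.001), ``consequence`` (not protein-altering), ``artifact`` (site on
    the cohort artifact blacklist).
    """
    fired = []
    if _in_regions(variant, igtcr_regions):
        fired.append("igtcr")
    if variant.mutant_reads < MIN_MUTANT_READS or variant.depth < MIN_DEPTH:
        fired.append("read_support")
    if variant.kg_freq is not None and variant.kg_freq > MAX_KG_FREQ:
        fired.append("kg_freq")
    if variant.consequence not in allowed_consequences:
        fired.append("consequence")
    if (variant.chrom, variant.pos, variant.ref, variant.alt) in artifact_list:
        fired.append("artifact")
    return tuple(fired)


def l1_criteria(variant: VariantCall,
                cgc_genes: frozenset = frozenset(),
                lof_consequences: frozenset = LOF_CONSEQUENCES) -> frozenset:
    """Subset of the five L1 criteria the variant satisfies.

    c1: COSMIC-recurrent (>=3 tumors) and VAF >= 0.1.
    c2: previously reported in pediatric cancer genomic projects.
    c3: loss-of-function consequence in a known tumor suppressor.
    c4: ClinVar Pathogenic / Likely Pathogenic.
    c5: VAF > 0.1, SIFT deleterious and PolyPhen damaging, gene in the
        COSMIC cancer gene census, and absent from 1000 Genomes.
    """
    met = set()
    if variant.cosmic_count >= COSMIC_RECURRENT and variant.vaf >= CLONAL_VAF:
        met.add("c1")
    if variant.prior_pediatric_report:
        met.add("c2")
    if variant.consequence in lof_consequences and variant.is_tsg:
        met.add("c3")
    if variant.clinvar_sig in CLINVAR_PATHOGENIC:
        met.add("c4")
    if (variant.vaf > CLONAL_VAF and variant.sift == "deleterious"
            and variant.polyphen in POLYPHEN_DAMAGING
            and variant.gene in cgc_genes and variant.kg_freq is None):
        met.add("c5")
    return frozenset(met)


def l2_met(variant: VariantCall) -> bool:
    """COSMIC-recurrent and (subclonal VAF <= 0.1 or absent from 1000G)."""
    return variant.cosmic_count >= COSMIC_RECURRENT and (
        variant.vaf <= CLONAL_VAF or variant.kg_freq is None)


def assign_level(variant: VariantCall,
                 cgc_genes: frozenset = frozenset()) -> str:
    """L1 > L2 > L3 with the documented precedence (a variant at VAF
    exactly 0.1 with COSMIC recurrence satisfies both c1 and the L2 clause
    and is graded L1)."""
    if l1_criteria(variant, cgc_genes):
        return "L1"
    if l2_met(variant):
        return "L2"
    return "L3"


def triage_variant(variant: VariantCall,
                   artifact_list: ArtifactList = EMPTY_ARTIFACTS,
                   igtcr_regions: Sequence[tuple] = (),
                   cgc_genes: frozenset = frozenset()) -> TriageRuleTrace:
    """Total triage of one call: exclusions, then level assignment."""
    fired = apply_exclusions(variant, artifact_list, igtcr_regions)
    if fired:
        level = "EXCLUDED"
        crit: frozenset = frozenset()
        l2 = False
    else:
        crit = l1_criteria(variant, cgc_genes)
        l2 = l2_met(variant)
        level = "L1" if crit else ("L2" if l2 else "L3")
    variant.level = level
    return TriageRuleTrace(variant, fired, level, crit, l2)


def triage_cohort(variants: Iterable[VariantCall],
                  artifact_list: ArtifactList = EMPTY_ARTIFACTS,
                  igtcr_regions: Sequence[tuple] = (),
                  cgc_genes: frozenset = frozenset()) -> list[TriageRuleTrace]:
    return [triage_variant(v, artifact_list, igtcr_regions, cgc_genes)
            for v in variants]


def derive_artifact_list(cohort_variants: Sequence[VariantCall],
                         min_sample_fraction: float = 0.05,
                         hotspot_whitelist: frozenset = frozenset(),
                         ) -> ArtifactList:
    """Blacklist sites called in more than ``min_sample_fraction`` of the
    cohort's samples, exempting whitelisted hotspot sites.

    A recurrent alignment artifact shows up at the same site across many
    unrelated samples; true hotspots do too, hence the whitelist
    (site keys (chrom, pos, ref, alt))."""
    if not cohort_variants:
        return ArtifactList(frozenset(), "cohort_derived", min_sample_fraction)
    n_samples = len({v.sample_id for v in cohort_variants})
    per_site: dict[tuple, set] = {}
    for v in cohort_variants:
        per_site.setdefault((v.chrom, v.pos, v.ref, v.alt), set()).add(v.sample_id)
    sites = frozenset(
        site for site, samples in per_site.items()
        if len(samples) / n_samples > min_sample_fraction
        and site not in hotspot_whitelist)
    return ArtifactList(sites, "cohort_derived", min_sample_fraction)


@dataclass
class ConcordanceResult:
    """RNA-seq call recovery against an orthogonal (e.g. WGS) truth set."""

    recovery: Optional[float]               # None when the truth set is empty
    n_truth: int
    n_matched: int
    matched: list = field(default_factory=list)
    missed: list = field(default_factory=list)
    extra: list = field(default_factory=list)   # calls absent from truth


def concordance(truth_mutations: Iterable[tuple],
                rnaseq_calls: Iterable[tuple]) -> ConcordanceResult:
    """Fraction of truth mutations recovered by the RNA-seq calls.

    Both sets are keyed by (sample, gene, protein change).  Also reports
    RNA-seq-specific calls for downstream curation.
    """
    truth = set(truth_mutations)
    calls = set(rnaseq_calls)
    matched = sorted(truth & calls)
    missed = sorted(truth - calls)
    extra = sorted(calls - truth)
    recovery = len(matched) / len(truth) if truth else None
    return ConcordanceResult(recovery, len(truth), len(matched),
                             matched, missed, extra)
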