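"""Synthetic pediatric-AML cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so every
stage — triage, nomination, landscape statistics, survival, risk
stratification — is testable without the controlled-access patient data:

* fusion categories from a multinomial over the observed cohort
  frequencies (RUNX1-RUNX1T1 0.281, KMT2A rearrangements 0.154, ...);
* per-gene driver-mutation Bernoulli frequencies (FLT3 0.192, KIT 0.185,
  NRAS 0.178, ...), with configurable planted co-occurrence pairs whose
  joint probability solves the 2x2 odds-ratio equation (default
  CSF3R x KIT at OR 5);
* hotspot allocation within genes, Beta-distributed VAF, negative-binomial
  depth, and decoy variant rows that deliberately exercise every triage
  exclusion and level branch;
* first-induction remission (CR1) probability keyed by risk group, and
  risk-group-specific exponential event-free survival calibrated to
  5-year rates (LR 0.849, IR 0.745, HR 0.182), with uniform
  administrative censoring and treatment abandonment attributed as a
  cause of a fraction of adverse events.

Survival is generated *after* classifying the generated lesions with the
SCMC-pAML rules, so the classifier -> survival chain is testable end to
end.  The same seed reproduces the cohort byte for byte.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (
    DriverEvent,
    FusionCall,
    PatientRecord,
    VariantCall,
    write_clinical_csv,
    write_fusions_tsv,
    write_variants_tsv,
)
from .config import DEFAULT_HOTSPOTS, DEFAULT_IGTCR_REGIONS
from .nominate import BackgroundCatalogue, GeneBackground
from .stratify import classify_scmc

# --------------------------------------------------------------------------
# Planted-pair construction
# --------------------------------------------------------------------------

def plant_pair(p1: float, p2: float, odds_ratio: float) -> float:
    """Joint probability p11 realizing the given marginals and odds ratio.

    Solves OR = p11*p00 / (p10*p01) with p10 = p1-p11 etc.; the admissible
    root lies in (max(0, p1+p2-1), min(p1, p2)).  OR=1 returns p1*p2.
    """
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("marginals must lie in (0,1)")
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if odds_ratio == 1.0:
        return p1 * p2
    # (1-OR) p11^2 + [1 + (OR-1)(p1+p2)] p11 - OR p1 p2 = 0
    a = 1.0 - odds_ratio
    b = 1.0 + (odds_ratio - 1.0) * (p1 + p2)
    c = -odds_ratio * p1 * p2
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("no admissible root for these marginals and OR")
    r = math.sqrt(disc)
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    for root in ((-b + r) / (2 * a), (-b - r) / (2 * a)):
        if lo < root < hi:
            return root
    raise ValueError("no admissible root for these marginals and OR")


def calibrate_hazard(s5: float, horizon: float = 5.0) -> float:
    """Exponential rate lambda with survival s5 at the horizon (years)."""
    if not (0.0 < s5 < 1.0):
        raise ValueError(f"5-year survival {s5} outside (0,1)")
    return -math.log(s5) / horizon


# --------------------------------------------------------------------------
# Simulation configuration
# --------------------------------------------------------------------------

#: Approximate coding lengths (aa) for the simulated driver genes.
GENE_LENGTHS: dict[str, int] = {
    "FLT3": 993, "KIT": 976, "NRAS": 189, "KRAS": 189, "CEBPA": 358,
    "ASXL2": 1435, "PTPN11": 593, "CSF3R": 836, "GATA2": 480, "JAK2": 1132,
    "NPM1": 294, "WT1": 449, "TET2": 2002, "TP53": 393, "RUNX1": 453,
    "ASXL1": 1541, "DHX15": 795, "DNM2": 870, "JAK3": 1124, "NF1": 2818,
}

#: Within-gene hotspot windows (aa ranges) used for position allocation;
#: genes not listed draw positions uniformly over their length.
GENE_HOTSPOT_RANGES: dict[str, list[tuple[int, int]]] = {
    "FLT3": [(829, 858)],
    "KIT": [(788, 828), (417, 448)],
    "NRAS": [(12, 13), (61, 61)],
    "KRAS": [(10, 17), (61, 61)],
    "CSF3R": [(615, 625), (741, 791)],
    "JAK2": [(617, 617)],
    "PTPN11": [(58, 76)],
    "TP53": [(173, 282)],
    "GATA2": [(349, 398)],
    "NPM1": [(286, 290)],
}


@dataclass
class SimConfig:
    """All planted parameters of the synthetic cohort (defaults follow the
    published cohort's frequencies and 5-year EFS rates)."""

    n_patients: int = 292
    fusion_probs: dict = field(default_factory=lambda: {
        "RUNX1-RUNX1T1": 0.281, "KMT2A-rearranged": 0.154,
        "CBFB-MYH11": 0.038, "CBFA2T3-GLIS2": 0.041,
        "NUP98-KDM5A": 0.024, "NUP98-NSD1": 0.017, "FUS-ERG": 0.017,
        "DEK-NUP214": 0.003, "XPO1-TNRC18": 0.007, "other-fusion": 0.103,
    })
    gene_probs: dict = field(default_factory=lambda: {
        "FLT3": 0.192, "KIT": 0.185, "NRAS": 0.178, "KRAS": 0.092,
        "CEBPA": 0.082, "ASXL2": 0.072, "PTPN11": 0.062, "CSF3R": 0.051,
        "GATA2": 0.051, "JAK2": 0.051, "WT1": 0.024, "NPM1": 0.021,
        "DHX15": 0.020, "NF1": 0.020, "TET2": 0.014, "RUNX1": 0.015,
        "TP53": 0.010, "DNM2": 0.010, "JAK3": 0.010, "ASXL1": 0.004,
    })
    #: planted co-occurrence: (gene_1, gene_2) -> odds ratio
    planted_pairs: dict = field(default_factory=lambda: {("CSF3R", "KIT"): 5.0})
    itd_probs: dict = field(default_factory=lambda: {"FLT3": 0.073, "MYC": 0.010})
    focal_deletion_probs: dict = field(default_factory=lambda: {"CBL-del-ex8/9": 0.041})
    karyotype_probs: dict = field(default_factory=lambda: {
        "complex": 0.030, "monosomal": 0.010, "minus7": 0.015,
        "minus17": 0.005, "del5q": 0.005,
    })
    hotspot_weight: float = 0.8          # P(driver position falls in a hotspot window)
    gold_medal_prob: float = 0.9         # P(planted driver carries a gold medal)
    prior_report_prob: float = 0.5       # P(planted driver flagged as previously reported)
    vaf_beta: tuple = (4.0, 6.0)
    depth_nb: tuple = (4.0, 120.0)       # (shape r, mean); depth = 10 + NB
    decoy_rate: float = 3.0              # mean decoy (non-driver) rows per patient
    cr1_prob: dict = field(default_factory=lambda: {"LR": 0.95, "IR": 0.85, "HR": 0.55})
    efs5_targets: dict = field(default_factory=lambda: {"LR": 0.849, "IR": 0.745, "HR": 0.182})
    censor_window: tuple = (2.0, 12.0)   # uniform administrative censoring (years)
    abandonment_given_event: float = 0.25
    death_given_event: float = 0.15
    age_lognorm: tuple = (1.5, 0.75)     # ln-scale mu, sigma; clipped to [0, 18]

    def validate(self) -> None:
        total = sum(self.fusion_probs.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"fusion category probabilities sum to {total} > 1")
        for name, p in {**self.fusion_probs, **self.gene_probs,
                        **self.itd_probs, **self.karyotype_probs}.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability for {name} outside [0,1]: {p}")
        seen = set()
        for (g1, g2), odds in self.planted_pairs.items():
            if odds <= 0:
                raise ValueError(f"planted OR for {g1}x{g2} must be positive")
            if g1 in seen or g2 in seen:
                raise ValueError("a gene may join at most one planted pair")
            seen |= {g1, g2}
            # raises if the marginals cannot carry the OR
            plant_pair(self.gene_probs[g1], self.gene_probs[g2], odds)


@dataclass
class SyntheticCohort:
    patients: list
    variants: list
    fusions: list
    itds: list
    deletions: list
    truth: dict

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        write_clinical_csv(self.patients, os.path.join(out_dir, "clinical.csv"))
        write_variants_tsv(self.variants, os.path.join(out_dir, "variants.tsv"))
        write_fusions_tsv(self.fusions, os.path.join(out_dir, "fusions.tsv"))
        events = [{"sample_id": e.sample_id, "kind": e.kind, "feature": e.feature}
                  for e in self.itds + self.deletions]
        pd.DataFrame(events, columns=["sample_id", "kind", "feature"]) \
            .to_csv(os.path.join(out_dir, "events.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

_FAB_BY_FUSION = {
    "CBFA2T3-GLIS2": {"M7": 1.0},
    "XPO1-TNRC18": {"M7": 1.0},
    "NUP98-KDM5A": {"M7": 0.6, "M5": 0.4},
    "RUNX1-RUNX1T1": {"M2": 0.8, "M1": 0.2},
    "CBFB-MYH11": {"M4": 0.9, "M5": 0.1},
    "KMT2A-rearranged": {"M5": 0.6, "M4": 0.3, "M7": 0.1},
}
_FAB_DEFAULT = {"M0": 0.05, "M1": 0.15, "M2": 0.25, "M4": 0.2, "M5": 0.2,
                "M6": 0.05, "M7": 0.1}

_BASES = "ACGT"


def _gene_chrom_base(gene: str) -> tuple[str, int]:
    # deterministic pseudo-coordinates for the synthetic genome
    h = sum(ord(c) * (i + 1) for i, c in enumerate(gene))
    return f"chr{1 + h % 20}", 1_000_000 + (h % 997) * 10_000


def _sample_fab(rng: np.random.Generator, fusion: Optional[str]) -> str:
    table = _FAB_BY_FUSION.get(fusion, _FAB_DEFAULT)
    labels = sorted(table)
    probs = np.array([table[k] for k in labels])
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def _sample_position(rng: np.random.Generator, gene: str, hotspot_weight: float) -> int:
    length = GENE_LENGTHS[gene]
    ranges = GENE_HOTSPOT_RANGES.get(gene)
    if ranges and rng.random() < hotspot_weight:
        lo, hi = ranges[int(rng.integers(len(ranges)))]
        return int(rng.integers(lo, hi + 1))
    return int(rng.integers(1, length + 1))


def _driver_variant(rng: np.random.Generator, cfg: SimConfig, sample_id: str,
                    gene: str) -> tuple[VariantCall, bool, str]:
    """One planted driver mutation; returns (call, prior_report, medal)."""
    pos = _sample_position(rng, gene, cfg.hotspot_weight)
    chrom, base = _gene_chrom_base(gene)
    a, b = cfg.vaf_beta
    vaf = float(np.clip(rng.beta(a, b), 0.01, 0.99))
    r, mean = cfg.depth_nb
    depth = 10 + int(rng.negative_binomial(r, r / (r + mean)))
    mr = int(round(vaf * depth))
    mr = min(max(mr, 1), depth)
    vaf = mr / depth
    ref = _BASES[int(rng.integers(4))]
    alt = _BASES[(int(rng.integers(1, 4)) + _BASES.index(ref)) % 4]
    prior = bool(rng.random() < cfg.prior_report_prob)
    medal = "gold" if rng.random() < cfg.gold_medal_prob else "silver"
    v = VariantCall(
        sample_id=sample_id, gene=gene, chrom=chrom, pos=base + pos * 3,
        ref=ref, alt=alt, consequence="missense", protein_pos=pos,
        aa_change=f"p.X{pos}Y", vaf=vaf, depth=depth, mutant_reads=mr,
        cosmic_count=int(3 + rng.poisson(20)), kg_freq=None,
        clinvar_sig=None, sift="deleterious", polyphen="probably_damaging",
        is_tsg=gene in ("TP53", "WT1", "NF1", "ASXL1"),
        prior_pediatric_report=prior,
    )
    return v, prior, medal


_DECOY_KINDS = ("synonymous", "low_depth", "polymorphism", "igtcr", "passenger")


def _decoy_variant(rng: np.random.Generator, cfg: SimConfig, sample_id: str) -> VariantCall:
    """A non-driver row exercising one of the exclusion / L3 branches."""
    kind = _DECOY_KINDS[int(rng.integers(len(_DECOY_KINDS)))]
    gene = sorted(GENE_LENGTHS)[int(rng.integers(len(GENE_LENGTHS)))]
    chrom, base = _gene_chrom_base(gene)
    pos = int(rng.integers(1, GENE_LENGTHS[gene] + 1))
    depth = 30 + int(rng.integers(100))
    vaf = float(np.clip(rng.beta(2, 2), 0.02, 0.98))
    mr = max(int(round(vaf * depth)), 3)
    kwargs = dict(sample_id=sample_id, gene=gene, chrom=chrom,
                  pos=base + pos * 3, ref="C", alt="T",
                  consequence="missense", protein_pos=pos,
                  aa_change=f"p.X{pos}Y", vaf=mr / depth, depth=depth,
                  mutant_reads=mr, cosmic_count=0, kg_freq=None)
    if kind == "synonymous":
        kwargs["consequence"] = "synonymous"
    elif kind == "low_depth":
        kwargs.update(depth=6, mutant_reads=2, vaf=2 / 6)
    elif kind == "polymorphism":
        kwargs["kg_freq"] = float(0.002 + rng.random() * 0.3)
    elif kind == "igtcr":
        c, s, e = DEFAULT_IGTCR_REGIONS[int(rng.integers(len(DEFAULT_IGTCR_REGIONS)))]
        kwargs.update(chrom=c, pos=int(s + 1 + rng.integers(e - s)))
    # "passenger": clean row with no supporting evidence -> L3
    return VariantCall(**kwargs)


def simulate_background(genes: Optional[dict] = None, seed: int = 0,
                        n_per_gene: tuple = (150, 400),
                        cluster_weight: float = 0.8) -> BackgroundCatalogue:
    """Synthetic published-mutation catalogue with clusters at the known
    hotspot windows (stand-in for a real external background; labelled
    synthetic in the truth manifest)."""
    rng = np.random.default_rng(seed)
    genes = genes or GENE_LENGTHS
    out = []
    for gene in sorted(genes):
        length = GENE_LENGTHS.get(gene, 500)
        n = int(rng.integers(*n_per_gene))
        counts: dict[int, int] = {}
        ranges = GENE_HOTSPOT_RANGES.get(gene)
        for _ in range(n):
            if ranges and rng.random() < cluster_weight:
                lo, hi = ranges[int(rng.integers(len(ranges)))]
                pos = int(rng.integers(lo, hi + 1))
            else:
                pos = int(rng.integers(1, length + 1))
            counts[pos] = counts.get(pos, 0) + 1
        out.append(GeneBackground(gene, length, tuple(sorted(counts.items()))))
    return BackgroundCatalogue(out)


def _sample_gene_mutations(rng: np.random.Generator, cfg: SimConfig) -> set:
    """One patient's mutated-gene set honouring the planted pair ORs."""
    paired = {g for pair in cfg.planted_pairs for g in pair}
    genes = set()
    for (g1, g2), odds in cfg.planted_pairs.items():
        p1, p2 = cfg.gene_probs[g1], cfg.gene_probs[g2]
        p11 = plant_pair(p1, p2, odds)
        u = rng.random()
        if u < p11:
            genes |= {g1, g2}
        elif u < p1:
            genes.add(g1)
        elif u < p1 + (p2 - p11):
            genes.add(g2)
    for g, p in cfg.gene_probs.items():
        if g not in paired and rng.random() < p:
            genes.add(g)
    return genes


def generate(cfg: SimConfig, seed: int) -> SyntheticCohort:
    """Generate a full synthetic cohort; byte-reproducible given the seed."""
    cfg.validate()
    rng = np.random.default_rng(seed)

    fusion_cats = sorted(cfg.fusion_probs)
    fusion_p = np.array([cfg.fusion_probs[c] for c in fusion_cats])
    p_none = 1.0 - fusion_p.sum()

    hazards = {g: calibrate_hazard(s) for g, s in cfg.efs5_targets.items()}

    patients, variants, fusions, itds, deletions = [], [], [], [], []
    medals: dict[tuple, str] = {}
    truth_rows = []

    for i in range(cfg.n_patients):
        sid = f"S{i:05d}"
        # ---- lesions ------------------------------------------------------
        u = rng.random()
        acc = 0.0
        fusion_cat = None
        for c, p in zip(fusion_cats, fusion_p):
            acc += p
            if u < acc:
                fusion_cat = c
                break
        _ = p_none
        sample_fusions = []
        if fusion_cat is not None:
            partner_map = {
                "RUNX1-RUNX1T1": ("RUNX1", "RUNX1T1"), "CBFB-MYH11": ("CBFB", "MYH11"),
                "CBFA2T3-GLIS2": ("CBFA2T3", "GLIS2"), "NUP98-KDM5A": ("NUP98", "KDM5A"),
                "NUP98-NSD1": ("NUP98", "NSD1"), "FUS-ERG": ("FUS", "ERG"),
                "DEK-NUP214": ("DEK", "NUP214"), "XPO1-TNRC18": ("XPO1", "TNRC18"),
                "KMT2A-rearranged": ("KMT2A", "MLLT3"), "other-fusion": ("PTPRA", "FUS"),
            }
            ga, gb = partner_map[fusion_cat]
            sample_fusions.append(FusionCall(sid, ga, gb, in_frame=True))

        mutated = _sample_gene_mutations(rng, cfg)
        sample_variants, sample_medals = [], []
        for gene in sorted(mutated):
            v, _prior, medal = _driver_variant(rng, cfg, sid, gene)
            sample_variants.append(v)
            sample_medals.append(medal)

        n_decoys = int(rng.poisson(cfg.decoy_rate))
        decoys = [_decoy_variant(rng, cfg, sid) for _ in range(n_decoys)]

        sample_itds = [DriverEvent(sid, "itd", f"{g}-ITD")
                       for g, p in sorted(cfg.itd_probs.items()) if rng.random() < p]
        sample_dels = [DriverEvent(sid, "focal_deletion", label)
                       for label, p in sorted(cfg.focal_deletion_probs.items())
                       if rng.random() < p]
        flags = frozenset(f for f, p in sorted(cfg.karyotype_probs.items())
                          if rng.random() < p)

        # ---- risk group, CR1, survival -----------------------------------
        events = [DriverEvent(sid, "mutation", v.gene) for v in sample_variants]
        events += [DriverEvent(sid, "mutation", lbl) for v in sample_variants
                   for lbl in _hotspot_labels(v)]
        events += [DriverEvent(sid, "fusion", f.category) for f in sample_fusions]
        events += sample_itds + sample_dels

        age = float(np.clip(rng.lognormal(*cfg.age_lognorm), 0.1, 18.0))
        provisional = PatientRecord(sid, age, cr1=True, karyotype_flags=flags,
                                    efs_time=0, os_time=0)
        prov_group, _ = classify_scmc(provisional, events)
        cr1 = bool(rng.random() < cfg.cr1_prob[prov_group])
        patient_stub = PatientRecord(sid, age, cr1=cr1, karyotype_flags=flags,
                                     efs_time=0, os_time=0)
        group, rule = classify_scmc(patient_stub, events)

        lam = hazards[group]
        t_event = float(rng.exponential(1.0 / lam))
        c_lo, c_hi = cfg.censor_window
        t_cens = float(c_lo + rng.random() * (c_hi - c_lo))
        if t_event <= t_cens:
            efs_time, efs_event = t_event, True
            u2 = rng.random()
            if u2 < cfg.abandonment_given_event:
                cause = "abandonment"
                os_time, os_event, aband = t_event, True, True
            elif u2 < cfg.abandonment_given_event + cfg.death_given_event:
                cause = "death"
                os_time, os_event, aband = t_event, True, False
            else:
                cause = "relapse"
                t_death = t_event + float(rng.exponential(1.0))
                if t_death <= t_cens:
                    os_time, os_event = t_death, True
                else:
                    os_time, os_event = t_cens, False
                aband = False
        else:
            cause = ""
            efs_time, efs_event = t_cens, False
            os_time, os_event, aband = t_cens, False, False

        fab = _sample_fab(rng, fusion_cat)
        patient = PatientRecord(sid, age, fab=fab, protocol="AML-SIM-2009",
                                cr1=cr1, karyotype_flags=flags,
                                efs_time=round(efs_time, 4), efs_event=efs_event,
                                os_time=round(os_time, 4), os_event=os_event,
                                abandonment=aband)
        patients.append(patient)
        variants.extend(sample_variants + decoys)
        for v, m in zip(sample_variants, sample_medals):
            medals[v.key] = m
        fusions.extend(sample_fusions)
        itds.extend(sample_itds)
        deletions.extend(sample_dels)
        truth_rows.append({
            "sample_id": sid, "fusion": fusion_cat, "mutated_genes": sorted(mutated),
            "scmc_group": group, "scmc_rule": rule, "cr1": cr1,
            "event_cause": cause, "n_decoys": n_decoys,
        })

    truth = {
        "seed": seed,
        "config": _jsonable(asdict(cfg)),
        "hazards": hazards,
        "note": "synthetic cohort; all parameters planted, see config",
        "patients": truth_rows,
        "medals": {"|".join(map(str, k)): m for k, m in sorted(medals.items())},
    }
    return SyntheticCohort(patients, variants, fusions, itds, deletions, truth)


def _hotspot_labels(v: VariantCall) -> list:
    from .cohort import hotspot_labels_for
    return hotspot_labels_for(v.gene, v.protein_pos, DEFAULT_HOTSPOTS)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def medals_for(cohort: SyntheticCohort, variants: list) -> list:
    """Positionally aligned medal labels for a variant list (decoys and
    unlisted calls get 'none')."""
    lookup = cohort.truth["medals"]
    return [lookup.get("|".join(map(str, v.key)), "none") for v in variants]
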