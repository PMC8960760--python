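"""Configuration data for the pediatric-AML driver landscape pipeline.

Rule tables are data, not code: the hotspot definitions, pathway map,
consequence vocabulary and risk-stratification lesion sets below are
defaults that can be overridden from a YAML file via :func:`load_config`.
Amino-acid ranges are 1-based inclusive on the canonical transcript; exon
coordinates are resolved through :data:`EXON_AA_RANGES` so users can pin a
different transcript build by editing config rather than code.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import yaml

# --------------------------------------------------------------------------
# Consequence vocabulary
# --------------------------------------------------------------------------

#: Nonsynonymous / potentially protein-altering consequences retained by the
#: triage exclusion filter.  Anything outside this set is filtered out.
ALLOWED_CONSEQUENCES = frozenset({
    "missense",
    "stop_gained",
    "inframe_insertion",
    "inframe_deletion",
    "inframe_indel",
    "frameshift",
    "splice_acceptor",
    "splice_donor",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "protein_altering",
    "splice_region",
    "coding_sequence",
})

#: Loss-of-function consequences used by the tumor-suppressor L1 criterion.
LOF_CONSEQUENCES = frozenset({
    "frameshift", "splice_acceptor", "splice_donor", "stop_gained",
})

#: ClinVar classifications accepted by the L1 pathogenicity criterion.
CLINVAR_PATHOGENIC = frozenset({"Pathogenic", "Likely Pathogenic"})

#: PolyPhen calls counted as damaging (possibly_damaging or stronger).
POLYPHEN_DAMAGING = frozenset({"possibly_damaging", "probably_damaging"})

# --------------------------------------------------------------------------
# Hotspot definitions (Fig.-2-style protein domains / exons)
# --------------------------------------------------------------------------

#: Canonical-transcript exon → amino-acid ranges used to resolve exon-level
#: hotspots.  KIT ranges follow NM_000222.
EXON_AA_RANGES: dict[tuple[str, int], tuple[int, int]] = {
    ("KIT", 8): (417, 448),
    ("KIT", 17): (788, 828),
    ("CBL", 8): (366, 409),
    ("CBL", 9): (410, 477),
}


@dataclass(frozen=True)
class HotspotDefinition:
    """A named recurrently-mutated protein region.

    ``kind`` is ``aa_range`` (explicit amino-acid bounds), ``exon``
    (resolved via :data:`EXON_AA_RANGES`) or ``event`` (an annotated event
    such as FLT3-ITD that carries no protein position).
    """

    label: str
    gene: str
    kind: str  # aa_range | exon | event
    aa_lo: Optional[int] = None
    aa_hi: Optional[int] = None
    exon: Optional[int] = None

    def resolved_range(self) -> Optional[tuple[int, int]]:
        if self.kind == "aa_range":
            return (self.aa_lo, self.aa_hi)
        if self.kind == "exon":
            key = (self.gene, self.exon)
            if key not in EXON_AA_RANGES:
                raise KeyError(f"no exon→aa mapping for {self.gene} exon {self.exon}")
            return EXON_AA_RANGES[key]
        return None

    def __post_init__(self):
        if self.kind == "aa_range" and (self.aa_lo is None or self.aa_hi is None or self.aa_lo > self.aa_hi):
            raise ValueError(f"hotspot {self.label}: invalid aa range {self.aa_lo}-{self.aa_hi}")


DEFAULT_HOTSPOTS: tuple[HotspotDefinition, ...] = (
    HotspotDefinition("FLT3-TKD", "FLT3", "aa_range", 835, 836),
    HotspotDefinition("FLT3-AL", "FLT3", "aa_range", 829, 858),
    HotspotDefinition("KRAS-PL", "KRAS", "aa_range", 10, 17),
    HotspotDefinition("CSF3R-CY", "CSF3R", "aa_range", 651, 831),
    HotspotDefinition("KIT-E17", "KIT", "exon", exon=17),
    HotspotDefinition("KIT-E8", "KIT", "exon", exon=8),
    HotspotDefinition("FLT3-ITD", "FLT3", "event"),
    HotspotDefinition("CBL-del-ex8/9", "CBL", "event"),
)

# --------------------------------------------------------------------------
# Pathway map (six biological pathways)
# --------------------------------------------------------------------------

DEFAULT_PATHWAY_MAP: dict[str, str] = {
    # transcription regulation
    "CEBPA": "transcription", "GATA2": "transcription", "RUNX1": "transcription",
    "WT1": "transcription", "NPM1": "transcription", "UBTF": "transcription",
    "MYC": "transcription", "SPOP": "transcription", "ETV6": "transcription",
    # epigenetics
    "ASXL1": "epigenetics", "ASXL2": "epigenetics", "TET2": "epigenetics",
    "ARID2": "epigenetics", "KMT2C": "epigenetics", "EZH2": "epigenetics",
    "BCOR": "epigenetics", "DNMT3A": "epigenetics",
    # RAS signaling
    "NRAS": "ras", "KRAS": "ras", "PTPN11": "ras", "NF1": "ras",
    "LZTR1": "ras", "CBL": "ras", "RIT1": "ras",
    # other signaling (kinases / receptors)
    "FLT3": "signaling", "KIT": "signaling", "JAK2": "signaling",
    "JAK3": "signaling", "CSF3R": "signaling", "SH2B3": "signaling",
    "DNM2": "signaling", "MPL": "signaling",
    # tumor suppressors / cell cycle
    "TP53": "tumor_suppressor", "RB1": "tumor_suppressor",
    "PHF6": "tumor_suppressor", "CDKN2A": "tumor_suppressor",
    # spliceosome / RNA processing
    "DHX15": "splicing", "SRSF2": "splicing", "U2AF1": "splicing",
    "SF3B1": "splicing",
}

# --------------------------------------------------------------------------
# Fusion categories
# --------------------------------------------------------------------------

#: Fusions named as their own categories; any fusion whose partner set
#: matches gets the canonical 5'-3' label.
NAMED_FUSIONS: dict[frozenset, str] = {
    frozenset(label.split("-")): label
    for label in [
        "RUNX1-RUNX1T1", "CBFB-MYH11", "CBFA2T3-GLIS2", "FUS-ERG",
        "DEK-NUP214", "NUP98-NSD1", "NUP98-KDM5A", "XPO1-TNRC18",
        "XPO1-MLLT10",
    ]
}

#: Genes whose remaining rearrangements collapse into a gene-centric
#: category regardless of partner (named fusions above take precedence).
REARRANGEMENT_GENES = ("KMT2A", "NUP98")

# --------------------------------------------------------------------------
# Risk-stratification rule tables
# --------------------------------------------------------------------------

#: ELN-2017-style genetic groups adapted to pediatric AML.  Lesion labels
#: match the DriverEvent feature vocabulary (gene symbols for mutations,
#: canonical fusion names, karyotype flags prefixed ``kary:``).
ELN_RULES: dict = {
    "adverse": [
        "TP53", "ASXL1", "RUNX1-mut", "FLT3-ITD-without-NPM1",
        "DEK-NUP214", "KMT2A-rearranged",
        "kary:complex", "kary:monosomal", "kary:minus7", "kary:minus17",
        "kary:del5q",
    ],
    "favorable": [
        "RUNX1-RUNX1T1", "CBFB-MYH11", "NPM1-without-FLT3-ITD", "CEBPA",
    ],
}

#: SCMC-pAML rule table.  Applied in precedence order:
#: high-risk lesions > RUNX1-RUNX1T1 subdivision > KMT2A-r (IR) >
#: favorable mutations (LR) > CR1-based default.
SCMC_RULES: dict = {
    "high_risk": [
        "FUS-ERG", "CBFA2T3-GLIS2", "NUP98-KDM5A", "NUP98-NSD1",
        "TP53", "ASXL1", "RUNX1-mut", "FLT3-ITD-without-NPM1",
        "DEK-NUP214",
        "kary:complex", "kary:monosomal", "kary:minus7", "kary:minus17",
        "kary:del5q",
    ],
    "runx1_runx1t1_comut": ["CSF3R", "KIT-E17"],
    "intermediate": ["KMT2A-rearranged"],
    "favorable": ["CEBPA", "NPM1", "GATA2", "CBFB-MYH11"],
    "unknown_cr1_policy": "ir_path",  # treat unknown CR1 as CR1-achieved, flag it
}


#: BED-style (chrom, start0, end) Ig/TCR loci on GRCh37 used by the triage
#: exclusion filter; supplied as config because the exact intervals are a
#: pipeline input, not a constant of the method.
DEFAULT_IGTCR_REGIONS: tuple[tuple[str, int, int], ...] = (
    ("chr14", 105_586_000, 106_880_000),   # IGH
    ("chr2", 89_156_000, 90_274_000),      # IGK
    ("chr22", 22_380_000, 23_265_000),     # IGL
    ("chr7", 141_998_000, 142_511_000),    # TRB
    ("chr14", 22_090_000, 23_022_000),     # TRA/TRD
)


@dataclass
class PipelineConfig:
    """Bundle of the editable rule tables, overridable from YAML."""

    hotspots: tuple[HotspotDefinition, ...] = DEFAULT_HOTSPOTS
    pathway_map: dict = field(default_factory=lambda: dict(DEFAULT_PATHWAY_MAP))
    eln_rules: dict = field(default_factory=lambda: copy.deepcopy(ELN_RULES))
    scmc_rules: dict = field(default_factory=lambda: copy.deepcopy(SCMC_RULES))
    allowed_consequences: frozenset = ALLOWED_CONSEQUENCES
    lof_consequences: frozenset = LOF_CONSEQUENCES
    artifact_min_sample_fraction: float = 0.05
    cluster_window: int = 5
    fdr_threshold: float = 0.05


def load_config(path: Optional[str] = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig`, overriding defaults from YAML.

    The YAML file may carry any subset of ``hotspots`` (list of mappings
    with label/gene/kind/aa_lo/aa_hi/exon), ``pathway_map``, ``eln_rules``,
    ``scmc_rules``, ``cluster_window``, ``fdr_threshold``,
    ``artifact_min_sample_fraction``.
    """
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "hotspots" in raw:
        cfg.hotspots = tuple(HotspotDefinition(**h) for h in raw["hotspots"])
    for key in ("pathway_map", "eln_rules", "scmc_rules"):
        if key in raw:
            getattr(cfg, key).update(raw[key])
    for key in ("cluster_window", "fdr_threshold", "artifact_min_sample_fraction"):
        if key in raw:
            setattr(cfg, key, raw[key])
    return cfg
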