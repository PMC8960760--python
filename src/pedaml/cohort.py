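"""Domain types and table I/O for the AML driver-landscape pipeline.

Variant tables are accepted either as a flat MAF-like TSV (one row per
sample-variant) or as annotated VCF text with a CSQ-style INFO field; both
dialects normalize to the same :class:`VariantCall` records.  Fusion calls
and clinical covariates arrive as TSV/CSV.  The per-patient driver events
are assembled into a boolean sample x feature :class:`CohortMatrix` that
downstream recurrence, co-occurrence and survival analyses consume.

Conventions: genomic and protein positions are 1-based; indel alleles are
VCF-style left-aligned; a missing optional annotation is represented as
``None`` (absent), never silently zero-filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import (
    NAMED_FUSIONS,
    REARRANGEMENT_GENES,
    DEFAULT_HOTSPOTS,
    DEFAULT_PATHWAY_MAP,
    HotspotDefinition,
)


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an invalid layout."""


class RowError(ValueError):
    """A row failed to parse; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class VariantCall:
    """One annotated nonsynonymous call with its triage evidence fields."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    protein_pos: Optional[int] = None
    aa_change: str = ""
    vaf: float = 0.0
    depth: int = 0
    mutant_reads: int = 0
    cosmic_count: int = 0
    kg_freq: Optional[float] = None      # None = not in 1000 Genomes
    clinvar_sig: Optional[str] = None
    sift: Optional[str] = None
    polyphen: Optional[str] = None
    is_tsg: bool = False
    prior_pediatric_report: bool = False
    level: Optional[str] = None          # EXCLUDED | L1 | L2 | L3 once triaged

    def __post_init__(self):
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"{self.sample_id}:{self.gene} vaf {self.vaf} outside [0,1]")
        if self.depth < 0 or self.mutant_reads < 0:
            raise ValueError("negative read counts")
        if self.mutant_reads > self.depth:
            raise ValueError(
                f"{self.sample_id}:{self.gene} mutant_reads {self.mutant_reads} > depth {self.depth}")
        if self.kg_freq is not None and not (0.0 <= self.kg_freq <= 1.0):
            raise ValueError(f"kg_freq {self.kg_freq} outside [0,1]")

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


def fusion_category(gene_a: str, gene_b: str) -> str:
    """Deterministic category label for a fusion partner pair.

    Named fusions (RUNX1-RUNX1T1, NUP98-NSD1, ...) keep their canonical
    name; remaining KMT2A / NUP98 partnerships collapse to
    "<gene>-rearranged"; anything else is labeled "other-fusion".
    """
    pair = frozenset((gene_a, gene_b))
    if pair in NAMED_FUSIONS:
        return NAMED_FUSIONS[pair]
    for g in REARRANGEMENT_GENES:
        if g in pair:
            return f"{g}-rearranged"
    return "other-fusion"


@dataclass
class FusionCall:
    sample_id: str
    gene_a: str
    gene_b: str
    in_frame: bool = True
    internal: bool = False
    category: str = field(default="")

    def __post_init__(self):
        if self.gene_a == self.gene_b and not self.internal:
            raise ValueError(
                f"{self.sample_id}: {self.gene_a} fused to itself without internal flag")
        if not self.category:
            self.category = fusion_category(self.gene_a, self.gene_b)


KARYOTYPE_FLAGS = ("complex", "monosomal", "minus7", "minus17", "del5q")


@dataclass
class PatientRecord:
    sample_id: str
    age_years: float
    fab: str = "unknown"
    protocol: str = ""
    cr1: Optional[bool] = None           # None = unknown
    karyotype_flags: frozenset = frozenset()
    efs_time: float = 0.0
    efs_event: bool = False
    os_time: float = 0.0
    os_event: bool = False
    abandonment: bool = False

    def __post_init__(self):
        if self.age_years < 0:
            raise ValueError(f"{self.sample_id}: negative age")
        if self.efs_time < 0 or self.os_time < 0:
            raise ValueError(f"{self.sample_id}: negative survival time")
        if not (math.isfinite(self.efs_time) and math.isfinite(self.os_time)):
            raise ValueError(f"{self.sample_id}: non-finite survival time")
        if self.efs_time > self.os_time + 1e-9:
            raise ValueError(
                f"{self.sample_id}: efs_time {self.efs_time} exceeds os_time {self.os_time}")
        unknown = set(self.karyotype_flags) - set(KARYOTYPE_FLAGS)
        if unknown:
            raise ValueError(f"{self.sample_id}: unknown karyotype flags {sorted(unknown)}")
        object.__setattr__(self, "karyotype_flags", frozenset(self.karyotype_flags))


@dataclass(frozen=True)
class DriverEvent:
    """Unified per-patient driver record.

    ``kind`` is mutation / fusion / itd / focal_deletion; ``feature`` is the
    canonical label used in the cohort matrix (gene symbol, hotspot label
    such as "KIT-E17", fusion category, "FLT3-ITD", "CBL-del-ex8/9").
    """

    sample_id: str
    kind: str
    feature: str
    source: Optional[str] = None


# --------------------------------------------------------------------------
# Hotspot label primitive (shared with landscape.assign_hotspots)
# --------------------------------------------------------------------------

def hotspot_labels_for(gene: str, protein_pos: Optional[int],
                       defs: Sequence[HotspotDefinition] = DEFAULT_HOTSPOTS) -> list[str]:
    """All hotspot labels whose aa range contains the given position.

    Overlapping definitions (FLT3-TKD inside FLT3-AL) each contribute a
    label; event-kind definitions (ITD, focal deletions) never match a
    protein position.
    """
    if protein_pos is None:
        return []
    labels = []
    for d in defs:
        if d.gene != gene or d.kind == "event":
            continue
        lo, hi = d.resolved_range()
        if lo <= protein_pos <= hi:
            labels.append(d.label)
    return labels


# --------------------------------------------------------------------------
# Variant table I/O
# --------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt", "consequence",
    "protein_pos", "aa_change", "vaf", "depth", "mutant_reads",
    "cosmic_count", "kg_freq", "clinvar_sig", "sift", "polyphen",
    "is_tsg", "prior_pediatric_report", "level",
]
_MANDATORY = VARIANT_COLUMNS[:7] + ["vaf", "depth", "mutant_reads"]


def _opt_str(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "" or v == ".":
        return None
    return str(v)


def _opt_float(v, line: int, col: str) -> Optional[float]:
    s = _opt_str(v)
    if s is None:
        return None
    try:
        return float(s)
    except ValueError:
        raise RowError(line, f"unparsable {col}: {v!r}")


def _opt_int(v, line: int, col: str) -> Optional[int]:
    f = _opt_float(v, line, col)
    return None if f is None else int(round(f))


def _bool(v) -> bool:
    return str(v).strip().lower() in ("1", "true", "t", "yes", "y")


def _row_to_variant(row: dict, line: int) -> VariantCall:
    try:
        return VariantCall(
            sample_id=str(row["sample_id"]),
            gene=str(row["gene"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            consequence=str(row["consequence"]),
            protein_pos=_opt_int(row.get("protein_pos"), line, "protein_pos"),
            aa_change=_opt_str(row.get("aa_change")) or "",
            vaf=_must_float(row.get("vaf"), line, "vaf"),
            depth=_must_int(row.get("depth"), line, "depth"),
            mutant_reads=_must_int(row.get("mutant_reads"), line, "mutant_reads"),
            cosmic_count=_opt_int(row.get("cosmic_count"), line, "cosmic_count") or 0,
            kg_freq=_opt_float(row.get("kg_freq"), line, "kg_freq"),
            clinvar_sig=_opt_str(row.get("clinvar_sig")),
            sift=_opt_str(row.get("sift")),
            polyphen=_opt_str(row.get("polyphen")),
            is_tsg=_bool(row.get("is_tsg", False)),
            prior_pediatric_report=_bool(row.get("prior_pediatric_report", False)),
            level=_opt_str(row.get("level")),
        )
    except RowError:
        raise
    except (ValueError, KeyError) as exc:
        raise RowError(line, str(exc))


def _must_float(v, line, col) -> float:
    f = _opt_float(v, line, col)
    if f is None:
        raise RowError(line, f"missing {col}")
    return f


def _must_int(v, line, col) -> int:
    i = _opt_int(v, line, col)
    if i is None:
        raise RowError(line, f"missing {col}")
    return i


def _read_variants_tsv(path: str) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"variant TSV missing mandatory column(s): {', '.join(missing)}")
    out = []
    for i, row in enumerate(df.to_dict("records")):
        out.append(_row_to_variant(row, line=i + 2))  # +2: header is line 1
    return out


# VCF dialect: standard VCF text, one record per sample-variant with the
# sample in INFO/SAMPLE and annotations in a CSQ field
# (Consequence|Gene|Protein_position|Amino_acids|SIFT|PolyPhen).
_VCF_INFO_KEYS = ("SAMPLE", "VAF", "DP", "MR", "COSMIC_CNT", "KG_AF",
                  "CLNSIG", "TSG", "PEDREP", "CSQ")


def _read_variants_vcf(path: str) -> list[VariantCall]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) < 8:
                raise RowError(lineno, f"VCF record with {len(parts)} fields")
            chrom, pos, _id, ref, alt, _qual, _filter, info = parts[:8]
            kv = {}
            for item in info.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k] = v
                else:
                    kv[item] = "1"
            csq = kv.get("CSQ", "")
            fields = csq.split("|")
            fields += [""] * (6 - len(fields))
            consequence, gene, ppos, aa, sift, polyphen = fields[:6]
            if "SAMPLE" not in kv:
                raise RowError(lineno, "VCF record missing INFO/SAMPLE")
            row = {
                "sample_id": kv["SAMPLE"], "gene": gene, "chrom": chrom,
                "pos": pos, "ref": ref, "alt": alt, "consequence": consequence,
                "protein_pos": ppos, "aa_change": aa,
                "vaf": kv.get("VAF", ""), "depth": kv.get("DP", ""),
                "mutant_reads": kv.get("MR", ""),
                "cosmic_count": kv.get("COSMIC_CNT", ""),
                "kg_freq": kv.get("KG_AF", ""),
                "clinvar_sig": kv.get("CLNSIG", "").replace("_", " ") or None,
                "sift": sift, "polyphen": polyphen,
                "is_tsg": kv.get("TSG", "0"), "prior_pediatric_report": kv.get("PEDREP", "0"),
                "level": None,
            }
            out.append(_row_to_variant(row, lineno))
    return out


def read_variants(path: str, dialect: str = "tsv") -> list[VariantCall]:
    """Read a variant table in the ``tsv`` (MAF-like) or ``vcf_csq`` dialect."""
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf_csq":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'vcf_csq')")


def variants_to_frame(variants: Iterable[VariantCall]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append({
            "sample_id": v.sample_id, "gene": v.gene, "chrom": v.chrom,
            "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "consequence": v.consequence,
            "protein_pos": "" if v.protein_pos is None else v.protein_pos,
            "aa_change": v.aa_change, "vaf": v.vaf, "depth": v.depth,
            "mutant_reads": v.mutant_reads, "cosmic_count": v.cosmic_count,
            "kg_freq": "" if v.kg_freq is None else v.kg_freq,
            "clinvar_sig": v.clinvar_sig or "", "sift": v.sift or "",
            "polyphen": v.polyphen or "",
            "is_tsg": int(v.is_tsg),
            "prior_pediatric_report": int(v.prior_pediatric_report),
            "level": v.level or "",
        })
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_variants_tsv(variants: Iterable[VariantCall], path: str) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample identifier">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=MR,Number=1,Type=Integer,Description="Mutant reads">
##INFO=<ID=COSMIC_CNT,Number=1,Type=Integer,Description="COSMIC recurrence count">
##INFO=<ID=KG_AF,Number=1,Type=Float,Description="1000 Genomes allele frequency">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar significance">
##INFO=<ID=TSG,Number=1,Type=Integer,Description="Known tumor suppressor gene">
##INFO=<ID=PEDREP,Number=1,Type=Integer,Description="Previously reported in pediatric cancer genomics">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence|Gene|Protein_position|Amino_acids|SIFT|PolyPhen">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(variants: Iterable[VariantCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for v in variants:
            csq = "|".join([
                v.consequence, v.gene,
                "" if v.protein_pos is None else str(v.protein_pos),
                v.aa_change, v.sift or "", v.polyphen or "",
            ])
            info = [f"SAMPLE={v.sample_id}", f"VAF={v.vaf:g}", f"DP={v.depth}",
                    f"MR={v.mutant_reads}", f"COSMIC_CNT={v.cosmic_count}"]
            if v.kg_freq is not None:
                info.append(f"KG_AF={v.kg_freq:g}")
            if v.clinvar_sig:
                info.append(f"CLNSIG={v.clinvar_sig.replace(' ', '_')}")
            info += [f"TSG={int(v.is_tsg)}", f"PEDREP={int(v.prior_pediatric_report)}",
                     f"CSQ={csq}"]
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{';'.join(info)}\n")


# --------------------------------------------------------------------------
# Fusion & clinical table I/O
# --------------------------------------------------------------------------

def read_fusions(path: str) -> list[FusionCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = {"sample_id", "gene_a", "gene_b"}
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"fusion TSV missing column(s): {', '.join(sorted(missing))}")
    out = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            out.append(FusionCall(
                sample_id=row["sample_id"], gene_a=row["gene_a"],
                gene_b=row["gene_b"],
                in_frame=_bool(row.get("in_frame", "true")),
                internal=_bool(row.get("internal", "false")),
            ))
        except ValueError as exc:
            raise RowError(i + 2, str(exc))
    return out


FUSION_COLUMNS = ["sample_id", "gene_a", "gene_b", "in_frame", "internal", "category"]


def write_fusions_tsv(fusions: Iterable[FusionCall], path: str) -> None:
    rows = [{
        "sample_id": f.sample_id, "gene_a": f.gene_a, "gene_b": f.gene_b,
        "in_frame": int(f.in_frame), "internal": int(f.internal),
        "category": f.category,
    } for f in fusions]
    pd.DataFrame(rows, columns=FUSION_COLUMNS).to_csv(path, sep="\t", index=False)


CLINICAL_COLUMNS = ["sample_id", "age_years", "fab", "protocol", "cr1",
                    "karyotype_flags", "efs_time", "efs_event", "os_time",
                    "os_event", "abandonment"]


def read_clinical(path: str) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    need = {"sample_id", "age_years", "efs_time", "efs_event", "os_time", "os_event"}
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"clinical CSV missing column(s): {', '.join(sorted(missing))}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"duplicate sample_id in clinical table: {dup.iloc[0]}")
    out = []
    for i, row in enumerate(df.to_dict("records")):
        cr1_raw = _opt_str(row.get("cr1"))
        cr1 = None if cr1_raw is None or cr1_raw.lower() == "unknown" else _bool(cr1_raw)
        flags = frozenset(f for f in str(row.get("karyotype_flags", "")).split("|") if f)
        try:
            out.append(PatientRecord(
                sample_id=row["sample_id"],
                age_years=_must_float(row["age_years"], i + 2, "age_years"),
                fab=_opt_str(row.get("fab")) or "unknown",
                protocol=_opt_str(row.get("protocol")) or "",
                cr1=cr1, karyotype_flags=flags,
                efs_time=_must_float(row["efs_time"], i + 2, "efs_time"),
                efs_event=_bool(row["efs_event"]),
                os_time=_must_float(row["os_time"], i + 2, "os_time"),
                os_event=_bool(row["os_event"]),
                abandonment=_bool(row.get("abandonment", "0")),
            ))
        except RowError:
            raise
        except ValueError as exc:
            raise RowError(i + 2, str(exc))
    return out


def write_clinical_csv(patients: Iterable[PatientRecord], path: str) -> None:
    rows = [{
        "sample_id": p.sample_id, "age_years": p.age_years, "fab": p.fab,
        "protocol": p.protocol,
        "cr1": "unknown" if p.cr1 is None else int(p.cr1),
        "karyotype_flags": "|".join(sorted(p.karyotype_flags)),
        "efs_time": p.efs_time, "efs_event": int(p.efs_event),
        "os_time": p.os_time, "os_event": int(p.os_event),
        "abandonment": int(p.abandonment),
    } for p in patients]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Cohort matrix
# --------------------------------------------------------------------------

@dataclass
class CohortMatrix:
    """Boolean sample x feature presence matrix with a pathway map."""

    presence: pd.DataFrame                 # bool, index=samples, columns=features
    pathway_map: dict = field(default_factory=dict)
    low_recurrence: frozenset = frozenset()

    @property
    def samples(self) -> list[str]:
        return list(self.presence.index)

    @property
    def features(self) -> list[str]:
        return list(self.presence.columns)

    def recurrence_counts(self) -> pd.Series:
        return self.presence.sum(axis=0)

    def recurrence_fractions(self) -> pd.Series:
        return self.presence.mean(axis=0)


def events_from_calls(driver_variants: Sequence[VariantCall],
                      fusions: Sequence[FusionCall] = (),
                      itds: Sequence[DriverEvent] = (),
                      deletions: Sequence[DriverEvent] = (),
                      hotspot_defs: Sequence[HotspotDefinition] = DEFAULT_HOTSPOTS,
                      ) -> list[DriverEvent]:
    """Expand nominated calls into DriverEvents (gene + hotspot features)."""
    events: list[DriverEvent] = []
    for v in driver_variants:
        src = f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}"
        events.append(DriverEvent(v.sample_id, "mutation", v.gene, src))
        for label in hotspot_labels_for(v.gene, v.protein_pos, hotspot_defs):
            events.append(DriverEvent(v.sample_id, "mutation", label, src))
    for f in fusions:
        events.append(DriverEvent(f.sample_id, "fusion", f.category,
                                  f"{f.gene_a}-{f.gene_b}"))
    events.extend(itds)
    events.extend(deletions)
    return events


def build_cohort_matrix(driver_variants: Sequence[VariantCall] = (),
                        fusions: Sequence[FusionCall] = (),
                        itds: Sequence[DriverEvent] = (),
                        deletions: Sequence[DriverEvent] = (),
                        samples: Optional[Sequence[str]] = None,
                        hotspot_defs: Sequence[HotspotDefinition] = DEFAULT_HOTSPOTS,
                        pathway_map: Optional[dict] = None,
                        min_recurrence: int = 3,
                        ) -> CohortMatrix:
    """Assemble the boolean patient x driver-feature matrix.

    Duplicate events collapse to a single True (idempotence).  Features
    seen in fewer than ``min_recurrence`` samples are retained but flagged
    in ``low_recurrence``.  ``samples`` fixes the row universe (samples
    without events keep an all-False row); by default rows are the samples
    carrying at least one event.
    """
    events = events_from_calls(driver_variants, fusions, itds, deletions, hotspot_defs)
    if samples is None:
        samples = sorted({e.sample_id for e in events})
    samples = list(samples)
    features = sorted({e.feature for e in events})
    presence = pd.DataFrame(False, index=samples, columns=features, dtype=bool)
    for e in events:
        if e.sample_id in presence.index:
            presence.loc[e.sample_id, e.feature] = True
    counts = presence.sum(axis=0)
    low = frozenset(counts.index[counts < min_recurrence])
    return CohortMatrix(presence=presence,
                        pathway_map=dict(pathway_map or DEFAULT_PATHWAY_MAP),
                        low_recurrence=low)
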