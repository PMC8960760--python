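"""Table parsing, round-trips, fusion categories and the cohort matrix."""

import pandas as pd
import pytest

from pedaml import (
    FusionCall,
    PatientRecord,
    RowError,
    SchemaError,
    build_cohort_matrix,
    fusion_category,
    read_clinical,
    read_fusions,
    read_variants,
    write_clinical_csv,
    write_fusions_tsv,
    write_variants_tsv,
    write_variants_vcf,
)
from pedaml.cohort import VARIANT_COLUMNS

from conftest import make_variant


# ---------------------------------------------------------------- variants

def test_empty_variant_table_gives_empty_list(tmp_path):
    p = tmp_path / "v.tsv"
    p.write_text("\t".join(VARIANT_COLUMNS) + "\n")
    assert read_variants(str(p), "tsv") == []


def test_direct_parse_of_counts(tmp_path):
    v = make_variant(depth=7, mutant_reads=3, vaf=3 / 7)
    p = tmp_path / "v.tsv"
    write_variants_tsv([v], str(p))
    (got,) = read_variants(str(p), "tsv")
    assert got.depth == 7 and got.mutant_reads == 3


def test_tsv_and_vcf_dialects_normalize_identically(tmp_path):
    variants = [
        make_variant(),
        make_variant(sample_id="S2", gene="TP53", chrom="chr17", pos=7_577_120,
                     ref="C", alt="A", consequence="stop_gained", protein_pos=213,
                     aa_change="p.R213*", vaf=0.5, depth=40, mutant_reads=20,
                     cosmic_count=12, kg_freq=0.0002,
                     clinvar_sig="Pathogenic", sift="deleterious",
                     polyphen="probably_damaging", is_tsg=True,
                     prior_pediatric_report=True),
        make_variant(sample_id="S3", protein_pos=None, aa_change="",
                     consequence="splice_donor"),
    ]
    t, v = tmp_path / "v.tsv", tmp_path / "v.vcf"
    write_variants_tsv(variants, str(t))
    write_variants_vcf(variants, str(v))
    from_tsv = read_variants(str(t), "tsv")
    from_vcf = read_variants(str(v), "vcf_csq")
    for a, b, orig in zip(from_tsv, from_vcf, variants):
        for f in ("sample_id", "gene", "chrom", "pos", "ref", "alt",
                  "consequence", "protein_pos", "cosmic_count", "kg_freq",
                  "clinvar_sig", "sift", "polyphen", "is_tsg",
                  "prior_pediatric_report", "depth", "mutant_reads"):
            assert getattr(a, f) == getattr(b, f) == getattr(orig, f), f
        assert a.vaf == pytest.approx(b.vaf) == pytest.approx(orig.vaf)


def test_missing_mandatory_column_names_it(tmp_path):
    cols = [c for c in VARIANT_COLUMNS if c != "vaf"]
    p = tmp_path / "v.tsv"
    p.write_text("\t".join(cols) + "\n")
    with pytest.raises(SchemaError, match="vaf"):
        read_variants(str(p), "tsv")


def test_unparsable_vaf_reports_line_number(tmp_path):
    df = pd.DataFrame([{c: "" for c in VARIANT_COLUMNS}])
    df.update(pd.DataFrame([{
        "sample_id": "S1", "gene": "KIT", "chrom": "chr4", "pos": 1,
        "ref": "A", "alt": "T", "consequence": "missense",
        "vaf": "not-a-number", "depth": 10, "mutant_reads": 3}]))
    p = tmp_path / "v.tsv"
    df.to_csv(p, sep="\t", index=False)
    with pytest.raises(RowError, match="line 2"):
        read_variants(str(p), "tsv")


def test_missing_optional_annotations_stay_absent(tmp_path):
    v = make_variant(kg_freq=None, clinvar_sig=None, sift=None, polyphen=None)
    p = tmp_path / "v.tsv"
    write_variants_tsv([v], str(p))
    (got,) = read_variants(str(p), "tsv")
    assert got.kg_freq is None and got.clinvar_sig is None
    assert got.sift is None and got.polyphen is None


def test_variant_invariants_rejected():
    with pytest.raises(ValueError):
        make_variant(mutant_reads=50, depth=40)
    with pytest.raises(ValueError):
        make_variant(vaf=1.5)


# ----------------------------------------------------------------- fusions

@pytest.mark.parametrize("a,b,expected", [
    ("KMT2A", "MLLT3", "KMT2A-rearranged"),
    ("MLLT10", "KMT2A", "KMT2A-rearranged"),
    ("NUP98", "NSD1", "NUP98-NSD1"),
    ("NSD1", "NUP98", "NUP98-NSD1"),
    ("NUP98", "HOXA9", "NUP98-rearranged"),
    ("RUNX1", "RUNX1T1", "RUNX1-RUNX1T1"),
    ("PTPRA", "FUS", "other-fusion"),
])
def test_fusion_category_rules(a, b, expected):
    assert fusion_category(a, b) == expected


def test_fusion_roundtrip_and_self_fusion_guard(tmp_path):
    calls = [FusionCall("S1", "KMT2A", "MLLT3"), FusionCall("S2", "NUP98", "NSD1")]
    p = tmp_path / "f.tsv"
    write_fusions_tsv(calls, str(p))
    got = read_fusions(str(p))
    assert [(f.sample_id, f.category) for f in got] == \
        [("S1", "KMT2A-rearranged"), ("S2", "NUP98-NSD1")]
    with pytest.raises(ValueError):
        FusionCall("S3", "FLT3", "FLT3")


# ---------------------------------------------------------------- clinical

def _patient(**kw):
    base = dict(sample_id="P1", age_years=4.0, efs_time=2.0, os_time=3.0)
    base.update(kw)
    return PatientRecord(**base)


def test_clinical_roundtrip_preserves_unknown_cr1(tmp_path):
    pats = [_patient(cr1=None), _patient(sample_id="P2", cr1=True,
                                         karyotype_flags=frozenset({"minus7"}))]
    p = tmp_path / "c.csv"
    write_clinical_csv(pats, str(p))
    got = read_clinical(str(p))
    assert got[0].cr1 is None
    assert got[1].cr1 is True and got[1].karyotype_flags == frozenset({"minus7"})


def test_clinical_validation_errors(tmp_path):
    with pytest.raises(ValueError, match="efs_time"):
        _patient(efs_time=5.0, os_time=3.0)
    with pytest.raises(ValueError):
        _patient(efs_time=-1.0)
    pats = [_patient(), _patient()]  # duplicate sample_id
    p = tmp_path / "c.csv"
    write_clinical_csv(pats, str(p))
    with pytest.raises(SchemaError, match="duplicate"):
        read_clinical(str(p))


# ------------------------------------------------------------ cohort matrix

def test_matrix_kit_d816v_sets_gene_and_hotspot():
    m = build_cohort_matrix([make_variant()])  # KIT D816V
    assert bool(m.presence.loc["S1", "KIT"]) and bool(m.presence.loc["S1", "KIT-E17"])


def test_matrix_no_events_all_false():
    m = build_cohort_matrix([], samples=["A", "B"])
    assert m.presence.shape == (2, 0)
    assert not m.presence.to_numpy().any()


def test_matrix_duplicate_events_idempotent():
    m = build_cohort_matrix([make_variant(), make_variant()])
    assert int(m.presence.loc["S1", "KIT"]) == 1
    assert m.recurrence_counts()["KIT"] == 1


def test_matrix_column_sums_match_event_list(small_cohort):
    from pedaml import events_from_calls
    variants = [v for v in small_cohort.variants if v.cosmic_count >= 3]
    m = build_cohort_matrix(variants, small_cohort.fusions,
                            small_cohort.itds, small_cohort.deletions,
                            samples=[p.sample_id for p in small_cohort.patients])
    events = events_from_calls(variants, small_cohort.fusions,
                               small_cohort.itds, small_cohort.deletions)
    for feat in m.features:
        independent = len({e.sample_id for e in events if e.feature == feat})
        assert m.recurrence_counts()[feat] == independent


def test_low_recurrence_features_flagged_not_dropped():
    vs = [make_variant(sample_id=f"S{i}") for i in range(3)]
    vs.append(make_variant(sample_id="S9", gene="NRAS", protein_pos=12, pos=999))
    m = build_cohort_matrix(vs, min_recurrence=3)
    assert "NRAS" in m.features and "NRAS" in m.low_recurrence
    assert "KIT" not in m.low_recurrence
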