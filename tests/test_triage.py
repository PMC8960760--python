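"""Exclusion rules, L1/L2/L3 grading, artifact derivation, concordance."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from pedaml import (
    ArtifactList,
    apply_exclusions,
    assign_level,
    concordance,
    derive_artifact_list,
    triage_cohort,
    triage_variant,
)
from pedaml.config import DEFAULT_IGTCR_REGIONS

from conftest import make_variant

CGC = frozenset({"KIT", "NRAS", "TP53"})


# ------------------------------------------------------------- exclusions

@pytest.mark.parametrize("kw,rule", [
    (dict(chrom="chr14", pos=105_600_000), "igtcr"),
    (dict(depth=7, mutant_reads=3, vaf=3 / 7), "read_support"),
    (dict(depth=100, mutant_reads=2, vaf=0.02), "read_support"),
    (dict(kg_freq=0.002), "kg_freq"),
    (dict(consequence="synonymous"), "consequence"),
])
def test_each_exclusion_rule_fires(kw, rule):
    fired = apply_exclusions(make_variant(**kw), igtcr_regions=DEFAULT_IGTCR_REGIONS)
    assert rule in fired


def test_artifact_list_membership_fires():
    v = make_variant()
    artifacts = ArtifactList(frozenset({(v.chrom, v.pos, v.ref, v.alt)}))
    assert "artifact" in apply_exclusions(v, artifacts)


def test_no_rule_fires_on_clean_variant():
    v = make_variant(kg_freq=0.0005, depth=100, mutant_reads=30, vaf=0.3)
    assert apply_exclusions(v, igtcr_regions=DEFAULT_IGTCR_REGIONS) == ()


def test_threshold_boundaries():
    # depth 8 / mutant reads 3 are the weakest admissible support
    ok = make_variant(depth=8, mutant_reads=3, vaf=3 / 8)
    assert "read_support" not in apply_exclusions(ok)
    # kg_freq exactly 0.001 is retained (rule is strict >)
    assert "kg_freq" not in apply_exclusions(make_variant(kg_freq=0.001))


def test_exclusions_order_independent():
    v = make_variant(consequence="synonymous", kg_freq=0.5, depth=5,
                     mutant_reads=1, vaf=0.2)
    regions = list(DEFAULT_IGTCR_REGIONS)
    fired = set(apply_exclusions(v, igtcr_regions=regions))
    for perm in itertools.islice(itertools.permutations(regions), 5):
        assert set(apply_exclusions(v, igtcr_regions=list(perm))) == fired


# ------------------------------------------------------------------ levels

L1_CASES = {
    "c1": dict(cosmic_count=5, vaf=0.25),
    "c2": dict(prior_pediatric_report=True),
    "c3": dict(consequence="frameshift", is_tsg=True),
    "c4": dict(clinvar_sig="Likely Pathogenic"),
    "c5": dict(vaf=0.2, sift="deleterious", polyphen="possibly_damaging",
               gene="KIT", kg_freq=None),
}


@pytest.mark.parametrize("crit", sorted(L1_CASES))
def test_each_l1_criterion_alone_grades_l1(crit):
    v = make_variant(**L1_CASES[crit])
    assert assign_level(v, CGC) == "L1"
    trace = triage_variant(v, cgc_genes=CGC)
    assert crit in trace.l1_criteria_met and trace.level == "L1"


def test_l2_recurrent_subclonal():
    # COSMIC-recurrent at subclonal VAF, no L1 evidence
    v = make_variant(cosmic_count=4, vaf=0.05, mutant_reads=5, depth=100)
    assert assign_level(v) == "L2"


def test_l2_recurrent_absent_from_1000g_clause():
    # present in 1000G at low frequency and clonal: c1 applies (L1);
    # strip recurrence -> falls through to L3
    v = make_variant(cosmic_count=4, vaf=0.05, mutant_reads=5, depth=100,
                     kg_freq=0.0005)
    assert assign_level(v) == "L2"  # vaf <= 0.1 branch


def test_l3_fallthrough():
    v = make_variant(cosmic_count=0, vaf=0.4, mutant_reads=40, depth=100)
    assert assign_level(v, CGC) == "L3"


def test_vaf_boundary_prefers_l1():
    v = make_variant(cosmic_count=3, vaf=0.1, mutant_reads=10, depth=100)
    assert assign_level(v) == "L1"


def test_c5_requires_all_conjuncts():
    base = L1_CASES["c5"]
    for knock in (dict(vaf=0.05, mutant_reads=5), dict(sift="tolerated"),
                  dict(polyphen="benign"), dict(gene="ZZZ3"),
                  dict(kg_freq=0.0001)):
        v = make_variant(**{**base, **knock})
        assert "c5" not in triage_variant(v, cgc_genes=CGC).l1_criteria_met


def test_triage_total_and_trace_rederives(small_cohort):
    traces = triage_cohort(small_cohort.variants,
                           igtcr_regions=DEFAULT_IGTCR_REGIONS, cgc_genes=CGC)
    assert len(traces) == len(small_cohort.variants)
    for t in traces:
        assert t.level in ("EXCLUDED", "L1", "L2", "L3")
        # audit: the decision is re-derivable from the trace
        if t.fired_exclusions:
            assert t.level == "EXCLUDED"
        elif t.l1_criteria_met:
            assert t.level == "L1"
        elif t.l2_met:
            assert t.level == "L2"
        else:
            assert t.level == "L3"


_ORDER = {"L3": 0, "L2": 1, "L1": 2}


@settings(max_examples=200, derandomize=True)
@given(cosmic=st.integers(0, 10), vaf_pct=st.integers(1, 99),
       dc=st.integers(0, 5), dv=st.integers(0, 30),
       kg_present=st.booleans())
def test_level_monotone_in_cosmic_and_vaf(cosmic, vaf_pct, dc, dv, kg_present):
    """Raising COSMIC recurrence or VAF never demotes the level."""
    kg = 0.0005 if kg_present else None
    def lvl(c, vp):
        v = make_variant(cosmic_count=c, vaf=vp / 100, depth=100,
                         mutant_reads=vp, kg_freq=kg)
        return _ORDER[assign_level(v, CGC)]
    assert lvl(cosmic + dc, min(vaf_pct + dv, 99)) >= lvl(cosmic, vaf_pct)


# --------------------------------------------------------- artifact deriv.

def _site_calls(n_samples, site_samples, chrom="chr1", pos=123):
    calls = [make_variant(sample_id=f"S{i}", gene="GENE", chrom=chrom, pos=pos)
             for i in range(site_samples)]
    # pad cohort with unrelated singleton calls so the denominator is n_samples
    calls += [make_variant(sample_id=f"S{i}", chrom="chr9", pos=5000 + i)
              for i in range(n_samples)]
    return calls


def test_artifact_derivation_counting_oracle():
    calls = _site_calls(100, 20)
    al = derive_artifact_list(calls, min_sample_fraction=0.05)
    assert ("chr1", 123, "A", "T") in al


def test_artifact_whitelist_override():
    calls = _site_calls(100, 20)
    al = derive_artifact_list(calls, 0.05,
                              hotspot_whitelist=frozenset({("chr1", 123, "A", "T")}))
    assert ("chr1", 123, "A", "T") not in al


def test_rare_site_not_an_artifact():
    calls = _site_calls(100, 1)
    al = derive_artifact_list(calls, 0.05)
    assert ("chr1", 123, "A", "T") not in al


def test_empty_cohort_empty_artifact_list():
    assert derive_artifact_list([], 0.05).sites == frozenset()


# ------------------------------------------------------------- concordance

def test_concordance_recovery_fraction():
    truth = [("S", "G", f"p.{i}") for i in range(21)]
    calls = truth[:18] + [("S", "NRAS", "p.G13D")]
    res = concordance(truth, calls)
    assert res.recovery == pytest.approx(18 / 21)
    assert round(res.recovery, 3) == 0.857
    assert res.extra == [("S", "NRAS", "p.G13D")]


def test_concordance_identity_disjoint_empty():
    t = [("S", "G", "p.1")]
    assert concordance(t, t).recovery == 1.0
    assert concordance(t, [("S", "G", "p.2")]).recovery == 0.0
    assert concordance([], t).recovery is None
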