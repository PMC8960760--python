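"""Recurrence, hotspot, cross-cohort and co-occurrence statistics.

Per-feature recurrence is compared between cohorts (e.g. an East-Asian vs
a Western pediatric AML cohort) with two-sided Fisher exact tests on
mutated / not-mutated x cohort 2x2 tables, overall and within the <3 y and
3-14 y age strata, with Benjamini-Hochberg correction across the compared
features.  Pairwise co-occurrence / mutual exclusivity between driver
features (FAB groups enter as pseudo-features) uses the same exact test;
the direction is read off the odds ratio.  Pairs formed by fusion
partners or by two domains of one gene are flagged so they can be set
aside from the analytic pair count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .cohort import CohortMatrix, VariantCall, hotspot_labels_for
from .config import DEFAULT_HOTSPOTS, HotspotDefinition


# --------------------------------------------------------------------------
# Hotspot assignment
# --------------------------------------------------------------------------

def assign_hotspots(driver_mutations: Sequence[VariantCall],
                    defs: Sequence[HotspotDefinition] = DEFAULT_HOTSPOTS,
                    known_genes: Optional[frozenset] = None,
                    ) -> list[tuple[VariantCall, tuple[str, ...]]]:
    """Label each driver mutation with its gene plus every matching hotspot.

    A mutation may carry several labels (FLT3 aa 835 lies in both the TKD
    and the activation-loop definitions); the gene-level feature is always
    retained alongside.  ``known_genes`` (when given) validates the
    definitions' gene symbols up front.
    """
    if known_genes is not None:
        bad = sorted({d.gene for d in defs} - set(known_genes))
        if bad:
            raise ValueError(f"hotspot definitions reference unknown gene(s): {', '.join(bad)}")
    out = []
    for v in driver_mutations:
        labels = (v.gene, *hotspot_labels_for(v.gene, v.protein_pos, defs))
        out.append((v, labels))
    return out


# --------------------------------------------------------------------------
# Cross-cohort comparison
# --------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    feature: str
    stratum: str                     # "overall", "<3", "3-14"
    count_a: int
    n_a: int
    count_b: int
    n_b: int
    p_value: float
    q_value: Optional[float] = None
    direction: str = "none"          # "higher_in_a" | "higher_in_b" | "none"


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]]."""
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def compare_counts(feature: str, count_a: int, n_a: int, count_b: int, n_b: int,
                   stratum: str = "overall") -> ComparisonResult:
    """Compare one feature's recurrence between two cohorts from counts."""
    if count_a > n_a or count_b > n_b:
        raise ValueError(f"{feature}: count exceeds denominator")
    p = fisher_2x2(count_a, n_a - count_a, count_b, n_b - count_b)
    fa = count_a / n_a if n_a else 0.0
    fb = count_b / n_b if n_b else 0.0
    direction = "higher_in_a" if fa > fb else ("higher_in_b" if fb > fa else "none")
    return ComparisonResult(feature, stratum, count_a, n_a, count_b, n_b, p,
                            direction=direction)


def compare_cohorts(matrix_a: CohortMatrix, matrix_b: CohortMatrix,
                    features: Optional[Sequence[str]] = None,
                    ages_a: Optional[pd.Series] = None,
                    ages_b: Optional[pd.Series] = None,
                    age_cut: float = 3.0, age_max: float = 15.0,
                    ) -> list[ComparisonResult]:
    """Per-feature Fisher tests overall and per age stratum, BH-adjusted.

    Age strata are <3 years and 3-14 years (an exact 3.0 falls into the
    older stratum).  A feature missing from one cohort counts as zero
    mutated there; a zero-size stratum skips the feature with a warning
    note in the result list (the feature is simply absent for that
    stratum).  BH correction is applied within each stratum across the
    compared features.
    """
    if features is None:
        features = sorted(set(matrix_a.features) | set(matrix_b.features))

    def counts(matrix: CohortMatrix, ages: Optional[pd.Series], stratum: str):
        idx = pd.Index(matrix.samples)
        if stratum != "overall":
            if ages is None:
                return None
            ages = ages.reindex(idx)
            if stratum == "<3":
                keep = ages < age_cut
            else:
                keep = (ages >= age_cut) & (ages < age_max)
            idx = idx[keep.fillna(False).to_numpy(dtype=bool)]
        return matrix.presence.loc[idx]

    results: list[ComparisonResult] = []
    for stratum in ("overall", "<3", "3-14"):
        sub_a = counts(matrix_a, ages_a, stratum)
        sub_b = counts(matrix_b, ages_b, stratum)
        if sub_a is None or sub_b is None or len(sub_a) == 0 or len(sub_b) == 0:
            continue
        batch = []
        for f in features:
            ca = int(sub_a[f].sum()) if f in sub_a.columns else 0
            cb = int(sub_b[f].sum()) if f in sub_b.columns else 0
            batch.append(compare_counts(f, ca, len(sub_a), cb, len(sub_b), stratum))
        q = multipletests([r.p_value for r in batch], method="fdr_bh")[1]
        for r, qv in zip(batch, q):
            r.q_value = float(qv)
        results.extend(batch)
    return results


# --------------------------------------------------------------------------
# Pairwise co-occurrence / mutual exclusivity
# --------------------------------------------------------------------------

@dataclass
class PairCorrelation:
    feature_1: str
    feature_2: str
    n11: int
    n10: int
    n01: int
    n00: int
    p_value: float
    direction: str                   # "co-occur" | "exclusive" | "none"
    same_gene_or_partner: bool = False
    q_value: Optional[float] = None


def _same_gene_or_partner(f1: str, f2: str) -> bool:
    """True for pairs joined by a shared gene symbol (a gene and its own
    hotspot/domain, or two domains of one gene) or by fusion partnership
    (a feature naming a gene that appears in the other's fusion label)."""
    def parts(f: str) -> set:
        return set(f.replace("/", "-").split("-"))
    return bool(parts(f1) & parts(f2))


def pairwise_correlation(matrix: CohortMatrix,
                         features: Optional[Sequence[str]] = None,
                         fab_labels: Optional[pd.Series] = None,
                         ) -> list[PairCorrelation]:
    """Fisher exact test on every unordered feature pair.

    FAB groups, when given as a per-sample series, join the feature set as
    pseudo-features ("FAB-M5", ...).  Constant features (all True or all
    False) are skipped.  Direction comes from the sample odds ratio
    (cross-product on the 2x2); pairs between fusion partners or domains
    of a single gene are flagged rather than dropped.
    """
    pres = matrix.presence.copy()
    if fab_labels is not None:
        fab_labels = fab_labels.reindex(pres.index)
        for fab in sorted(x for x in fab_labels.dropna().unique() if x != "unknown"):
            pres[f"FAB-{fab}"] = (fab_labels == fab).to_numpy()
    if features is None:
        features = list(pres.columns)
    out = []
    for f1, f2 in combinations(features, 2):
        a = pres[f1].to_numpy(dtype=bool)
        b = pres[f2].to_numpy(dtype=bool)
        if a.all() or (~a).all() or b.all() or (~b).all():
            continue  # constant feature: association undefined
        n11 = int((a & b).sum()); n10 = int((a & ~b).sum())
        n01 = int((~a & b).sum()); n00 = int((~a & ~b).sum())
        p = fisher_2x2(n11, n10, n01, n00)
        cross = n11 * n00 - n10 * n01
        direction = "co-occur" if cross > 0 else ("exclusive" if cross < 0 else "none")
        out.append(PairCorrelation(f1, f2, n11, n10, n01, n00, p, direction,
                                   _same_gene_or_partner(f1, f2)))
    if out:
        q = multipletests([r.p_value for r in out], method="fdr_bh")[1]
        for r, qv in zip(out, q):
            r.q_value = float(qv)
    return out


def significant_pairs(pairs: Sequence[PairCorrelation], alpha: float = 0.05,
                      exclude_flagged: bool = True) -> list[PairCorrelation]:
    """Pairs significant at the raw two-sided p < alpha convention; by
    default the same-gene / fusion-partner pairs are excluded (the
    150 -> 143 analytic-pair convention)."""
    return [r for r in pairs if r.p_value < alpha
            and not (exclude_flagged and r.same_gene_or_partner)]


# --------------------------------------------------------------------------
# Pathway rollup
# --------------------------------------------------------------------------

def pathway_rollup(matrix: CohortMatrix,
                   gene_features_only: bool = True) -> pd.Series:
    """Fraction of samples with >=1 event in each pathway (OR semantics).

    Features missing from the pathway map raise with the full list unless
    they are hotspot/fusion labels and ``gene_features_only`` is set, in
    which case only plain gene symbols are rolled up (hotspot labels would
    double-count their gene).
    """
    pmap = matrix.pathway_map
    features = matrix.features
    if gene_features_only:
        features = [f for f in features if f in pmap]
        unmapped = []
    else:
        unmapped = [f for f in matrix.features if f not in pmap]
    if unmapped:
        raise ValueError(f"features missing from pathway map: {', '.join(sorted(unmapped))}")
    pathways = sorted(set(pmap.values()))
    out = {}
    n = len(matrix.samples)
    for pw in pathways:
        members = [f for f in features if pmap[f] == pw]
        if not members or n == 0:
            out[pw] = 0.0
        else:
            out[pw] = float(matrix.presence[members].any(axis=1).mean())
    return pd.Series(out, name="mutated_fraction")
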