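"""Rule-based AML risk stratification: ELN-derived baseline and SCMC-pAML.

Both models map a patient's driver events, karyotype flags and (for
SCMC-pAML) first-induction remission status onto three risk tiers
{LR, IR, HR}.  The baseline follows ELN-2017-style genetic groups; the
revised SCMC-pAML model re-classifies lesions whose prognosis differs in
Chinese pediatric AML: FUS-ERG, CBFA2T3-GLIS2, NUP98-KDM5A and NUP98-NSD1
join the high-risk tier, KMT2A rearrangements move to intermediate, and
RUNX1-RUNX1T1 patients are subdivided by CR1 status and CSF3R / KIT
exon-17 co-mutation.  Rule tables are config data
(:data:`pedaml.config.ELN_RULES`, :data:`pedaml.config.SCMC_RULES`), so
the shipped reconstruction can be pinned to a published rule sheet by
editing config rather than code.

Every assignment carries the id of the rule that fired, and the engine is
total: a default rule always applies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cohort import DriverEvent, PatientRecord
from .config import ELN_RULES, SCMC_RULES

GROUPS = ("LR", "IR", "HR")


@dataclass(frozen=True)
class RiskAssignment:
    sample_id: str
    eln_group: Optional[str] = None
    scmc_group: Optional[str] = None
    eln_rule: str = ""
    scmc_rule: str = ""


def _feature_set(patient: PatientRecord, events: Iterable[DriverEvent]) -> set:
    """Patient's lesion vocabulary: event features, karyotype flags, and
    the derived composite lesions the rule tables name."""
    feats = {e.feature for e in events if e.sample_id == patient.sample_id}
    feats |= {f"kary:{flag}" for flag in patient.karyotype_flags}
    if "FLT3-ITD" in feats:
        feats.add("FLT3-ITD-without-NPM1" if "NPM1" not in feats
                  else "FLT3-ITD-with-NPM1")
    if "NPM1" in feats and "FLT3-ITD" not in feats:
        feats.add("NPM1-without-FLT3-ITD")
    if "RUNX1" in feats:
        # a RUNX1 sequence mutation, distinct from the RUNX1-RUNX1T1 fusion
        feats.add("RUNX1-mut")
    return feats


def classify_eln(patient: PatientRecord, events: Iterable[DriverEvent],
                 rules: dict = ELN_RULES) -> tuple[str, str]:
    """ELN-style genetic classification -> (group, rule id).

    Adverse lesions dominate, then favorable lesions; everything else is
    intermediate (the total default).
    """
    feats = _feature_set(patient, events)
    for lesion in rules["adverse"]:
        if lesion in feats:
            return "HR", f"adverse:{lesion}"
    for lesion in rules["favorable"]:
        if lesion in feats:
            return "LR", f"favorable:{lesion}"
    return "IR", "default"


def classify_scmc(patient: PatientRecord, events: Iterable[DriverEvent],
                  rules: dict = SCMC_RULES) -> tuple[str, str]:
    """SCMC-pAML classification -> (group, rule id).

    Precedence: (1) high-risk lesions; (2) RUNX1-RUNX1T1 subdivision by
    CR1 and CSF3R + KIT-E17 co-mutation; (3) KMT2A-r -> IR; (4) favorable
    mutations -> LR; (5) default by CR1 (CR1 -> IR, no CR1 -> HR).
    Unknown CR1 follows the configured policy (default: treated as the
    CR1-achieved path, with the rule id flagged "unknown-cr1").
    """
    feats = _feature_set(patient, events)
    cr1 = patient.cr1
    cr1_known = cr1 is not None
    if not cr1_known and rules.get("unknown_cr1_policy", "ir_path") == "ir_path":
        cr1 = True
    suffix = "" if cr1_known else ";unknown-cr1"

    for lesion in rules["high_risk"]:
        if lesion in feats:
            return "HR", f"high_risk:{lesion}"
    if "RUNX1-RUNX1T1" in feats:
        if not cr1:
            return "HR", "runx1_runx1t1:no_cr1" + suffix
        comut = rules["runx1_runx1t1_comut"]
        if all(m in feats for m in comut):
            return "HR", "runx1_runx1t1:cr1+" + "+".join(comut) + suffix
        return "LR", "runx1_runx1t1:cr1" + suffix
    for lesion in rules["intermediate"]:
        if lesion in feats:
            return "IR", f"intermediate:{lesion}"
    for lesion in rules["favorable"]:
        if lesion in feats:
            return "LR", f"favorable:{lesion}"
    if cr1:
        return "IR", "default:cr1" + suffix
    return "HR", "default:no_cr1" + suffix


def stratify_cohort(patients: Sequence[PatientRecord],
                    events: Sequence[DriverEvent],
                    eln_rules: dict = ELN_RULES,
                    scmc_rules: dict = SCMC_RULES) -> list[RiskAssignment]:
    """Assign every patient under both models (total and deterministic)."""
    by_sample: dict[str, list] = {}
    for e in events:
        by_sample.setdefault(e.sample_id, []).append(e)
    out = []
    for p in patients:
        ev = by_sample.get(p.sample_id, [])
        eg, er = classify_eln(p, ev, eln_rules)
        sg, sr = classify_scmc(p, ev, scmc_rules)
        out.append(RiskAssignment(p.sample_id, eg, sg, er, sr))
    return out


def restratification_flows(eln_assignments: dict, scmc_assignments: dict
                           ) -> pd.DataFrame:
    """3x3 flow counts from ELN groups (rows) to SCMC groups (columns).

    Both mappings are sample_id -> group over the same sample set; the
    marginals equal each model's group sizes by construction.
    """
    if set(eln_assignments) != set(scmc_assignments):
        only = set(eln_assignments) ^ set(scmc_assignments)
        raise ValueError(f"sample(s) present under one model only: {sorted(only)[:5]}")
    flows = pd.DataFrame(0, index=list(GROUPS), columns=list(GROUPS), dtype=int)
    for sid, eg in eln_assignments.items():
        flows.loc[eg, scmc_assignments[sid]] += 1
    return flows


def group_sizes(assignments: Iterable[str]) -> pd.Series:
    counts = Counter(assignments)
    return pd.Series([counts.get(g, 0) for g in GROUPS], index=list(GROUPS))
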