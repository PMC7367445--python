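"""Screening flow, follow-up reclassification and AF-prevalence accounting.

Encodes the deterministic decision rules of a pharmacist-led screening
programme: the triage a participant receives after the cardiologist's
overread (normal letter, 12-lead ECG referral, GP review, or no action for
known anticoagulated AF), the final classification once follow-up resolves,
CHA2DS2-VASc and HAS-BLED risk scores, ESC-style anticoagulation
eligibility, and the cohort-level summary of known/new AF prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .accuracy import Estimate, exact_binomial_ci
from .calls import (
    AF,
    FU_AF_CONFIRMED,
    FU_DECLINED,
    FU_KNOWN_DX,
    FU_NO_RESPONSE,
    FU_SR,
    SR,
    UNCLASSIFIED,
    UNREADABLE,
    parse_followup,
)
from .cohort import stage_rng

__all__ = [
    "RiskProfile",
    "TriageAction",
    "FinalClassification",
    "ScreeningSummary",
    "cha2ds2vasc",
    "hasbled",
    "oac_eligible",
    "triage",
    "classify_final",
    "classify_cohort",
    "summarize",
    "simulate_followup",
]


TRIAGE_ACTIONS = ("no_action", "issue_normal_letter", "refer_12lecg", "gp_review", "cardiologist_review")
FINAL_STATUSES = (
    "known_af",
    "new_af",
    "af_not_confirmed",
    "new_non_af_diagnosis",
    "known_non_af_diagnosis",
    "normal",
    "declined",
    "no_response",
)


class CardiologistReadPending(ValueError):
    """Triage was requested before the cardiologist's read arrived."""


@dataclass(frozen=True)
class RiskProfile:
    """Inputs to the stroke-risk (CHA2DS2-VASc) and bleeding-risk (HAS-BLED) scores."""

    age: float
    sex: str
    congestive_heart_failure: bool = False
    hypertension: bool = False
    diabetes: bool = False
    prior_stroke_or_tia: bool = False
    vascular_disease: bool = False
    renal_disease: bool = False
    liver_disease: bool = False
    bleeding_history: bool = False
    labile_inr: bool = False
    alcohol_excess: bool = False
    bleeding_drugs: bool = False

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male or female, got {self.sex!r}")


def cha2ds2vasc(profile: RiskProfile) -> int:
    """CHA2DS2-VASc stroke-risk score, 0-9.

    Congestive heart failure 1, Hypertension 1, Age >= 75 2, Diabetes 1,
    prior Stroke/TIA 2, Vascular disease 1, Age 65-74 1, female Sex 1.
    """
    score = 0
    score += profile.congestive_heart_failure
    score += profile.hypertension
    if profile.age >= 75:
        score += 2
    elif profile.age >= 65:
        score += 1
    score += profile.diabetes
    score += 2 * profile.prior_stroke_or_tia
    score += profile.vascular_disease
    score += profile.sex == "female"
    return int(score)


def hasbled(profile: RiskProfile) -> int:
    """HAS-BLED bleeding-risk score: one point per present component.

    Hypertension, abnormal renal function, abnormal liver function, prior
    stroke, bleeding history, labile INR, elderly (age > 65), drugs
    predisposing to bleeding, alcohol excess.
    """
    components = (
        profile.hypertension,
        profile.renal_disease,
        profile.liver_disease,
        profile.prior_stroke_or_tia,
        profile.bleeding_history,
        profile.labile_inr,
        profile.age > 65,
        profile.bleeding_drugs,
        profile.alcohol_excess,
    )
    return int(sum(components))


def oac_eligible(score: int, sex: str, *, male_threshold: int = 2, female_threshold: int = 3) -> bool:
    """ESC sex-adjusted anticoagulation rule: score >= 2 (men) / >= 3 (women).

    The female threshold is one point higher because female sex itself
    contributes one point to CHA2DS2-VASc.
    """
    if score < 0:
        raise ValueError("score must be non-negative")
    return score >= (male_threshold if sex == "male" else female_threshold)


def profile_from_row(row: Mapping) -> RiskProfile:
    """Map a cohort row's comorbidity flags onto a :class:`RiskProfile`."""
    return RiskProfile(
        age=float(row["age"]),
        sex=row["sex"],
        congestive_heart_failure=bool(row["heart_failure"]),
        hypertension=bool(row["hypertension"]),
        diabetes=bool(row["diabetes"]),
        prior_stroke_or_tia=bool(row["tia"]),
        vascular_disease=bool(row["ihd"]) or bool(row["pvd"]),
        renal_disease=bool(row["renal_disease"]),
        bleeding_history=bool(row["intracranial_bleed"]),
    )


@dataclass(frozen=True)
class TriageAction:
    action: str
    reason: str = ""

    def __post_init__(self) -> None:
        if self.action not in TRIAGE_ACTIONS:
            raise ValueError(f"unknown triage action {self.action!r}")


def triage(row: Mapping, *, hr_low: int = 40, hr_high: int = 120) -> TriageAction:
    """Deterministic next step after the cardiologist's overread.

    * possible AF with a known, anticoagulated AF history: no action;
    * possible AF with a known history but no anticoagulation: GP review;
    * possible AF otherwise: 12-lead ECG referral;
    * normal SR with an out-of-range heart rate: 12-lead ECG / rate check;
    * normal SR otherwise: normal-result letter;
    * unclassified or unreadable trace: 12-lead ECG referral.
    """
    read = row.get("call_cardiologist") if hasattr(row, "get") else row["call_cardiologist"]
    if read is None or (isinstance(read, float) and np.isnan(read)) or read == "":
        raise CardiologistReadPending("cardiologist read not yet available")
    known = bool(row["known_af"])
    anticoagulated = bool(row["on_oac"])
    if read == AF:
        if known and anticoagulated:
            return TriageAction("no_action", "known AF already anticoagulated")
        if known:
            return TriageAction("gp_review", "known AF not anticoagulated")
        return TriageAction("refer_12lecg", "possible AF without known history")
    if read == SR:
        hr = int(row["hr_device"])
        if hr < hr_low or hr > hr_high:
            return TriageAction("refer_12lecg", f"normal rhythm with heart rate {hr}")
        return TriageAction("issue_normal_letter", "normal sinus rhythm")
    if read in (UNCLASSIFIED, UNREADABLE):
        return TriageAction("refer_12lecg", f"{read.lower()} trace, cardiologist recommends review")
    raise ValueError(f"unknown cardiologist call {read!r}")


@dataclass(frozen=True)
class FinalClassification:
    status: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in FINAL_STATUSES:
            raise ValueError(f"unknown final status {self.status!r}")
        if self.status == "new_non_af_diagnosis" and not self.label:
            raise ValueError("new_non_af_diagnosis requires a diagnosis label")


def classify_final(row: Mapping, followup: str | None = None) -> FinalClassification:
    """Resolve a participant to exactly one terminal classification.

    ``new_af`` requires a confirming 12-lead ECG outcome; a referred
    participant with a missing follow-up is treated as a non-response.
    """
    action = triage(row).action
    read = row["call_cardiologist"]
    known = bool(row["known_af"])
    if followup is None:
        followup = row.get("followup_12lecg", "") if hasattr(row, "get") else row["followup_12lecg"]
    if isinstance(followup, float) and np.isnan(followup):
        followup = ""

    if action in ("no_action", "gp_review") and read == AF and known:
        return FinalClassification("known_af")
    if action == "issue_normal_letter":
        return FinalClassification("normal")
    # referred branch
    if followup == "":
        return FinalClassification("no_response")
    kind, label = parse_followup(str(followup))
    if kind == FU_AF_CONFIRMED:
        return FinalClassification("new_af")
    if kind == FU_SR:
        if read == AF:
            return FinalClassification("af_not_confirmed")
        return FinalClassification("normal")
    if kind == FU_DECLINED:
        return FinalClassification("declined")
    if kind == FU_NO_RESPONSE:
        return FinalClassification("no_response")
    if kind == FU_KNOWN_DX:
        return FinalClassification("known_non_af_diagnosis")
    return FinalClassification("new_non_af_diagnosis", label)


def classify_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Per-participant triage action and final classification as new columns."""
    actions, reasons, statuses, labels = [], [], [], []
    for _, row in df.iterrows():
        t = triage(row)
        c = classify_final(row)
        actions.append(t.action)
        reasons.append(t.reason)
        statuses.append(c.status)
        labels.append(c.label or "")
    out = df.copy()
    out["triage_action"] = actions
    out["triage_reason"] = reasons
    out["final_status"] = statuses
    out["final_label"] = labels
    return out


@dataclass(frozen=True)
class ScreeningSummary:
    n_screened: int
    n_cardiologist_af: int
    prevalence_total: Estimate
    n_known_af: int
    prevalence_known: Estimate
    n_new_af: int
    prevalence_new: Estimate
    n_referred: int
    n_referred_possible_af: int
    n_oac_eligible: int
    n_on_oac_end: int
    n_new_non_af: int
    status_counts: Mapping[str, int]


def summarize(df: pd.DataFrame, *, level: float = 0.95) -> ScreeningSummary:
    """Cohort-level prevalence accounting with exact binomial intervals.

    Known AF counts participants with a documented history who were in AF
    at the screen (cardiologist read AF); new AF counts 12-lead-confirmed
    diagnoses.  OAC eligibility is assessed among cardiologist-AF
    participants with the sex-adjusted ESC rule.
    """
    if len(df) == 0:
        raise ValueError("cannot summarise an empty cohort")
    classified = df if "final_status" in df.columns else classify_cohort(df)
    n = len(classified)
    card_af = classified["call_cardiologist"] == AF
    known = card_af & (classified["known_af"] == 1)
    new = classified["final_status"] == "new_af"
    n_card_af = int(card_af.sum())
    n_known = int(known.sum())
    n_new = int(new.sum())

    eligible = 0
    on_oac_end = 0
    for _, row in classified[card_af].iterrows():
        score = cha2ds2vasc(profile_from_row(row))
        eligible += oac_eligible(score, row["sex"])
        initiated = bool(row.get("oac_initiated", 0)) if "oac_initiated" in classified.columns else False
        on_oac_end += bool(row["on_oac"]) or initiated

    def prev(count: int) -> Estimate:
        return Estimate(count / n, exact_binomial_ci(count, n, level))

    counts = classified["final_status"].value_counts().to_dict()
    return ScreeningSummary(
        n_screened=n,
        n_cardiologist_af=n_card_af,
        prevalence_total=prev(n_card_af),
        n_known_af=n_known,
        prevalence_known=prev(n_known),
        n_new_af=n_new,
        prevalence_new=prev(n_new),
        n_referred=int((classified["triage_action"] == "refer_12lecg").sum()),
        n_referred_possible_af=int((card_af & (classified["triage_action"] == "refer_12lecg")).sum()),
        n_oac_eligible=int(eligible),
        n_on_oac_end=int(on_oac_end),
        n_new_non_af=int((classified["final_status"] == "new_non_af_diagnosis").sum()),
        status_counts={k: int(v) for k, v in counts.items()},
    )


@dataclass(frozen=True)
class FollowupModel:
    """Sampling model for 12-lead ECG follow-up of referred participants.

    ``p_af_confirm`` is the probability that a truly-AF participant is still
    in AF at the (median ~16 days later) 12-lead ECG - paroxysmal episodes
    are often missed.  Non-AF referrals resolve to normal SR, a
    previously-diagnosed condition, or a new non-AF diagnosis.
    """

    p_declined: float = 0.012
    p_no_response: float = 0.046
    p_af_confirm: float = 0.5
    p_other_new_dx: float = 0.39
    p_other_known_dx: float = 0.30
    p_oac_initiation: float = 0.75
    new_dx_labels: tuple[str, ...] = ("AVB", "LVH", "BBB", "AEB", "VEB", "SINUS_BRADYCARDIA")

    def __post_init__(self) -> None:
        for name in ("p_declined", "p_no_response", "p_af_confirm", "p_other_new_dx",
                     "p_other_known_dx", "p_oac_initiation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_other_new_dx + self.p_other_known_dx > 1.0:
            raise ValueError("non-AF outcome probabilities exceed 1")


def simulate_followup(df: pd.DataFrame, model: FollowupModel | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw follow-up outcomes for every participant triage refers.

    Deterministic per seed; non-referred participants keep an empty
    follow-up field, preserving the invariant that follow-up is present
    only when triage demanded it.
    """
    model = model or FollowupModel()
    rng = stage_rng(seed, "followup")
    df = df.copy()
    followup = np.full(len(df), "", dtype=object)
    initiated = np.zeros(len(df), dtype=np.int64)
    for i, (_, row) in enumerate(df.iterrows()):
        if triage(row).action != "refer_12lecg":
            continue
        u = rng.random()
        if u < model.p_declined:
            followup[i] = FU_DECLINED
            continue
        if u < model.p_declined + model.p_no_response:
            followup[i] = FU_NO_RESPONSE
            continue
        if row["true_rhythm"] == "AF":
            if rng.random() < model.p_af_confirm:
                followup[i] = FU_AF_CONFIRMED
                initiated[i] = int(rng.random() < model.p_oac_initiation)
            else:
                followup[i] = FU_SR
        elif row["true_rhythm"] == "OTHER":
            v = rng.random()
            if v < model.p_other_new_dx:
                followup[i] = "NEW_DX:" + model.new_dx_labels[
                    int(rng.integers(len(model.new_dx_labels)))
                ]
            elif v < model.p_other_new_dx + model.p_other_known_dx:
                followup[i] = FU_KNOWN_DX
            else:
                followup[i] = FU_SR
        else:
            followup[i] = FU_SR
    df["followup_12lecg"] = followup
    df["oac_initiated"] = initiated
    return df


def summary_to_dict(s: ScreeningSummary) -> dict:
    def est(e: Estimate) -> dict:
        return {"value": e.value, "ci": list(e.ci)}

    return {
        "n_screened": s.n_screened,
        "n_cardiologist_af": s.n_cardiologist_af,
        "prevalence_total": est(s.prevalence_total),
        "n_known_af": s.n_known_af,
        "prevalence_known": est(s.prevalence_known),
        "n_new_af": s.n_new_af,
        "prevalence_new": est(s.prevalence_new),
        "n_referred": s.n_referred,
        "n_referred_possible_af": s.n_referred_possible_af,
        "n_oac_eligible": s.n_oac_eligible,
        "n_on_oac_end": s.n_on_oac_end,
        "n_new_non_af": s.n_new_non_af,
        "status_counts": dict(s.status_counts),
    }
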