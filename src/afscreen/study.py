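"""Deterministic reference screening cohort.

Reconstructs, row by row, a 604-participant pharmacist-led AF screening
dataset from its published summary counts, so that every downstream stage
can be exercised against the published figures without access to the
original case-report spreadsheets.  The construction fixes:

* cardiologist reads: 503 normal SR, 26 possible AF, 69 unclassified,
  6 unreadable;
* device algorithm: 484 / 39 / 75 / 6 with 24 of the 26 reference-AF
  participants called AF and 15 false positives;
* pharmacist read: 487 / 39 / 71 / 7 with 23 true positives and 16 false
  positives;
* pulse palpation: 526 / 65 / 12 / 1 (one impalpable pulse) with 20 true
  positives and 45 false positives;
* AF history: 18 of the 26 reference-AF participants known and
  anticoagulated; the other 8 referred for a 12-lead ECG, of whom 3
  confirmed in AF; one further unclassified participant confirmed in AF at
  follow-up (4 new AF in total, 3 started on anticoagulation);
* follow-up: 87 referrals resolving to 4 AF confirmations, 28 normal SR,
  22 previously-diagnosed conditions, 28 new non-AF diagnoses (8 of them
  first-degree AV block), 1 decline and 4 non-responses.

Cross-classifications the summary counts do not pin down (which exact rows
carry which pulse errors, ages of individual participants, and so on) are
filled deterministically; demographic noise uses a fixed internal seed.
The result is byte-identical across runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calls import (
    AF,
    FU_AF_CONFIRMED,
    FU_DECLINED,
    FU_KNOWN_DX,
    FU_NEW_DX_PREFIX,
    FU_NO_RESPONSE,
    FU_SR,
    RHYTHM_AF,
    RHYTHM_OTHER,
    RHYTHM_SR,
    SR,
    UNCLASSIFIED,
    UNREADABLE,
)
from .cohort import COMORBIDITIES, _PREV_AF, _PREV_NON_AF

__all__ = ["reference_study_cohort"]

_N = 604
# index blocks of the construction
_KNOWN_AF = range(0, 18)
_NEW_AF = range(18, 26)
_CARD_AF = range(0, 26)
_CARD_SR = range(26, 529)
_CARD_UNCL = range(529, 598)
_CARD_UNREAD = range(598, 604)


def _fill(col: np.ndarray, idx, value) -> None:
    col[list(idx)] = value


def reference_study_cohort() -> pd.DataFrame:
    """Build the deterministic 604-row reference cohort."""
    rng = np.random.default_rng(20170128)  # internal noise seed; construction is fixed

    card = np.full(_N, SR, dtype=object)
    _fill(card, _CARD_AF, AF)
    _fill(card, _CARD_UNCL, UNCLASSIFIED)
    _fill(card, _CARD_UNREAD, UNREADABLE)

    rhythm = np.full(_N, RHYTHM_SR, dtype=object)
    _fill(rhythm, _CARD_AF, RHYTHM_AF)
    _fill(rhythm, _CARD_UNCL, RHYTHM_OTHER)

    # device: 24 TP, 2 FN (SR call), 15 FP (6 on SR reads, 9 on unclassified),
    # 75 unclassified, unreadable on the 6 jointly-unreadable traces
    device = np.full(_N, SR, dtype=object)
    _fill(device, range(0, 24), AF)
    _fill(device, range(26, 32), AF)
    _fill(device, range(529, 538), AF)
    _fill(device, range(538, 598), UNCLASSIFIED)
    _fill(device, range(32, 47), UNCLASSIFIED)
    _fill(device, _CARD_UNREAD, UNREADABLE)

    # pharmacist: 23 TP, 3 FN, 16 FP (7 SR + 9 unclassified), 71 unclassified,
    # 7 unreadable (the 6 joint ones plus one extra normal trace)
    pharm = np.full(_N, SR, dtype=object)
    _fill(pharm, range(0, 23), AF)
    _fill(pharm, range(48, 55), AF)
    _fill(pharm, range(529, 538), AF)
    _fill(pharm, range(538, 598), UNCLASSIFIED)
    _fill(pharm, range(55, 66), UNCLASSIFIED)
    _fill(pharm, _CARD_UNREAD, UNREADABLE)
    pharm[47] = UNREADABLE

    # pulse: 20 TP, 6 FN, 45 FP (26 on other-abnormality rhythms -- ectopics,
    # tachy/bradycardia -- plus 19 on normal traces), 12 unclassified, 1 impalpable
    pulse = np.full(_N, SR, dtype=object)
    _fill(pulse, range(0, 20), AF)
    _fill(pulse, range(529, 555), AF)
    _fill(pulse, range(66, 85), AF)
    _fill(pulse, range(86, 98), UNCLASSIFIED)
    pulse[85] = UNREADABLE

    known_af = np.zeros(_N, dtype=np.int64)
    _fill(known_af, _KNOWN_AF, 1)
    # paroxysmal-AF history in participants in sinus rhythm on the day (~7%
    # of the normal stratum carried a known AF/PAF history)
    latent = rng.choice(np.arange(110, 529), size=35, replace=False)
    known_af[latent] = 1
    on_oac = known_af.copy()

    # follow-up outcomes for the 87 referred participants
    followup = np.full(_N, "", dtype=object)
    _fill(followup, (18, 19, 20), FU_AF_CONFIRMED)  # possible AF confirmed
    _fill(followup, range(21, 26), FU_SR)  # possible AF, in SR at 12LECG
    followup[556] = FU_AF_CONFIRMED  # unclassified trace, AF at 12LECG
    followup[560] = FU_DECLINED
    _fill(followup, range(561, 565), FU_NO_RESPONSE)
    _fill(followup, range(565, 588), FU_SR)
    _fill(followup, range(529, 551), FU_KNOWN_DX)
    for idx, label in (
        (range(588, 596), "AVB"),  # 8 new first-degree AV blocks
        (range(551, 556), "LVH"),
        ((557, 558, 559, 596, 597), "BBB"),
        (range(598, 602), "AEB"),
        ((602, 603), "VEB"),
        (range(98, 102), "SINUS_BRADYCARDIA"),  # low-rate referrals from normal reads
    ):
        _fill(followup, idx, FU_NEW_DX_PREFIX + label)

    oac_initiated = np.zeros(_N, dtype=np.int64)
    _fill(oac_initiated, (18, 19, 556), 1)  # 3 of the 4 new AF started on OAC

    # demographics: AF participants older (median ~82), 15/26 male
    age = np.zeros(_N, dtype=np.int64)
    af_ages = [76, 78, 80, 82, 84, 86, 75, 77, 79, 81, 83, 85, 88, 90, 75, 76, 82, 84,
               68, 70, 72, 80, 82, 73, 84, 79]
    age[:26] = af_ages
    rest = np.arange(26, _N)
    g = rng.gamma(shape=1.8661, scale=5.3761, size=rest.size)
    age[rest] = np.clip(65 + np.floor(g), 65, 99).astype(np.int64)

    sex = np.full(_N, "female", dtype=object)
    _fill(sex, list(range(0, 10)) + list(range(18, 23)), "male")  # 15 male with AF
    males_rest = rng.choice(rest, size=258 - 15, replace=False)  # 258 male overall (42.7%)
    sex[males_rest] = "male"

    height = np.clip(rng.normal(167.0, 10.4, _N) + np.where(sex == "male", 4.5, -3.5), 140, 205).round(1)
    bmi_draw = np.exp(rng.normal(3.2655, 0.1641, _N) + np.where(np.arange(_N) < 26, 0.08, 0.0))
    weight = (bmi_draw * (height / 100.0) ** 2).round(1)
    bmi = (weight / (height / 100.0) ** 2).round(1)

    hr = np.clip(rng.normal(73.0, 9.0, _N), 55, 95).round().astype(np.int64)
    hr[:26] += 15  # AF runs fast
    _fill(hr, range(98, 102), 38)  # bradycardic normal reads -> heart-rate referral

    df = pd.DataFrame(
        {
            "id": [f"S{i:05d}" for i in range(_N)],
            "age": age,
            "sex": sex,
            "height_cm": height,
            "weight_kg": weight,
            "bmi": bmi,
            "alcohol": (rng.random(_N) < 0.629).astype(np.int64),
            "smoker": (rng.random(_N) < 0.089).astype(np.int64),
        }
    )
    is_af = np.arange(_N) < 26
    for c in COMORBIDITIES:
        p = np.where(is_af, _PREV_AF[c], _PREV_NON_AF[c])
        df[c] = (rng.random(_N) < p).astype(np.int64)
    df["hypertension"] = np.where(is_af, 1, df["hypertension"])  # every AF row OAC-eligible
    df["known_af"] = known_af
    df["on_oac"] = on_oac
    df["true_rhythm"] = rhythm
    df["call_pulse"] = pulse
    df["call_device"] = device
    df["call_pharmacist"] = pharm
    df["call_cardiologist"] = card
    df["hr_pulse"] = np.maximum(hr - 2, 35)
    df["hr_device"] = hr
    df["followup_12lecg"] = followup
    df["oac_initiated"] = oac_initiated
    return df
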