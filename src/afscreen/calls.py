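"""Closed vocabularies shared across the screening pipeline.

Every rater (radial pulse palpation, the single-lead ECG device algorithm,
the pharmacist's read of the trace, and the overreading cardiologist) emits
one of four categorical calls.  True rhythm is a latent three-way state:
sinus rhythm, atrial fibrillation, or some other abnormality (e.g. ectopic
beats, conduction block) that is real but not AF.
"""

from __future__ import annotations

# Rater call categories (serialised verbatim in cohort CSV files).
SR = "SR"
AF = "AF"
UNCLASSIFIED = "UNCLASSIFIED"
UNREADABLE = "UNREADABLE"
CALL_CATEGORIES = frozenset({SR, AF, UNCLASSIFIED, UNREADABLE})

# Latent true rhythm classes.
RHYTHM_SR = "SR"
RHYTHM_AF = "AF"
RHYTHM_OTHER = "OTHER"
RHYTHM_CLASSES = frozenset({RHYTHM_SR, RHYTHM_AF, RHYTHM_OTHER})

SEXES = frozenset({"male", "female"})

RATERS = ("pulse", "device", "pharmacist", "cardiologist")

# 12-lead ECG follow-up outcomes.  A new non-AF diagnosis carries a label
# from the closed list below, serialised as ``NEW_DX:<label>``.
FU_AF_CONFIRMED = "AF_CONFIRMED"
FU_SR = "SR"
FU_DECLINED = "DECLINED"
FU_NO_RESPONSE = "NO_RESPONSE"
FU_KNOWN_DX = "KNOWN_DX"
FU_NEW_DX_PREFIX = "NEW_DX:"

NON_AF_DIAGNOSES = frozenset(
    {"LVH", "BBB", "AVB", "AEB", "VEB", "SINUS_BRADYCARDIA", "SINUS_TACHYCARDIA", "OTHER"}
)


def parse_followup(value: str) -> tuple[str, str | None]:
    """Split a follow-up code into ``(kind, label)``; raise on unknown codes."""
    if value in (FU_AF_CONFIRMED, FU_SR, FU_DECLINED, FU_NO_RESPONSE, FU_KNOWN_DX):
        return value, None
    if value.startswith(FU_NEW_DX_PREFIX):
        label = value[len(FU_NEW_DX_PREFIX):]
        if label not in NON_AF_DIAGNOSES:
            raise ValueError(f"unknown non-AF diagnosis label {label!r}")
        return "NEW_DX", label
    raise ValueError(f"unknown follow-up outcome {value!r}")
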