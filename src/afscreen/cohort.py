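"""Synthetic screening cohorts.

Generates tabular cohorts of over-65s attending an influenza-vaccination
clinic, with the demographic structure of a UK pharmacist-led AF screening
programme (n = 604, median age 73, IQR 69-78, 42.7% male, 4.3% AF by the
cardiologist's read), and simulates the four raters' categorical calls from
configurable per-rhythm misclassification distributions.

A cohort is a :class:`pandas.DataFrame` with the columns in
:data:`COHORT_COLUMNS`; one row per participant.  All randomness flows from
a single integer seed that fans out to per-stage child seeds by fixed
offsets, so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .calls import (
    AF,
    CALL_CATEGORIES,
    RATERS,
    RHYTHM_AF,
    RHYTHM_CLASSES,
    RHYTHM_OTHER,
    RHYTHM_SR,
    SR,
    UNCLASSIFIED,
    UNREADABLE,
)

__all__ = [
    "COMORBIDITIES",
    "COHORT_COLUMNS",
    "CohortConfig",
    "RaterErrorModel",
    "generate_cohort",
    "assign_true_rhythm",
    "simulate_calls",
    "write_cohort",
    "read_cohort",
    "import_s2_spreadsheet",
]


class ConfigurationError(ValueError):
    """Invalid cohort or rater configuration."""


class CohortParseError(ValueError):
    """A cohort file failed validation; message names the row and column."""


COMORBIDITIES = (
    "hypertension",
    "renal_disease",
    "diabetes",
    "thyroid_disease",
    "tia",
    "ihd",
    "heart_failure",
    "intracranial_bleed",
    "pvd",
    "copd",
)

COHORT_COLUMNS = (
    ("id", "str"),
    ("age", "int"),
    ("sex", "sex"),
    ("height_cm", "float"),
    ("weight_kg", "float"),
    ("bmi", "float"),
    ("alcohol", "flag"),
    ("smoker", "flag"),
    *((c, "flag") for c in COMORBIDITIES),
    ("known_af", "flag"),
    ("on_oac", "flag"),
    ("true_rhythm", "rhythm"),
    ("call_pulse", "call"),
    ("call_device", "call"),
    ("call_pharmacist", "call"),
    ("call_cardiologist", "call"),
    ("hr_pulse", "int"),
    ("hr_device", "int"),
    ("followup_12lecg", "followup"),
)

# Fixed per-stage offsets for fanning one global seed out to child streams.
_STAGE_OFFSETS = {"cohort": 11, "rhythm": 23, "calls": 37, "followup": 53, "psa": 71}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a pipeline stage, derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGE_OFFSETS[stage],)))


# Comorbidity prevalences by AF stratum.  AF participants carry elevated
# rates (hypertension, renal disease, diabetes and heart failure in
# particular); within a stratum comorbidities are sampled independently, as
# only marginal prevalences are identifiable from summary data.
_PREV_NON_AF = {
    "hypertension": 0.409,
    "renal_disease": 0.172,
    "diabetes": 0.129,
    "thyroid_disease": 0.086,
    "tia": 0.032,
    "ihd": 0.075,
    "heart_failure": 0.0,
    "intracranial_bleed": 0.011,
    "pvd": 0.043,
    "copd": 0.086,
}
_PREV_AF = {
    "hypertension": 0.692,
    "renal_disease": 0.423,
    "diabetes": 0.308,
    "thyroid_disease": 0.154,
    "tia": 0.115,
    "ihd": 0.115,
    "heart_failure": 0.077,
    "intracranial_bleed": 0.038,
    "pvd": 0.0,
    "copd": 0.08,
}


def _check_proportion(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level sampling parameters.

    Ages are drawn as ``age_min + Gamma(age_shape, age_scale)`` truncated at
    ``age_max``; the default shape/scale put the quartiles at roughly
    (69, 73, 78) years.  BMI is log-normal; height is normal and weight is
    derived from BMI and height.  ``known_af_fraction`` is the fraction with
    a documented AF history who are in AF at the screen;
    ``true_af_screenable_fraction`` is undiagnosed AF detectable by a
    single-time-point ECG; ``latent_af_in_sr_fraction`` is the fraction of
    sinus-rhythm participants with a paroxysmal-AF history (in SR on the
    day, so invisible to the screen).
    """

    n_participants: int = 604
    age_shape: float = 1.8661
    age_scale: float = 5.3761
    age_min: float = 65.0
    age_max: float = 100.0
    male_fraction: float = 0.427
    alcohol_fraction: float = 0.629
    smoker_fraction: float = 0.089
    bmi_log_mean: float = 3.2655
    bmi_log_sd: float = 0.1641
    height_mean_cm: float = 167.0
    height_sd_cm: float = 10.4
    comorbidity_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(_PREV_NON_AF)
    )
    comorbidity_prevalences_af: Mapping[str, float] = field(
        default_factory=lambda: dict(_PREV_AF)
    )
    known_af_fraction: float = 0.030
    true_af_screenable_fraction: float = 0.013
    other_abnormality_fraction: float = 0.114
    latent_af_in_sr_fraction: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError(f"n_participants must be positive, got {self.n_participants}")
        if self.age_min < 65:
            raise ConfigurationError("age_min must be >= 65 for an over-65s screening cohort")
        if self.age_max <= self.age_min:
            raise ConfigurationError("age_max must exceed age_min")
        for name in (
            "male_fraction",
            "alcohol_fraction",
            "smoker_fraction",
            "known_af_fraction",
            "true_af_screenable_fraction",
            "other_abnormality_fraction",
            "latent_af_in_sr_fraction",
        ):
            _check_proportion(name, getattr(self, name))
        for label, prevs in (
            ("comorbidity_prevalences", self.comorbidity_prevalences),
            ("comorbidity_prevalences_af", self.comorbidity_prevalences_af),
        ):
            for c in COMORBIDITIES:
                if c not in prevs:
                    raise ConfigurationError(f"{label} missing prevalence for {c!r}")
                _check_proportion(f"{label}[{c}]", prevs[c])
        total_af = self.known_af_fraction + self.true_af_screenable_fraction
        if total_af + self.other_abnormality_fraction > 1.0:
            raise ConfigurationError("rhythm-class fractions exceed 1")


def _validate_conditional(rater: str, table: Mapping[str, Mapping[str, float]]) -> None:
    for rhythm in RHYTHM_CLASSES:
        if rhythm not in table:
            raise ConfigurationError(f"{rater}: missing conditional row for rhythm {rhythm!r}")
        row = table[rhythm]
        unknown = set(row) - CALL_CATEGORIES
        if unknown:
            raise ConfigurationError(f"{rater}[{rhythm}]: unknown call categories {sorted(unknown)}")
        probs = [row.get(c, 0.0) for c in CALL_CATEGORIES]
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigurationError(f"{rater}[{rhythm}]: probabilities outside [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError(f"{rater}[{rhythm}]: probabilities sum to {sum(probs)}, not 1")


@dataclass(frozen=True)
class RaterErrorModel:
    """Per-rater conditional call distributions given the true rhythm.

    Each rater maps a true rhythm class to a probability distribution over
    the four call categories.  ``pharmacist_follows_device`` is the
    probability that the pharmacist simply copies the device's call (the
    pharmacist sees the device output during screening); 0 means
    conditionally independent calls.
    """

    pulse: Mapping[str, Mapping[str, float]]
    device: Mapping[str, Mapping[str, float]]
    pharmacist: Mapping[str, Mapping[str, float]]
    cardiologist: Mapping[str, Mapping[str, float]]
    pharmacist_follows_device: float = 0.0

    def __post_init__(self) -> None:
        for rater in RATERS:
            _validate_conditional(rater, getattr(self, rater))
        _check_proportion("pharmacist_follows_device", self.pharmacist_follows_device)

    @classmethod
    def default(cls) -> "RaterErrorModel":
        """Operating characteristics back-solved from the reference study's
        published category counts and accuracy table (device 92.3/97.4,
        pharmacist 88.5/97.2, pulse 76.9/92.2 vs the cardiologist).  These
        are derived defaults, fully overridable."""
        return cls(
            device={
                RHYTHM_AF: {AF: 0.914, SR: 0.040, UNCLASSIFIED: 0.036, UNREADABLE: 0.010},
                RHYTHM_SR: {SR: 0.928, AF: 0.012, UNCLASSIFIED: 0.050, UNREADABLE: 0.010},
                RHYTHM_OTHER: {UNCLASSIFIED: 0.720, SR: 0.130, AF: 0.130, UNREADABLE: 0.020},
            },
            pharmacist={
                RHYTHM_AF: {AF: 0.875, SR: 0.050, UNCLASSIFIED: 0.065, UNREADABLE: 0.010},
                RHYTHM_SR: {SR: 0.925, AF: 0.013, UNCLASSIFIED: 0.050, UNREADABLE: 0.012},
                RHYTHM_OTHER: {UNCLASSIFIED: 0.710, SR: 0.130, AF: 0.130, UNREADABLE: 0.030},
            },
            pulse={
                RHYTHM_AF: {AF: 0.768, SR: 0.197, UNCLASSIFIED: 0.033, UNREADABLE: 0.002},
                RHYTHM_SR: {SR: 0.945, AF: 0.040, UNCLASSIFIED: 0.013, UNREADABLE: 0.002},
                RHYTHM_OTHER: {SR: 0.560, AF: 0.350, UNCLASSIFIED: 0.088, UNREADABLE: 0.002},
            },
            cardiologist={
                RHYTHM_AF: {AF: 0.99, SR: 0.0, UNCLASSIFIED: 0.0, UNREADABLE: 0.01},
                RHYTHM_SR: {SR: 0.99, AF: 0.0, UNCLASSIFIED: 0.0, UNREADABLE: 0.01},
                RHYTHM_OTHER: {UNCLASSIFIED: 0.99, SR: 0.0, AF: 0.0, UNREADABLE: 0.01},
            },
        )

    @classmethod
    def error_free(cls) -> "RaterErrorModel":
        """Identity raters: AF -> AF call, SR -> SR, other -> unclassified."""
        perfect = {
            RHYTHM_AF: {AF: 1.0},
            RHYTHM_SR: {SR: 1.0},
            RHYTHM_OTHER: {UNCLASSIFIED: 1.0},
        }
        full = {r: {c: row.get(c, 0.0) for c in CALL_CATEGORIES} for r, row in perfect.items()}
        return cls(pulse=full, device=full, pharmacist=full, cardiologist=full)

    def implied_operating_point(
        self,
        rater: str,
        *,
        positive: frozenset[str] = frozenset({AF}),
        excluded: frozenset[str] = frozenset({UNREADABLE}),
        af_fraction: float = 0.043,
        other_fraction: float = 0.114,
    ) -> tuple[float, float]:
        """Population sensitivity and specificity implied by the conditionals.

        Sensitivity conditions on true AF, specificity on true non-AF (a mix
        of SR and other-abnormality weighted by the supplied fractions);
        excluded calls are removed from both denominators, matching pairwise
        exclusion downstream.
        """
        table = getattr(self, rater)

        def rate(row: Mapping[str, float]) -> tuple[float, float]:
            pos = sum(row.get(c, 0.0) for c in positive)
            exc = sum(row.get(c, 0.0) for c in excluded)
            return pos, exc

        pos_af, exc_af = rate(table[RHYTHM_AF])
        sens = pos_af / (1.0 - exc_af)
        w_sr = (1.0 - af_fraction - other_fraction) / (1.0 - af_fraction)
        w_ot = other_fraction / (1.0 - af_fraction)
        pos_neg = w_sr * rate(table[RHYTHM_SR])[0] + w_ot * rate(table[RHYTHM_OTHER])[0]
        exc_neg = w_sr * rate(table[RHYTHM_SR])[1] + w_ot * rate(table[RHYTHM_OTHER])[1]
        spec = 1.0 - pos_neg / (1.0 - exc_neg)
        return sens, spec


def generate_cohort(config: CohortConfig, *, include_rhythm: bool = True) -> pd.DataFrame:
    """Generate ``config.n_participants`` demographic rows; deterministic per seed.

    When ``include_rhythm`` is true (the default) the true-rhythm stage
    (:func:`assign_true_rhythm`) runs as well, because comorbidity
    prevalences are stratified by AF status.
    """
    n = config.n_participants
    rng = stage_rng(config.seed, "cohort")

    # truncated gamma ages via inverse-CDF on the admissible quantile range
    hi = stats.gamma.cdf(config.age_max - config.age_min, config.age_shape, scale=config.age_scale)
    u = rng.uniform(0.0, hi, size=n)
    age = config.age_min + stats.gamma.ppf(u, config.age_shape, scale=config.age_scale)
    age = np.floor(age).astype(np.int64)

    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    height = rng.normal(config.height_mean_cm, config.height_sd_cm, size=n)
    # women systematically shorter; recentre by sex around the overall mean
    height = height + np.where(sex == "male", 4.5, -3.5)
    height = np.clip(height, 140.0, 205.0).round(1)
    bmi = np.exp(rng.normal(config.bmi_log_mean, config.bmi_log_sd, size=n))
    weight = (bmi * (height / 100.0) ** 2).round(1)
    bmi = (weight / (height / 100.0) ** 2).round(1)  # recompute so the stored triple is exact

    df = pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "height_cm": height,
            "weight_kg": weight,
            "bmi": bmi,
            "alcohol": (rng.random(n) < config.alcohol_fraction).astype(np.int64),
            "smoker": (rng.random(n) < config.smoker_fraction).astype(np.int64),
        }
    )
    for c in COMORBIDITIES:
        df[c] = 0
    df["known_af"] = 0
    df["on_oac"] = 0
    df["true_rhythm"] = RHYTHM_SR
    if include_rhythm:
        df = assign_true_rhythm(df, config)
    return df


def assign_true_rhythm(df: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Assign latent rhythm, AF-history flags and stratified comorbidities.

    The AF fraction splits into ``known_af_fraction`` (documented history,
    anticoagulated, in AF on the day) and ``true_af_screenable_fraction``
    (undiagnosed, detectable).  A ``latent_af_in_sr_fraction`` of the
    sinus-rhythm stratum carries a paroxysmal-AF history flag.
    """
    n = len(df)
    rng = stage_rng(config.seed, "rhythm")
    df = df.copy()

    p_known = config.known_af_fraction
    p_new = config.true_af_screenable_fraction
    p_other = config.other_abnormality_fraction
    u = rng.random(n)
    known = u < p_known
    new_af = (u >= p_known) & (u < p_known + p_new)
    other = (u >= p_known + p_new) & (u < p_known + p_new + p_other)

    rhythm = np.full(n, RHYTHM_SR, dtype=object)
    rhythm[known | new_af] = RHYTHM_AF
    rhythm[other] = RHYTHM_OTHER
    df["true_rhythm"] = rhythm

    latent = (rhythm == RHYTHM_SR) & (rng.random(n) < config.latent_af_in_sr_fraction)
    df["known_af"] = (known | latent).astype(np.int64)
    df["on_oac"] = df["known_af"]  # documented AF history is anticoagulated by default

    is_af = rhythm == RHYTHM_AF
    for c in COMORBIDITIES:
        p = np.where(is_af, config.comorbidity_prevalences_af[c], config.comorbidity_prevalences[c])
        df[c] = (rng.random(n) < p).astype(np.int64)
    return df


def simulate_calls(
    df: pd.DataFrame, error_model: RaterErrorModel | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Draw the four raters' calls conditionally on true rhythm.

    Calls are conditionally independent given rhythm, except that the
    pharmacist copies the device's call with probability
    ``pharmacist_follows_device``.  Deterministic per seed.
    """
    if error_model is None:
        error_model = RaterErrorModel.default()
    if "true_rhythm" not in df.columns:
        raise ConfigurationError("cohort lacks true_rhythm; run assign_true_rhythm first")
    rng = stage_rng(0 if seed is None else seed, "calls")
    n = len(df)
    df = df.copy()
    cats = sorted(CALL_CATEGORIES)
    rhythm = df["true_rhythm"].to_numpy()

    def draw(table: Mapping[str, Mapping[str, float]]) -> np.ndarray:
        out = np.empty(n, dtype=object)
        u = rng.random(n)
        for rh in (RHYTHM_SR, RHYTHM_AF, RHYTHM_OTHER):
            mask = rhythm == rh
            if not mask.any():
                continue
            probs = np.array([table[rh].get(c, 0.0) for c in cats])
            edges = np.cumsum(probs)
            idx = np.searchsorted(edges, u[mask], side="right").clip(0, len(cats) - 1)
            out[mask] = np.array(cats, dtype=object)[idx]
        return out

    df["call_pulse"] = draw(error_model.pulse)
    df["call_device"] = draw(error_model.device)
    pharm = draw(error_model.pharmacist)
    if error_model.pharmacist_follows_device > 0:
        copy = rng.random(n) < error_model.pharmacist_follows_device
        pharm = np.where(copy, df["call_device"].to_numpy(), pharm)
    df["call_pharmacist"] = pharm
    df["call_cardiologist"] = draw(error_model.cardiologist)

    # heart rates: AF runs faster and the palpated rate reads slightly lower
    base = rng.normal(73.0, 12.0, size=n) + np.where(rhythm == RHYTHM_AF, 12.0, 0.0)
    df["hr_pulse"] = np.clip(base + rng.normal(-2.0, 3.0, size=n), 35, 160).round().astype(np.int64)
    df["hr_device"] = np.clip(base, 35, 160).round().astype(np.int64)
    df["followup_12lecg"] = ""
    return df


# ---------------------------------------------------------------------------
# Cohort file I/O


def _validate_cohort(df: pd.DataFrame, *, source: str = "cohort") -> None:
    from .calls import parse_followup

    missing = [c for c, _ in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"{source}: missing columns {missing}")
    for col, kind in COHORT_COLUMNS:
        values = df[col]
        if kind == "call":
            bad = ~values.isin(CALL_CATEGORIES)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortParseError(
                    f"{source}: row {row}, column {col!r}: unknown call category "
                    f"{values.iloc[row]!r}"
                )
        elif kind == "rhythm":
            bad = ~values.isin(RHYTHM_CLASSES)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortParseError(
                    f"{source}: row {row}, column {col!r}: unknown rhythm {values.iloc[row]!r}"
                )
        elif kind == "sex":
            bad = ~values.isin({"male", "female"})
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortParseError(
                    f"{source}: row {row}, column {col!r}: unknown sex {values.iloc[row]!r}"
                )
        elif kind == "flag":
            bad = ~values.isin((0, 1))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortParseError(
                    f"{source}: row {row}, column {col!r}: flag must be 0/1, got "
                    f"{values.iloc[row]!r}"
                )
        elif kind == "followup":
            for row, v in enumerate(values):
                if v == "" or (isinstance(v, float) and np.isnan(v)):
                    continue
                try:
                    parse_followup(str(v))
                except ValueError as exc:
                    raise CohortParseError(f"{source}: row {row}, column {col!r}: {exc}") from exc
    for col in ("hr_pulse", "hr_device"):
        bad = df[col] <= 0
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(f"{source}: row {row}, column {col!r}: heart rate must be positive")


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV (UTF-8, header row, fixed column order)."""
    _validate_cohort(df, source=str(path))
    out = df[[c for c, _ in COHORT_COLUMNS]]
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises :class:`CohortParseError`."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = pd.DataFrame(index=raw.index)
    missing = [c for c, _ in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortParseError(f"{path}: missing columns {missing}")
    for col, kind in COHORT_COLUMNS:
        try:
            if kind in ("int",):
                df[col] = raw[col].astype(np.int64)
            elif kind == "flag":
                df[col] = raw[col].astype(np.int64)
            elif kind == "float":
                df[col] = raw[col].astype(float)
            else:
                df[col] = raw[col]
        except ValueError as exc:
            raise CohortParseError(f"{path}: column {col!r}: {exc}") from exc
    _validate_cohort(df, source=str(path))
    return df


# Column-name aliases seen in spreadsheet exports of screening case-report
# data; used by the optional XLSX importer only.
_S2_ALIASES = {
    "participant id": "id",
    "patient id": "id",
    "age (years)": "age",
    "gender": "sex",
    "height": "height_cm",
    "weight": "weight_kg",
    "pulse palpation": "call_pulse",
    "kmd interpretation": "call_device",
    "kmd algorithm": "call_device",
    "pharmacist interpretation": "call_pharmacist",
    "cardiologist interpretation": "call_cardiologist",
    "pulse hr": "hr_pulse",
    "kmd hr": "hr_device",
    "12lecg outcome": "followup_12lecg",
}

_S2_CALL_ALIASES = {
    "normal": SR,
    "normal sr": SR,
    "sr": SR,
    "possible af": AF,
    "af": AF,
    "unclassified": UNCLASSIFIED,
    "unreadable": UNREADABLE,
    "impalpable": UNREADABLE,
}


def import_s2_spreadsheet(path) -> pd.DataFrame:
    """Import a case-report spreadsheet (XLSX) into the cohort CSV schema.

    Tolerant of common column-name and call-label aliases.  Columns absent
    from the spreadsheet are filled with neutral defaults.  Requires
    ``openpyxl``.
    """
    raw = pd.read_excel(path)
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    renamed = raw.rename(columns={a: t for a, t in _S2_ALIASES.items() if a in raw.columns})
    df = pd.DataFrame(index=renamed.index)
    defaults = {
        "str": "",
        "int": 0,
        "float": float("nan"),
        "flag": 0,
        "sex": "female",
        "rhythm": RHYTHM_SR,
        "call": SR,
        "followup": "",
    }
    for col, kind in COHORT_COLUMNS:
        if col in renamed.columns:
            values = renamed[col]
            if kind == "call":
                values = values.map(
                    lambda v: _S2_CALL_ALIASES.get(str(v).strip().lower(), str(v).strip().upper())
                )
            df[col] = values
        else:
            df[col] = defaults[kind]
    if "id" in df.columns and (df["id"] == "").all():
        df["id"] = [f"P{i:05d}" for i in range(len(df))]
    return df


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["comorbidity_prevalences"] = dict(d["comorbidity_prevalences"])
    d["comorbidity_prevalences_af"] = dict(d["comorbidity_prevalences_af"])
    return d


def config_from_dict(d: Mapping) -> CohortConfig:
    return CohortConfig(**d)
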