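"""Noninvasive blood-test score equations and the score registry.

Implements the six tests compared in the analysis, each as a pure function
of a patient record:

* **NIS4** — logistic composite of log10 miR-34a-5p fold change,
  alpha2-macroglobulin (g/L), log10 YKL-40 (ng/mL) and HbA1c (%).
* **NIS2+** — optimized two-analyte variant: log10 miR-34a-5p and log10
  YKL-40 with a sex main effect and a sex x miR-34a interaction
  (sex coded 0 female / 1 male), dropping A2M and HbA1c.
* **FIB-4** — age x AST / (platelets x sqrt(ALT)).
* **NFS** — the NAFLD fibrosis score linear combination of age, BMI,
  IFG/diabetes, AST/ALT ratio, platelets and albumin.
* **ELF** — 2.494 + 0.846 ln(HA) + 0.735 ln(PIIINP) + 0.391 ln(TIMP-1).
* **ALT** — the raw ALT with a sex-specific upper limit of normal
  (33 IU/L women, 41 IU/L men) used as a single cutoff.

The clinical NIS4/NIS2+ coefficients are proprietary and not published;
the package ships a frozen synthetic-calibration coefficient set (fit once
on the default synthetic cohort, provenance-labelled) and accepts any
user-supplied :class:`LogisticCompositeCoefficients`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from ._util import as_mapping, is_missing
from .cohort import MissingFieldError

__all__ = [
    "LogisticCompositeCoefficients",
    "CutoffPolicy",
    "ScoreDefinition",
    "AnalyteDomainError",
    "UnitSanityError",
    "score_nis4",
    "score_nis2plus",
    "score_fib4",
    "score_nfs",
    "score_elf",
    "score_alt",
    "score_all",
    "default_registry",
    "load_default_coefficients",
    "ALT_ULN_FEMALE",
    "ALT_ULN_MALE",
]

ALT_ULN_FEMALE = 33.0
ALT_ULN_MALE = 41.0

#: Default fasting-glucose threshold (mmol/L) for the NFS impaired-fasting-
#: glycemia indicator. A convention (ADA IFG lower bound), not a published
#: constant of the score comparison; overridable per call.
DEFAULT_IFG_THRESHOLD = 5.6


class AnalyteDomainError(ValueError):
    """An analyte value is outside the mathematical domain of a score."""

    def __init__(self, analyte: str, value):
        self.analyte = analyte
        super().__init__(f"{analyte} must be strictly positive, got {value!r}")


class UnitSanityError(ValueError):
    """A value is implausible for the unit the equation expects."""


@dataclass(frozen=True)
class LogisticCompositeCoefficients:
    """Coefficient set beta0..beta4 for a logistic composite score.

    ``variant`` fixes which covariates the betas multiply:
    ``nis4`` -> (log10 mir34a, a2m, log10 ykl40, hba1c);
    ``nis2plus`` -> (log10 mir34a, log10 ykl40, sex, log10 mir34a x sex).
    ``provenance`` is a mandatory free-text label tracing where the numbers
    came from (e.g. ``"synthetic-calibration-v1"``).
    """

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    beta4: float
    variant: str
    provenance: str

    def __post_init__(self):
        if self.variant not in ("nis4", "nis2plus"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not self.provenance:
            raise ValueError("provenance must be non-empty")

    @property
    def betas(self) -> tuple[float, ...]:
        return (self.beta0, self.beta1, self.beta2, self.beta3, self.beta4)


@dataclass(frozen=True)
class CutoffPolicy:
    """Cutoff policy for a test: dual (low/high), single, or sex-specific.

    Exactly one mode is active. With a dual policy, scores below ``low``
    rule the endpoint out, scores at or above ``high`` rule it in, and the
    range in between is the intermediate (moderate-risk) zone. Single-cutoff
    tests have no intermediate zone. Positivity convention is
    score >= cutoff throughout.
    """

    low: float | None = None
    high: float | None = None
    single: float | None = None
    sex_specific_single: tuple[float, float] | None = None  # (female, male)

    def __post_init__(self):
        modes = [
            self.low is not None and self.high is not None,
            self.single is not None,
            self.sex_specific_single is not None,
        ]
        if sum(modes) != 1 or (self.low is None) != (self.high is None):
            raise ValueError(
                "exactly one of {low+high, single, sex_specific_single} must be set"
            )
        if self.low is not None and not self.low < self.high:
            raise ValueError(f"low cutoff {self.low} must be < high cutoff {self.high}")

    @property
    def is_dual(self) -> bool:
        return self.low is not None

    def single_cutoffs(self, sex_array: np.ndarray | None = None) -> np.ndarray | float:
        """Resolve the effective single cutoff (per subject if sex-specific)."""
        if self.single is not None:
            return self.single
        if self.sex_specific_single is not None:
            if sex_array is None:
                raise MissingFieldError("sex")
            f, m = self.sex_specific_single
            return np.where(np.asarray(sex_array) == "male", m, f)
        raise ValueError("dual-cutoff policy has no single cutoff")


def _require_positive(get, *names):
    out = []
    for name in names:
        v = get(name)
        if is_missing(v):
            raise MissingFieldError(name, get("patient_id"))
        if v <= 0:
            raise AnalyteDomainError(name, v)
        out.append(float(v))
    return out


def _require(get, *names):
    out = []
    for name in names:
        v = get(name)
        if is_missing(v):
            raise MissingFieldError(name, get("patient_id"))
        out.append(v)
    return out


def _logistic(y: float) -> float:
    # expit, kept explicit to avoid over/underflow warnings on extreme y
    if y >= 0:
        return 1.0 / (1.0 + np.exp(-y))
    e = np.exp(y)
    return e / (1.0 + e)


def score_nis4(record, coeffs: LogisticCompositeCoefficients) -> float:
    """NIS4 composite: logistic(b0 + b1*log10(mir34a) + b2*a2m + b3*log10(ykl40) + b4*hba1c)."""
    if coeffs.variant != "nis4":
        raise ValueError(f"coefficient set is for variant {coeffs.variant!r}, expected 'nis4'")
    get = as_mapping(record)
    mir34a, ykl40, a2m, hba1c = _require_positive(get, "mir34a", "ykl40", "a2m", "hba1c")
    b0, b1, b2, b3, b4 = coeffs.betas
    y = b0 + b1 * np.log10(mir34a) + b2 * a2m + b3 * np.log10(ykl40) + b4 * hba1c
    return _logistic(y)


def score_nis2plus(record, coeffs: LogisticCompositeCoefficients) -> float:
    """NIS2+ composite with sex-corrected miR-34a (sex: 0 female, 1 male)."""
    if coeffs.variant != "nis2plus":
        raise ValueError(
            f"coefficient set is for variant {coeffs.variant!r}, expected 'nis2plus'"
        )
    get = as_mapping(record)
    mir34a, ykl40 = _require_positive(get, "mir34a", "ykl40")
    (sex,) = _require(get, "sex")
    s = 1.0 if sex == "male" else 0.0
    b0, b1, b2, b3, b4 = coeffs.betas
    lm = np.log10(mir34a)
    y = b0 + b1 * lm + b2 * np.log10(ykl40) + b3 * s + b4 * lm * s
    return _logistic(y)


def score_fib4(record) -> float:
    """FIB-4 = (age * AST) / (platelets * sqrt(ALT))."""
    get = as_mapping(record)
    platelets, alt = _require_positive(get, "platelets", "alt")
    age, ast = _require(get, "age", "ast")
    return (age * ast) / (platelets * np.sqrt(alt))


def score_nfs(
    record,
    ifg_threshold_mmol_per_L: float = DEFAULT_IFG_THRESHOLD,
    allow_g_per_L_albumin: bool = False,
) -> float:
    """NAFLD fibrosis score.

    -1.675 + 0.037*age + 0.094*BMI + 1.13*IFG/diabetes + 0.99*AST/ALT
    - 0.013*platelets - 0.66*albumin(g/dL).

    The IFG/diabetes indicator is 1 if the diabetes flag is set or, when a
    fasting glucose is available, glucose >= ``ifg_threshold_mmol_per_L``.
    Albumin above 10 is flagged as a probable g/L value (the equation wants
    g/dL) unless ``allow_g_per_L_albumin`` overrides the check.
    """
    get = as_mapping(record)
    (alt,) = _require_positive(get, "alt")
    age, bmi, ast, platelets, albumin, diabetes = _require(
        get, "age", "bmi", "ast", "platelets", "albumin", "diabetes"
    )
    if albumin > 10 and not allow_g_per_L_albumin:
        raise UnitSanityError(
            f"albumin {albumin} looks like g/L; the NFS equation expects g/dL "
            "(pass allow_g_per_L_albumin=True to override)"
        )
    fpg = get("fpg")
    ifg = bool(diabetes) or (not is_missing(fpg) and fpg >= ifg_threshold_mmol_per_L)
    return (
        -1.675
        + 0.037 * age
        + 0.094 * bmi
        + 1.13 * (1.0 if ifg else 0.0)
        + 0.99 * (ast / alt)
        - 0.013 * platelets
        - 0.66 * albumin
    )


def score_elf(record) -> float:
    """Enhanced Liver Fibrosis score: 2.494 + 0.846 ln HA + 0.735 ln PIIINP + 0.391 ln TIMP-1."""
    get = as_mapping(record)
    ha, piiinp, timp1 = _require_positive(get, "ha", "piiinp", "timp1")
    return 2.494 + 0.846 * np.log(ha) + 0.735 * np.log(piiinp) + 0.391 * np.log(timp1)


def score_alt(record) -> tuple[float, float]:
    """Raw ALT plus the sex-specific upper limit of normal.

    Returns ``(alt, uln)``; the test is positive iff alt >= uln
    (33 IU/L women, 41 IU/L men).
    """
    get = as_mapping(record)
    (alt,) = _require_positive(get, "alt")
    sex = get("sex")
    if is_missing(sex):
        raise MissingFieldError("sex", get("patient_id"))
    uln = ALT_ULN_MALE if sex == "male" else ALT_ULN_FEMALE
    return float(alt), uln


@dataclass(frozen=True)
class ScoreDefinition:
    """A named scoring rule and its cutoff policy."""

    name: str
    func: Callable  # record -> float
    policy: CutoffPolicy
    required_fields: tuple[str, ...]


def load_default_coefficients() -> dict[str, LogisticCompositeCoefficients]:
    """Load the frozen synthetic-calibration NIS4/NIS2+ coefficient sets."""
    text = resources.files("nashtriage.data").joinpath("coefficients.json").read_text()
    raw = json.loads(text)
    return {
        variant: LogisticCompositeCoefficients(**entry)
        for variant, entry in raw.items()
    }


def default_registry(
    coefficients: Mapping[str, LogisticCompositeCoefficients] | None = None,
) -> dict[str, ScoreDefinition]:
    """The six-test registry with the published low/high cutoffs.

    NIS4 (0.36, 0.63), NIS2+ (0.46, 0.68), FIB-4 (1.30, 2.67),
    NFS (-1.46, 0.68), ELF (7.70, 9.80), ALT single sex-specific ULN.
    """
    if coefficients is None:
        coefficients = load_default_coefficients()
    c4, c2 = coefficients["nis4"], coefficients["nis2plus"]
    return {
        "nis4": ScoreDefinition(
            "nis4", lambda r: score_nis4(r, c4), CutoffPolicy(low=0.36, high=0.63),
            ("mir34a", "ykl40", "a2m", "hba1c"),
        ),
        "nis2plus": ScoreDefinition(
            "nis2plus", lambda r: score_nis2plus(r, c2), CutoffPolicy(low=0.46, high=0.68),
            ("mir34a", "ykl40", "sex"),
        ),
        "fib4": ScoreDefinition(
            "fib4", score_fib4, CutoffPolicy(low=1.30, high=2.67),
            ("age", "ast", "platelets", "alt"),
        ),
        "nfs": ScoreDefinition(
            "nfs", score_nfs, CutoffPolicy(low=-1.46, high=0.68),
            ("age", "bmi", "diabetes", "ast", "alt", "platelets", "albumin"),
        ),
        "elf": ScoreDefinition(
            "elf", score_elf, CutoffPolicy(low=7.70, high=9.80),
            ("ha", "piiinp", "timp1"),
        ),
        "alt": ScoreDefinition(
            "alt", lambda r: score_alt(r)[0],
            CutoffPolicy(sex_specific_single=(ALT_ULN_FEMALE, ALT_ULN_MALE)),
            ("alt", "sex"),
        ),
    }


def score_all(
    cohort: pd.DataFrame,
    registry: Mapping[str, ScoreDefinition],
) -> tuple[pd.DataFrame, dict[tuple[str, str], str]]:
    """Score every patient on every registered test.

    Returns a DataFrame indexed by patient_id with one column per test,
    plus a dict mapping (patient_id, test) -> reason for any missing score
    (e.g. ``"missing:timp1"``).
    """
    scores = pd.DataFrame(index=pd.Index(cohort["patient_id"], name="patient_id"))
    reasons: dict[tuple[str, str], str] = {}
    for name, sdef in registry.items():
        col = np.full(len(cohort), np.nan)
        for i, (_, row) in enumerate(cohort.iterrows()):
            try:
                col[i] = sdef.func(row)
            except MissingFieldError as e:
                reasons[(row["patient_id"], name)] = f"missing:{e.field_name}"
            except AnalyteDomainError as e:
                reasons[(row["patient_id"], name)] = f"domain:{e.analyte}"
        scores[name] = col
    return scores, reasons


def score_frame_vectorized(
    cohort: pd.DataFrame,
    coefficients: Mapping[str, LogisticCompositeCoefficients] | None = None,
) -> pd.DataFrame:
    """Fast vectorized scoring of complete cohorts (all six tests).

    Requires all score inputs present; used by the simulator's calibration
    loop and the evaluation pipeline where cohorts are complete-case.
    """
    if coefficients is None:
        coefficients = load_default_coefficients()
    from scipy.special import expit

    lm = np.log10(cohort["mir34a"].to_numpy(float))
    ly = np.log10(cohort["ykl40"].to_numpy(float))
    s = (cohort["sex"].to_numpy() == "male").astype(float)
    c4, c2 = coefficients["nis4"], coefficients["nis2plus"]
    nis4 = expit(
        c4.beta0 + c4.beta1 * lm + c4.beta2 * cohort["a2m"].to_numpy(float)
        + c4.beta3 * ly + c4.beta4 * cohort["hba1c"].to_numpy(float)
    )
    nis2 = expit(c2.beta0 + c2.beta1 * lm + c2.beta2 * ly + c2.beta3 * s + c2.beta4 * lm * s)
    age = cohort["age"].to_numpy(float)
    ast = cohort["ast"].to_numpy(float)
    alt = cohort["alt"].to_numpy(float)
    plt_ = cohort["platelets"].to_numpy(float)
    fib4 = age * ast / (plt_ * np.sqrt(alt))
    dia = cohort["diabetes"].to_numpy(bool)
    if "fpg" in cohort.columns:
        fpg = cohort["fpg"].to_numpy(float)
        dia = dia | (~np.isnan(fpg) & (fpg >= DEFAULT_IFG_THRESHOLD))
    nfs = (
        -1.675 + 0.037 * age + 0.094 * cohort["bmi"].to_numpy(float) + 1.13 * dia.astype(float)
        + 0.99 * ast / alt - 0.013 * plt_ - 0.66 * cohort["albumin"].to_numpy(float)
    )
    elf = (
        2.494 + 0.846 * np.log(cohort["ha"].to_numpy(float))
        + 0.735 * np.log(cohort["piiinp"].to_numpy(float))
        + 0.391 * np.log(cohort["timp1"].to_numpy(float))
    )
    return pd.DataFrame(
        {"nis4": nis4, "nis2plus": nis2, "fib4": fib4, "nfs": nfs, "elf": elf, "alt": alt},
        index=pd.Index(cohort["patient_id"], name="patient_id"),
    )
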