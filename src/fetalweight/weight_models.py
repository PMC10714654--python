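"""Linear fetal-birth-weight (FBW) estimation models and weight categories.

Two population-specific multiple-linear-regression formulas estimate fetal
weight in grams from biometrics taken at 30–42 weeks of gestation:

``model1_physician`` — biometrics measured by a physician::

    EFW = 2294.857 + 81.018*AC - 42.132*GA + 13.970*E

``model2_image`` — biometrics measured by the image-processing pipeline::

    EFW = -780.532 + 7.269*AC - 5.031*BPD + 16.781*FL + 102.989*GA

with AC/BPD/FL in centimetres, GA (gestational age) in completed weeks and
E an integer ethnicity code.  The cm/weeks unit assignment is the only one
giving term magnitudes consistent with a grams output at term; biometry
measured in mm by :mod:`fetalweight.biometry` is converted automatically.

Birth-weight categories follow the standard neonatal bands: extremely low
(<1000 g), very low (1000–1500 g), low (1500–2500 g), normal (2500–4000 g,
exclusive), macrosomia (>=4000 g, severe at >=4500 g).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

from .biometry import BiometrySet

__all__ = [
    "LinearModel",
    "SubjectRecord",
    "Estimate",
    "WeightCategory",
    "MODEL1_PHYSICIAN",
    "MODEL2_IMAGE",
    "DEFAULT_ETHNICITY_CODEBOOK",
    "evaluate_linear_model",
    "predict_grams",
    "estimate_fbw",
    "classify_weight",
    "weight_report",
]

#: Plausible live-birth range; estimates outside it are flagged, not rejected.
PLAUSIBLE_RANGE_G = (500.0, 6000.0)

#: Provisional integer coding for the ethnicity predictor E (groups in the
#: order the study population is described); override via config where a
#: different codebook was used.
DEFAULT_ETHNICITY_CODEBOOK = {"oromo": 1, "amhara": 2, "snnpr": 3, "other": 4}


@dataclass(frozen=True)
class LinearModel:
    """A linear estimator: grams = intercept + sum(coef * predictor)."""

    name: str
    intercept: float
    terms: tuple[tuple[str, float, str], ...]  # (predictor, coefficient, unit)
    output_unit: str = "g"

    def __post_init__(self) -> None:
        names = [t[0] for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("predictor names must be unique")

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.terms)

    def coefficient(self, name: str) -> float:
        for pname, coef, _unit in self.terms:
            if pname == name:
                return coef
        raise KeyError(name)


MODEL1_PHYSICIAN = LinearModel(
    name="model1_physician",
    intercept=2294.857,
    terms=(
        ("ac_cm", 81.018, "cm"),
        ("ga_weeks", -42.132, "weeks"),
        ("ethnicity_code", 13.970, "code"),
    ),
)

MODEL2_IMAGE = LinearModel(
    name="model2_image",
    intercept=-780.532,
    terms=(
        ("ac_cm", 7.269, "cm"),
        ("bpd_cm", -5.031, "cm"),
        ("fl_cm", 16.781, "cm"),
        ("ga_weeks", 102.989, "weeks"),
    ),
)

_MODELS = {m.name: m for m in (MODEL1_PHYSICIAN, MODEL2_IMAGE)}


@dataclass(frozen=True)
class SubjectRecord:
    """One pregnancy: gestational age, biometrics and (if known) outcome."""

    subject_id: str
    ga_weeks: float
    biometry: BiometrySet
    ethnicity_code: int | None = None
    actual_bw_g: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if not self.ga_weeks > 0:
            raise ValueError("ga_weeks must be positive")
        if self.actual_bw_g is not None and not self.actual_bw_g > 0:
            raise ValueError("actual_bw_g must be positive when present")


@dataclass(frozen=True)
class Estimate:
    grams: float
    model: str
    plausible: bool
    flags: tuple[str, ...] = field(default=())


def evaluate_linear_model(model: LinearModel, predictors: Mapping[str, float]) -> float:
    """Evaluate ``intercept + sum(coef * value)``; purely deterministic."""
    total = model.intercept
    for name, coef, _unit in model.terms:
        if name not in predictors:
            raise ValueError(f"missing predictor {name!r} for model {model.name!r}")
        total += coef * float(predictors[name])
    return total


def predict_grams(
    model_id: str,
    *,
    ac_cm: float | None = None,
    bpd_cm: float | None = None,
    fl_cm: float | None = None,
    ga_weeks: float | None = None,
    ethnicity_code: float | None = None,
) -> Estimate:
    """Estimate FBW in grams from named predictors in model units."""
    model = _MODELS.get(model_id)
    if model is None:
        raise ValueError(f"unknown model {model_id!r}; choose from {sorted(_MODELS)}")
    supplied = {
        "ac_cm": ac_cm,
        "bpd_cm": bpd_cm,
        "fl_cm": fl_cm,
        "ga_weeks": ga_weeks,
        "ethnicity_code": ethnicity_code,
    }
    values = {k: v for k, v in supplied.items() if v is not None}
    grams = evaluate_linear_model(model, values)
    lo, hi = PLAUSIBLE_RANGE_G
    plausible = lo <= grams <= hi
    flags = () if plausible else ("implausible_weight",)
    return Estimate(grams=grams, model=model.name, plausible=plausible, flags=flags)


def estimate_fbw(record: SubjectRecord, model_id: str) -> Estimate:
    """Estimate FBW for a subject record.

    Biometrics stored in mm (the biometry pipeline's unit) are converted to
    the centimetres the formulas expect.
    """
    b = record.biometry

    def cm(v: float | None) -> float | None:
        return None if v is None else v / 10.0

    return predict_grams(
        model_id,
        ac_cm=cm(b.ac_mm),
        bpd_cm=cm(b.bpd_mm),
        fl_cm=cm(b.fl_mm),
        ga_weeks=record.ga_weeks,
        ethnicity_code=record.ethnicity_code,
    )


class WeightCategory(enum.Enum):
    EXTREMELY_LOW = "extremely_low"
    VERY_LOW = "very_low"
    LOW = "low"
    NORMAL = "normal"
    MACROSOMIA = "macrosomia"


def classify_weight(grams: float) -> WeightCategory:
    """Map a positive birth weight (g) to its neonatal category.

    Boundaries: <1000 extremely low; [1000, 1500) very low; [1500, 2500]
    low; (2500, 4000) normal (strict, per the defining inequalities);
    >=4000 macrosomia.  The boundary weights 2500 and 4000 therefore fall in
    the adjacent non-normal classes.
    """
    if not grams > 0:
        raise ValueError("birth weight must be positive")
    if grams < 1000:
        return WeightCategory.EXTREMELY_LOW
    if grams < 1500:
        return WeightCategory.VERY_LOW
    if grams <= 2500:
        return WeightCategory.LOW
    if grams < 4000:
        return WeightCategory.NORMAL
    return WeightCategory.MACROSOMIA


def weight_report(grams: float) -> dict:
    """Category plus sub-flags (``severe_macrosomia`` at >= 4500 g)."""
    cat = classify_weight(grams)
    flags = []
    if grams >= 4500:
        flags.append("severe_macrosomia")
    return {"grams": grams, "category": cat, "flags": tuple(flags)}
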