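"""Logistic lipid-index models (L1/L2/L3): scoring, fitting, prevalence
recalibration and risk-enhancer flagging.

Three chained logistic models turn a lipid panel into an ASCVD
probability:

* **L1** uses only the spherical coordinates (r, theta, phi) of the
  standardized lipid point.
* **L2** uses the L1 probability plus one-hot sex indicators.
* **L3** adds age in years, and is the headline risk index.

Each probability is also reported multiplied by 100 as a "lipid index"
on a 0-100 scale. The published coefficients ship as bundled defaults
(degrees convention for the angles; the L1 probability enters L2/L3 on
the 0-1 scale). A model trained at one outcome prevalence can be carried
to a population with a different prevalence by the logit-shift method:
add logit(p_target) - logit(p_source) to the intercept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConvergenceError,
    DomainError,
    FitError,
    SchemaError,
    UnitError,
)
from .lipid_model import CohortTable, LipidPanel, Sex
from .spherical import (
    AngleUnit,
    StandardizationParams,
    TransformMode,
    cartesian_to_spherical,
    spherical_batch,
    transform_cohort,
    transform_to_cartesian,
)

#: Feature names understood by the scoring pipeline.
KNOWN_FEATURES = ("r", "theta", "phi", "L1", "age", "female", "male")


@dataclass(frozen=True)
class LogisticModel:
    """A named logistic model: p = sigma(B0 + sum_i B_i x_i).

    ``coefficients`` is an ordered (feature_name, B_i) list; the names
    declare how each x_i is computed by the scoring pipeline (spherical
    coordinate, chained L1 probability, age in years, or one-hot sex
    indicator). ``angle_unit`` records the convention the spherical
    coefficients were trained under; ``standardization`` must be attached
    before panels can be scored through the spherical transform.

    The intercept is stored together with its unshifted base and the
    cumulative logit shift applied so far, so that shifting to a
    prevalence and back restores the original intercept exactly.
    """

    name: str
    intercept: float
    coefficients: tuple[tuple[str, float], ...]
    angle_unit: AngleUnit = "degrees"
    standardization: StandardizationParams | None = None
    training_prevalence: float | None = None
    standard_errors: tuple[tuple[str, float], ...] | None = None
    base_intercept: float | None = None
    applied_shift: float = 0.0

    def __post_init__(self) -> None:
        names = [n for n, _ in self.coefficients]
        if len(names) != len(set(names)):
            raise DomainError(f"{self.name}: duplicate feature names in coefficients")
        if self.training_prevalence is not None and not (
            0.0 < self.training_prevalence < 1.0
        ):
            raise DomainError(
                f"{self.name}: training_prevalence must be in (0, 1)"
            )
        if self.base_intercept is None:
            object.__setattr__(self, "base_intercept", self.intercept)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.coefficients)

    def linear_predictor(self, features: Mapping[str, float]) -> float:
        eta = self.intercept
        for name, beta in self.coefficients:
            if name not in features:
                raise SchemaError(
                    f"{self.name}: missing feature {name!r} "
                    f"(supplied: {sorted(features)})"
                )
            eta += beta * float(features[name])
        return eta


def _sigmoid(eta: float | np.ndarray) -> float | np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def _logit(p: float) -> float:
    if not 0.0 < p < 1.0:
        raise DomainError(f"proportion must be strictly inside (0, 1), got {p}")
    return math.log(p / (1.0 - p))


def default_models() -> dict[str, LogisticModel]:
    """The published L1/L2/L3 coefficient sets (degrees convention).

    The L1 model's spherical features require standardization parameters
    for the target population; attach them with
    :func:`attach_standardization` before scoring panels.
    """
    return {
        "L1": LogisticModel(
            name="L1",
            intercept=-2.371,
            coefficients=(("r", 0.3550), ("theta", -0.0107), ("phi", -0.0268)),
            angle_unit="degrees",
        ),
        "L2": LogisticModel(
            name="L2",
            intercept=-1.383,
            coefficients=(("L1", 3.783), ("female", -0.9089), ("male", -0.3693)),
            angle_unit="degrees",
        ),
        "L3": LogisticModel(
            name="L3",
            intercept=-4.756,
            coefficients=(
                ("L1", 3.718),
                ("age", 0.0504),
                ("female", -0.2605),
                ("male", 0.2615),
            ),
            angle_unit="degrees",
        ),
    }


def attach_standardization(
    models: Mapping[str, LogisticModel], params: StandardizationParams
) -> dict[str, LogisticModel]:
    """Return a copy of the model set with standardization attached to each."""
    return {k: replace(m, standardization=params) for k, m in models.items()}


def score_logistic(
    model: LogisticModel,
    features: Mapping[str, float],
    angle_unit: AngleUnit | None = None,
) -> float:
    """Evaluate sigma(B0 + sum B_i x_i) for named feature values.

    ``angle_unit`` declares the unit of any supplied theta/phi values; if
    given and the model consumes spherical angles under a different
    convention, a :class:`UnitError` is raised rather than silently
    mis-scoring.
    """
    uses_angles = any(n in ("theta", "phi") for n in model.feature_names)
    if angle_unit is not None and uses_angles and angle_unit != model.angle_unit:
        raise UnitError(
            f"{model.name} expects angles in {model.angle_unit}, got {angle_unit}"
        )
    return float(_sigmoid(model.linear_predictor(features)))


@dataclass(frozen=True)
class LipidIndexResult:
    """Probabilities (l1..l3 in (0,1)) and 0-100 indices (li = 100 * l)."""

    l1: float
    l2: float
    l3: float
    r: float
    theta: float
    phi: float
    clip_warning: bool = False
    degenerate: bool = False

    @property
    def li1(self) -> float:
        return 100.0 * self.l1

    @property
    def li2(self) -> float:
        return 100.0 * self.l2

    @property
    def li3(self) -> float:
        return 100.0 * self.l3


def _sex_indicators(sex: Sex | None, model_name: str) -> dict[str, float]:
    if sex is None:
        raise SchemaError(f"{model_name}: sex is required (L1 alone is computable)")
    return {
        "female": 1.0 if sex is Sex.FEMALE else 0.0,
        "male": 1.0 if sex is Sex.MALE else 0.0,
    }


def _spherical_features(
    panel: LipidPanel, model: LogisticModel, mode: TransformMode
):
    if model.standardization is None:
        raise SchemaError(
            f"{model.name}: standardization parameters are required to score a "
            "panel; attach them with attach_standardization()"
        )
    point = transform_to_cartesian(panel, model.standardization, mode)
    if point is None:
        raise DomainError(
            f"{panel.subject_id}: outside the z-score bound in training_filter mode"
        )
    sph = cartesian_to_spherical(point, model.angle_unit)
    return sph, point.clipped


def score_l1(
    panel: LipidPanel,
    model: LogisticModel,
    mode: TransformMode = "scoring_clip",
) -> float:
    """Score the spherical-features-only model for one subject.

    Unlike :func:`compose_indices` this needs neither sex nor age, so L1
    remains computable when demographics are missing.
    """
    sph, _ = _spherical_features(panel, model, mode)
    return score_logistic(model, {"r": sph.r, "theta": sph.theta, "phi": sph.phi})


def compose_indices(
    panel: LipidPanel,
    models: Mapping[str, LogisticModel],
    mode: TransformMode = "scoring_clip",
) -> LipidIndexResult:
    """Chain L1 -> L2 -> L3 for one subject.

    Computes the spherical features from the panel via the L1 model's
    standardization, scores L1, feeds the L1 *probability* (0-1 scale)
    with one-hot sex into L2, and additionally age into L3. All models
    must share angle unit and standardization.
    """
    for key in ("L1", "L2", "L3"):
        if key not in models:
            raise SchemaError(f"model set missing {key!r}")
    m1, m2, m3 = models["L1"], models["L2"], models["L3"]
    if not (m1.angle_unit == m2.angle_unit == m3.angle_unit):
        raise UnitError("L1/L2/L3 must share an angle unit")
    sph, clipped = _spherical_features(panel, m1, mode)
    l1 = score_logistic(m1, {"r": sph.r, "theta": sph.theta, "phi": sph.phi})
    sex_ind = _sex_indicators(panel.sex, m2.name)
    l2 = score_logistic(m2, {"L1": l1, **sex_ind})
    if panel.age is None:
        raise SchemaError(f"{m3.name}: age is required")
    l3 = score_logistic(m3, {"L1": l1, "age": panel.age, **sex_ind})
    return LipidIndexResult(
        l1=l1,
        l2=l2,
        l3=l3,
        r=sph.r,
        theta=sph.theta,
        phi=sph.phi,
        clip_warning=clipped,
        degenerate=sph.degenerate,
    )


def score_cohort(
    cohort: CohortTable,
    models: Mapping[str, LogisticModel],
    mode: TransformMode = "scoring_clip",
) -> pd.DataFrame:
    """Vectorised :func:`compose_indices` over a cohort.

    Returns a DataFrame aligned with the kept records: subject_id, the
    spherical features, L1/L2/L3 probabilities, LI1/LI2/LI3 indices and
    clip/degeneracy flags. In ``training_filter`` mode, records outside
    the z-bound are dropped (their ids appear in neither output).
    """
    m1, m2, m3 = models["L1"], models["L2"], models["L3"]
    if m1.standardization is None:
        raise SchemaError("L1 model has no standardization parameters attached")
    points, kept, clipped = transform_cohort(cohort, m1.standardization, mode)
    sph = spherical_batch(points, m1.angle_unit)
    records = [r for r, k in zip(cohort.records, kept) if k]

    def beta(model: LogisticModel) -> dict[str, float]:
        return dict(model.coefficients)

    b1 = beta(m1)
    eta1 = m1.intercept + b1["r"] * sph[:, 0] + b1["theta"] * sph[:, 1] + b1["phi"] * sph[:, 2]
    l1 = _sigmoid(eta1)

    sex_missing = [r.subject_id for r in records if r.sex is None]
    if sex_missing:
        raise SchemaError(
            f"sex is required to score L2/L3; missing for {sex_missing[:5]}"
        )
    age_missing = [r.subject_id for r in records if r.age is None]
    if age_missing:
        raise SchemaError(f"age is required to score L3; missing for {age_missing[:5]}")
    female = np.array([1.0 if r.sex is Sex.FEMALE else 0.0 for r in records])
    male = 1.0 - female
    age = np.array([r.age for r in records], dtype=float)

    b2 = beta(m2)
    l2 = _sigmoid(m2.intercept + b2["L1"] * l1 + b2["female"] * female + b2["male"] * male)
    b3 = beta(m3)
    l3 = _sigmoid(
        m3.intercept
        + b3["L1"] * l1
        + b3["age"] * age
        + b3["female"] * female
        + b3["male"] * male
    )
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "r": sph[:, 0],
            "theta": sph[:, 1],
            "phi": sph[:, 2],
            "L1": l1,
            "L2": l2,
            "L3": l3,
            "LI1": 100.0 * l1,
            "LI2": 100.0 * l2,
            "LI3": 100.0 * l3,
            "clip_warning": clipped,
        }
    )


def fit_logistic(
    features: pd.DataFrame,
    outcomes: Sequence[int] | np.ndarray,
    ridge: float = 1e-4,
    name: str = "fitted",
    angle_unit: AngleUnit = "degrees",
    standardization: StandardizationParams | None = None,
) -> LogisticModel:
    """Maximum-likelihood logistic fit with an optional ridge penalty.

    A small ridge (default 1e-4) keeps the deliberately redundant
    {female, male, intercept} parameterisation of the published models
    estimable without a singular fit. ``ridge=0`` requests the exact
    unpenalised MLE and raises :class:`ConvergenceError` under complete
    separation. Wald standard errors from the observed information matrix
    are stored on the returned model; the intercept is never penalised.
    """
    y = np.asarray(outcomes, dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or len(y) != len(X):
        raise FitError("features and outcomes must align row-wise")
    n = len(y)
    if n < 10:
        raise FitError(f"need at least 10 rows to fit, got {n}")
    if not (0 < y.sum() < n):
        raise FitError("outcomes contain a single class; cannot fit")
    if ridge < 0:
        raise DomainError("ridge penalty must be >= 0")
    names = list(features.columns)
    prevalence = float(y.mean())

    if not names:  # intercept-only: closed-form MLE
        return LogisticModel(
            name=name,
            intercept=_logit(prevalence),
            coefficients=(),
            angle_unit=angle_unit,
            standardization=standardization,
            training_prevalence=prevalence,
        )

    if ridge > 0:
        from sklearn.linear_model import LogisticRegression

        # sklearn minimises 0.5 w'w + C * log-loss  =>  C = 1/ridge
        clf = LogisticRegression(
            C=1.0 / ridge, solver="lbfgs", max_iter=5000, tol=1e-10
        )
        clf.fit(X, y)
        intercept = float(clf.intercept_[0])
        coefs = clf.coef_[0].astype(float)
    else:
        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        design = sm.add_constant(X, has_constant="add")
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise ConvergenceError(
                f"unpenalised fit failed ({exc}); a small ridge penalty "
                "(e.g. 1e-4) regularises separated or collinear data"
            ) from None
        params = np.asarray(res.params, dtype=float)
        if not res.mle_retvals.get("converged", False) or not np.all(
            np.isfinite(params)
        ) or np.max(np.abs(params)) > 1e3:
            raise ConvergenceError(
                "unpenalised fit did not converge (possible complete "
                "separation); retry with ridge > 0"
            )
        intercept = float(params[0])
        coefs = params[1:]

    # Wald SEs from the observed information at the estimate
    eta = intercept + X @ coefs
    p = _sigmoid(eta)
    w = p * (1.0 - p)
    design = np.column_stack([np.ones(n), X])
    info = design.T @ (design * w[:, None])
    if ridge > 0:
        pen = ridge * np.eye(info.shape[0])
        pen[0, 0] = 0.0
        info = info + pen
    try:
        cov = np.linalg.inv(info)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(info.shape[0], np.nan)

    return LogisticModel(
        name=name,
        intercept=intercept,
        coefficients=tuple(zip(names, (float(c) for c in coefs))),
        angle_unit=angle_unit,
        standardization=standardization,
        training_prevalence=prevalence,
        standard_errors=tuple(
            zip(["intercept"] + names, (float(s) for s in ses))
        ),
    )


def logit_shift(
    model: LogisticModel, p_source: float, p_target: float
) -> LogisticModel:
    """Recalibrate the intercept from a source to a target prevalence.

    Adds logit(p_target) - logit(p_source) to the intercept, leaving all
    coefficients untouched. Shifts compose on the model's unshifted base
    intercept, so shifting a -> b -> a restores the original intercept
    bit-for-bit.
    """
    delta = _logit(p_target) - _logit(p_source)
    new_applied = model.applied_shift + delta
    return replace(
        model,
        intercept=model.base_intercept + new_applied,
        applied_shift=new_applied,
    )


@dataclass(frozen=True)
class RiskEnhancerThresholds:
    """Guideline risk-enhancer thresholds (inequalities are >=)."""

    ldlc: float = 160.0  # mg/dL
    tg: float = 175.0  # mg/dL
    apob: float = 130.0  # mg/dL
    l3: float = 0.37  # L3 probability (80th percentile, US reference)


DEFAULT_ENHANCER_THRESHOLDS = RiskEnhancerThresholds()


@dataclass(frozen=True)
class RiskEnhancerResult:
    flags: frozenset[str]
    missing: frozenset[str]


def risk_enhancer_flags(
    panel: LipidPanel,
    l3: float,
    thresholds: RiskEnhancerThresholds = DEFAULT_ENHANCER_THRESHOLDS,
) -> RiskEnhancerResult:
    """Which risk-enhancer inequalities a subject meets.

    Returns the subset of {ldlc_high, tg_high, apob_high, l3_high} whose
    ``value >= threshold`` holds. A missing apoB cannot raise its flag and
    is reported in ``missing`` instead.
    """
    flags: set[str] = set()
    missing: set[str] = set()
    if panel.ldlc >= thresholds.ldlc:
        flags.add("ldlc_high")
    if panel.tg >= thresholds.tg:
        flags.add("tg_high")
    if panel.apob is None:
        missing.add("apob")
    elif panel.apob >= thresholds.apob:
        flags.add("apob_high")
    if l3 >= thresholds.l3:
        flags.add("l3_high")
    return RiskEnhancerResult(flags=frozenset(flags), missing=frozenset(missing))


# ---------------------------------------------------------------------------
# Model file I/O: flat text key/value with one [section] per model.

def models_to_file(models: Mapping[str, LogisticModel], path: str) -> None:
    """Serialise a model set to a text key/value file with sections."""
    lines: list[str] = []
    for key, m in models.items():
        lines.append(f"[{key}]")
        lines.append(f"name = {m.name}")
        lines.append(f"intercept = {m.intercept!r}")
        lines.append(f"angle_unit = {m.angle_unit}")
        for fname, b in m.coefficients:
            lines.append(f"coef.{fname} = {b!r}")
        if m.training_prevalence is not None:
            lines.append(f"training_prevalence = {m.training_prevalence!r}")
        lines.append(f"base_intercept = {m.base_intercept!r}")
        lines.append(f"applied_shift = {m.applied_shift!r}")
        if m.standardization is not None:
            s = m.standardization
            for fname in (
                "mean_inv_h",
                "sd_inv_h",
                "mean_ln_tg",
                "sd_ln_tg",
                "mean_nhdlc",
                "sd_nhdlc",
                "shift",
                "z_bound",
            ):
                lines.append(f"standardization.{fname} = {float(getattr(s, fname))!r}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def models_from_file(path: str) -> dict[str, LogisticModel]:
    """Read a model set written by :func:`models_to_file`."""
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = {}
                sections[line[1:-1]] = current
                continue
            if current is None:
                raise SchemaError(f"{path}: key/value before any [section]")
            key, _, value = line.partition("=")
            current[key.strip()] = value.strip()

    models: dict[str, LogisticModel] = {}
    for key, kv in sections.items():
        std = None
        std_keys = {k: v for k, v in kv.items() if k.startswith("standardization.")}
        if std_keys:
            std = StandardizationParams(
                **{k.split(".", 1)[1]: float(v) for k, v in std_keys.items()}
            )
        coefs = tuple(
            (k.split(".", 1)[1], float(v))
            for k, v in kv.items()
            if k.startswith("coef.")
        )
        try:
            models[key] = LogisticModel(
                name=kv.get("name", key),
                intercept=float(kv["intercept"]),
                coefficients=coefs,
                angle_unit=kv.get("angle_unit", "degrees"),  # type: ignore[arg-type]
                standardization=std,
                training_prevalence=(
                    float(kv["training_prevalence"])
                    if "training_prevalence" in kv
                    else None
                ),
                base_intercept=(
                    float(kv["base_intercept"]) if "base_intercept" in kv else None
                ),
                applied_shift=float(kv.get("applied_shift", 0.0)),
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: model section [{key}] missing {exc}") from None
    return models
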