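"""Synthetic lipid-panel cohorts with the correlation structure the
phenotyping and risk-index pipeline assumes.

The generator draws the *transformed* features — 1/HDLC, ln TG and
non-HDLC — from a trivariate normal with positive pairwise correlations
(the transforms exist precisely to make the features jointly
near-normal and positively correlated), then back-transforms:
``hdlc = 1/inv_h``, ``tg = exp(ln_tg)``, ``tc = nhdlc + hdlc``. Default
moments are chosen so the back-transformed medians land near US
reference values (HDLC ~ 51, TG ~ 107, non-HDLC ~ 146 mg/dL); they are
documented approximations of a general-population survey, not fitted
estimates. Outcomes are simulated from a stored logistic model so that
fitting code can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigError, DomainError
from .lipid_model import CohortTable, LipidPanel, Sex
from .risk_index import LogisticModel, score_cohort

#: Default transformed-scale moments (US general-population scale).
DEFAULT_MEANS = {"inv_h": 1.0 / 51.0, "ln_tg": math.log(107.0), "nhdlc": 146.0}
DEFAULT_SDS = {"inv_h": 0.006, "ln_tg": 0.55, "nhdlc": 40.0}

#: Positive pairwise correlations in (inv_h, ln_tg, nhdlc) order. The
#: strong inv_h <-> ln_tg entry reflects the well-known inverse TG-HDL
#: relationship (positive after inversion of HDLC).
DEFAULT_CORR = np.array(
    [
        [1.00, 0.50, 0.15],
        [0.50, 1.00, 0.35],
        [0.15, 0.35, 1.00],
    ]
)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    ``means``/``sds`` are on the transformed scale (keys ``inv_h``,
    ``ln_tg``, ``nhdlc``); ``corr`` is their 3x3 correlation matrix,
    symmetric positive-definite with non-negative off-diagonals by
    default. Ages are uniform over ``age_range`` (years); ``sex_ratio``
    is the proportion female. ``survival_scale`` (years) and ``horizon``
    control outcome simulation (see :func:`simulate_outcomes`).
    """

    n: int = 1000
    seed: int = 0
    means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MEANS))
    sds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SDS))
    corr: np.ndarray = field(default_factory=lambda: DEFAULT_CORR.copy())
    age_range: tuple[float, float] = (40.0, 70.0)
    sex_ratio: float = 0.52
    with_apob: bool = True
    survival_scale: float = 8.0
    horizon: float = 15.0

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError("sex_ratio must be in [0, 1]")
        if self.corr.shape != (3, 3) or not np.allclose(self.corr, self.corr.T):
            raise ConfigError("corr must be a symmetric 3x3 matrix")
        try:
            np.linalg.cholesky(self.corr)
        except np.linalg.LinAlgError:
            raise ConfigError("corr must be positive-definite") from None
        for key in ("inv_h", "ln_tg", "nhdlc"):
            if key not in self.means or key not in self.sds:
                raise ConfigError(f"means/sds must define {key!r}")
            if not self.sds[key] > 0:
                raise ConfigError(f"sd for {key!r} must be positive")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigError("age_range must be increasing")
        if self.survival_scale <= 0 or self.horizon <= 0:
            raise ConfigError("survival_scale and horizon must be positive")


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a synthetic cohort; deterministic for a fixed seed.

    Tail draws yielding non-physiological panels (inv_h <= 0, nhdlc <= 0,
    or TG outside (1, 5000) mg/dL) are resampled and counted in
    ``n_rejected['resampled']``.
    """
    rng = np.random.default_rng(config.seed)
    order = ("inv_h", "ln_tg", "nhdlc")
    mean = np.array([config.means[k] for k in order])
    sd = np.array([config.sds[k] for k in order])
    cov = config.corr * np.outer(sd, sd)

    draws = np.empty((config.n, 3))
    need = np.ones(config.n, dtype=bool)
    n_resampled = 0
    while need.any():
        k = int(need.sum())
        cand = rng.multivariate_normal(mean, cov, size=k, method="cholesky")
        ok = (
            (cand[:, 0] > 1e-4)  # hdlc below 10,000 mg/dL, positive
            & (cand[:, 2] > 0)
            & (cand[:, 1] > 0)
            & (cand[:, 1] < math.log(5000.0))
        )
        idx = np.flatnonzero(need)
        draws[idx[ok]] = cand[ok]
        need[idx[ok]] = False
        n_resampled += k - int(ok.sum())

    inv_h, ln_tg, nhdlc = draws[:, 0], draws[:, 1], draws[:, 2]
    hdlc = 1.0 / inv_h
    tg = np.exp(ln_tg)
    tc = nhdlc + hdlc
    age = rng.uniform(config.age_range[0], config.age_range[1], size=config.n)
    female = rng.random(config.n) < config.sex_ratio
    apob = None
    if config.with_apob:
        # apoB tracks non-HDLC (every apoB particle carries its cholesterol)
        apob = np.clip(0.62 * nhdlc + rng.normal(0.0, 10.0, config.n), 5.0, None)
    records = [
        LipidPanel(
            subject_id=f"S{i:06d}",
            tc=float(tc[i]),
            hdlc=float(hdlc[i]),
            tg=float(tg[i]),
            age=float(age[i]),
            sex=Sex.FEMALE if female[i] else Sex.MALE,
            apob=float(apob[i]) if config.with_apob else None,
            on_lipid_lowering=False,
        )
        for i in range(config.n)
    ]
    table = CohortTable(
        records=records, source_label=f"synthetic(seed={config.seed})"
    )
    if n_resampled:
        table.n_rejected["resampled"] = n_resampled
    return table


def simulate_outcomes(
    cohort: CohortTable,
    models: LogisticModel | Mapping[str, LogisticModel],
    survival_scale: float = 8.0,
    seed: int = 0,
    horizon: float = 15.0,
) -> CohortTable:
    """Attach simulated ASCVD outcomes driven by a logistic model.

    ``models`` is either a single :class:`LogisticModel` over panel-level
    features, or an {L1, L2, L3} set, in which case the L3 probability
    drives the outcome. Events are Bernoulli(p_i); an event's time is
    exponential with rate p_i / survival_scale (higher risk, earlier
    events), while non-events are administratively censored at
    ``horizon`` years. Deterministic per seed.
    """
    if survival_scale <= 0 or horizon <= 0:
        raise DomainError("survival_scale and horizon must be positive")
    rng = np.random.default_rng(seed)
    p = _probabilities(cohort, models)
    event = rng.random(len(cohort)) < p
    # exponential with rate proportional to risk; scale_i = survival_scale / p_i
    t_event = rng.exponential(scale=survival_scale / np.clip(p, 1e-12, None))
    records = [
        LipidPanel(
            subject_id=r.subject_id,
            tc=r.tc,
            hdlc=r.hdlc,
            tg=r.tg,
            age=r.age,
            sex=r.sex,
            apob=r.apob,
            on_lipid_lowering=r.on_lipid_lowering,
            event=bool(event[i]),
            time=float(t_event[i]) if event[i] else float(horizon),
        )
        for i, r in enumerate(cohort.records)
    ]
    return CohortTable(
        records=records,
        source_label=cohort.source_label,
        n_rejected=cohort.n_rejected.copy(),
        rejected=list(cohort.rejected),
    )


def _probabilities(
    cohort: CohortTable, models: LogisticModel | Mapping[str, LogisticModel]
) -> np.ndarray:
    if isinstance(models, LogisticModel):
        model = models
        if not model.feature_names:  # intercept-only
            from .risk_index import _sigmoid

            return np.full(len(cohort), float(_sigmoid(model.intercept)))
        if set(model.feature_names) <= {"r", "theta", "phi"}:
            scored = score_cohort(
                cohort, {"L1": model, "L2": _NULL_L2, "L3": _NULL_L3}
            )
            return scored["L1"].to_numpy()
        raise DomainError(
            "single-model outcome simulation supports intercept-only or "
            "spherical-feature models; pass an {L1, L2, L3} set otherwise"
        )
    scored = score_cohort(cohort, models)
    return scored["L3"].to_numpy()


# Placeholder models so score_cohort's chain can run when only L1 matters.
_NULL_L2 = LogisticModel(
    name="null-L2", intercept=0.0, coefficients=(("L1", 0.0), ("female", 0.0), ("male", 0.0))
)
_NULL_L3 = LogisticModel(
    name="null-L3",
    intercept=0.0,
    coefficients=(("L1", 0.0), ("age", 0.0), ("female", 0.0), ("male", 0.0)),
)
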