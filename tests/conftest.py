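import math

import numpy as np
import pytest

from lipidsphere import (
    GeneratorConfig,
    LipidPanel,
    Sex,
    attach_standardization,
    default_models,
    fit_standardization,
    generate_cohort,
    simulate_outcomes,
)
from lipidsphere.spherical import StandardizationParams


@pytest.fixture(scope="session")
def reference_standardization() -> StandardizationParams:
    """Fixed population moments (US general-population scale) so worked
    examples are reproducible without refitting."""
    return StandardizationParams(
        mean_inv_h=1.0 / 51.0,
        sd_inv_h=0.006,
        mean_ln_tg=math.log(107.0),
        sd_ln_tg=0.55,
        mean_nhdlc=146.0,
        sd_nhdlc=40.0,
    )


@pytest.fixture(scope="session")
def bundled_models(reference_standardization):
    return attach_standardization(default_models(), reference_standardization)


@pytest.fixture()
def mean_subject() -> LipidPanel:
    """A male, 55 y subject sitting exactly at the reference feature means."""
    return LipidPanel(
        subject_id="mean", tc=146.0 + 51.0, hdlc=51.0, tg=107.0, age=55.0,
        sex=Sex.MALE,
    )


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Moderate-size synthetic cohort with simulated outcomes."""
    cohort = generate_cohort(GeneratorConfig(n=4000, seed=11))
    params = fit_standardization(cohort)
    models = attach_standardization(default_models(), params)
    return simulate_outcomes(cohort, models, seed=12), models


@pytest.fixture()
def cohort_csv(tmp_path):
    """A small, hand-written cohort CSV."""
    path = tmp_path / "cohort.csv"
    path.write_text(
        "subject_id,age,sex,tc,hdlc,tg,apob,on_lipid_lowering,event,time\n"
        "a,55,F,204,54,134,99,0,0,10\n"
        "b,62,male,214,52,131,93,0,1,4.5\n"
        "c,41,M,180,45,107,,0,,\n"
    )
    return str(path)
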