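import numpy as np
import pandas as pd
import pytest

from tgtacs.cohort import Contamination, GeneratorParams, generate_cohort, generate_gameplays, inject_contaminants
from tgtacs.study_design import Schedule


@pytest.fixture(scope="session")
def schedule():
    return Schedule()


@pytest.fixture(scope="session")
def clean_params():
    return GeneratorParams(seed=42)


@pytest.fixture(scope="session")
def clean_tables(clean_params, schedule):
    """Uncontaminated cohort + gameplay table at trial scale (38/39)."""
    cohort = generate_cohort(clean_params)
    gameplays = generate_gameplays(cohort, schedule, clean_params)
    return cohort, gameplays


def mm_dprime_aggregate(seed: int, null_group: bool = False):
    """One trial-scale replicate of the 2-back arm, filtered and
    aggregated to the group x gameplay d' series (shared by calibration
    and property tests)."""
    from tgtacs.cohort import _MM_CRIT, _MM_DPRIME, CurveCoefs
    from tgtacs.preprocessing import run_filter_pipeline
    from tgtacs.sdt import aggregate_group_rates

    mm_d = (CurveCoefs(b0=1.2, b_g=4.74e-3, b_g2=-1.55e-5)
            if null_group else _MM_DPRIME)
    params = GeneratorParams(
        seed=seed,
        dprime_coefs={"sm_1back": CurveCoefs(), "mm_2back": mm_d},
        criterion_coefs={"sm_1back": CurveCoefs(), "mm_2back": _MM_CRIT},
    )
    cohort = generate_cohort(params)
    table = generate_gameplays(cohort, params=params, tasks=("mm_2back",))
    filtered, _ = run_filter_pipeline(table, "sdt")
    return aggregate_group_rates(filtered)


@pytest.fixture(scope="session")
def contaminated(schedule):
    """Gameplay table carrying every artefact class, plus its manifest."""
    params = GeneratorParams(
        seed=7,
        contamination=Contamination(
            n_dropouts=2,
            n_excess_gameplays=5,
            n_no_response=8,
            constant_yes_responder=True,
        ),
    )
    cohort = generate_cohort(params)
    gameplays = generate_gameplays(cohort, schedule, params)
    table, manifest = inject_contaminants(gameplays, params)
    return table, manifest
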