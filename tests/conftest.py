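import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

# lifelines is chatty about small datasets and step sizes; irrelevant here
warnings.filterwarnings("ignore", module="lifelines")
try:
    from scipy.integrate import IntegrationWarning

    warnings.filterwarnings("ignore", category=IntegrationWarning)
except ImportError:  # pragma: no cover
    pass


from irskit.cohort import Patient, TherapyLine  # noqa: E402
from irskit.scoring import MolecularCovariates  # noqa: E402
from irskit.tmb import TumorSample  # noqa: E402


def make_patient(
    pid: str = "P1",
    lines=(),
    collection_day: int = 0,
    death_day=None,
    last_followup_day: int = 400,
    tumor_type: str = "NSCLC",
    covariates: bool = True,
    msi_high: bool = False,
    **kw,
) -> Patient:
    """Minimal valid patient for cohort tests."""
    cov = MolecularCovariates(5.0, 4.0, 4.0, 4.0, 4.0) if covariates else None
    sample = TumorSample(pid, 0.6, 1.2, msi_high) if covariates else None
    return Patient(
        patient_id=pid,
        age_at_collection=65.0,
        sex="F",
        tumor_type=tumor_type,
        collection_day=collection_day,
        death_day=death_day,
        last_followup_day=last_followup_day,
        covariates=cov,
        sample=sample,
        lines=[
            ln if isinstance(ln, TherapyLine) else TherapyLine(pid, i + 1, *ln).classified()
            for i, ln in enumerate(lines)
        ],
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2023)
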