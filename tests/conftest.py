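import math

import numpy as np
import pytest

from ppsn.cohort import Cohort, MarkerPanel, PatientRecord
from ppsn.synth import generate, paper_calibrated_config


def separable_config(seed, n=72):
    """Generator settings whose classes are (near-)perfectly separable at
    the true cutoffs: frailty loading ~1 makes all marker severities move
    together, every cutoff sits at the common severity origin, and a huge
    latent effect with a pinned intercept makes death deterministic in the
    abnormal-marker count."""
    base = paper_calibrated_config(seed=seed)
    markers = [
        m.model_copy(update={"cutoff": math.exp(m.mean) if m.log_scale else m.mean})
        for m in base.markers
    ]
    return base.model_copy(update={
        "markers": markers,
        "frailty_loading": 0.9999,
        "pre_post_correlation": 0.99995,
        "latent_effect": 1e4,
        "death_intercept": -3.5e4,
        "missing_pre_fraction": 0.0,
        "n": n,
    })


def make_record(i, *, pre=True, post=True, death=False, **kw):
    """Minimal valid record with optional marker panels."""
    pre_panel = MarkerPanel(
        neutrophil_pct=70.0 + i, lymphocyte_pct=20.0 - 0.5 * i,
        lymphocyte_count=12.0 - 0.3 * i, platelet_count=25.0,
    ) if pre else None
    post_panel = MarkerPanel(
        neutrophil_pct=45.0 + i, lymphocyte_pct=40.0 - 0.5 * i,
        lymphocyte_count=18.0 - 0.4 * i, platelet_count=20.0 - 0.3 * i,
    ) if post else None
    defaults = dict(
        age=60.0, bmi=22.0, parity=1, figo_stage=3, subtype="serous",
        surgical_outcome="complete", days_first_treatment_to_ids=140.0,
        death=death, os_days=1000.0 + 10 * i, recurrence=death,
        pfs_days=600.0 + 10 * i,
    )
    defaults.update(kw)
    return PatientRecord(patient_id=f"P{i:03d}", pre=pre_panel, post=post_panel, **defaults)


@pytest.fixture
def small_cohort():
    """10 records: the 5 sickest (highest marker index) died."""
    return Cohort(
        records=tuple(make_record(i, death=i >= 5) for i in range(10)),
        provenance="fixture",
    )


@pytest.fixture(scope="session")
def calibrated_cohort():
    """One cohort at the shipped study-calibrated settings."""
    return generate(paper_calibrated_config(seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230519)
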