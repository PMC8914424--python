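import numpy as np
import pytest

from biledrain_econ.decision_model import default_us_model
from biledrain_econ.synthetic_trial import calibrate_to_targets
from biledrain_econ.trial_cost_comparison import PatientCostRecord


@pytest.fixture(scope="session")
def us_model():
    """The packaged US Medicare two-strategy decision model."""
    return default_us_model()


@pytest.fixture(scope="session")
def calibrated_configs():
    """Arm generator configs calibrated to the published cost summaries.

    Session-scoped: calibration runs a recentering simulation and is shared
    across tests.
    """
    return calibrate_to_targets()


def make_record(
    patient_id="p1",
    arm="EUS-BD",
    hospital=3000.0,
    primary=1029.15,
    reint=0.0,
    n_reint=0,
    sessions=1,
):
    return PatientCostRecord(
        patient_id=patient_id,
        arm=arm,
        hospital_other_cost=hospital,
        primary_bd_cost=primary,
        reintervention_cost=reint,
        n_reinterventions=n_reint,
        n_primary_sessions=sessions,
    )


def trial_structure_fixture():
    """Deterministic records reproducing the source trial's re-intervention
    structure: 8 of 32 EUS-BD patients with 11 events total, 17 of 31 PTBD
    patients with 29 events total."""
    rng = np.random.default_rng(12345)
    records = []
    # 5 patients x 1 event + 3 patients x 2 events = 11 events over 8 patients
    eus_counts = [1] * 5 + [2] * 3 + [0] * 24
    # 7x1 + 8x2 + 2x3 = 29 events over 17 patients
    ptbd_counts = [1] * 7 + [2] * 8 + [3] * 2 + [0] * 14
    for arm, counts in (("EUS-BD", eus_counts), ("PTBD", ptbd_counts)):
        for i, k in enumerate(counts):
            records.append(
                make_record(
                    patient_id=f"{arm}-{i}",
                    arm=arm,
                    hospital=float(rng.uniform(1500, 9000)),
                    primary=float(rng.uniform(800, 1800)),
                    reint=float(rng.uniform(100, 1600)) if k else 0.0,
                    n_reint=k,
                )
            )
    return records


@pytest.fixture()
def trial_structure_records():
    return trial_structure_fixture()
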