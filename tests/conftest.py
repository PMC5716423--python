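import numpy as np
import pytest

from arcverify import ArcPlan, ControlPoint, MachineGeometry


@pytest.fixture
def geometry():
    return MachineGeometry()


def make_cp(index, mu, gantry, bank_a=None, bank_b=None, jaws=None):
    """Control point with open jaws and symmetric banks unless overridden."""
    if bank_a is None:
        bank_a = np.full(40, -10.0)
    if bank_b is None:
        bank_b = np.full(40, 10.0)
    if jaws is None:
        jaws = np.array([-200.0, 200.0, -200.0, 200.0])
    return ControlPoint(index=index, cumulative_mu=mu, gantry_deg=gantry,
                        bank_a=np.asarray(bank_a, dtype=float),
                        bank_b=np.asarray(bank_b, dtype=float),
                        jaws=np.asarray(jaws, dtype=float))


def make_plan(cps, sense=-1, patient_id="P001", field_id="A1"):
    plan = ArcPlan(patient_id=patient_id, field_id=field_id,
                   control_points=cps, rotation_sense=sense)
    plan.validate()
    return plan


@pytest.fixture
def two_cp_plan():
    """mu 0 -> 100, gantry 175 -> 171, leaves at +/-10 mm, open jaws."""
    return make_plan([make_cp(0, 0.0, 175.0), make_cp(1, 100.0, 171.0)])


def random_plan(rng, n_cp=10, sense=-1, start=175.0, total_mu=100.0, span=350.0):
    """Random validated plan with monotone MU and smoothly moving leaves."""
    mu = np.sort(rng.uniform(0, total_mu, n_cp - 2))
    mu = np.concatenate([[0.0], mu, [total_mu]])
    unwrapped = start + sense * np.linspace(0.0, span, n_cp)
    cps = []
    center = rng.normal(0, 20, 40)
    width = rng.uniform(5, 60, 40)
    for k in range(n_cp):
        center = center + rng.normal(0, 2, 40)
        width = np.maximum(width + rng.normal(0, 2, 40), 1.0)
        cps.append(make_cp(k, float(mu[k]), float(unwrapped[k] % 360.0),
                           bank_a=center - width / 2, bank_b=center + width / 2))
    return make_plan(cps, sense=sense)
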