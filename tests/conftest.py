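import numpy as np
import pytest

import dialsim as ds
from dialsim.pump import PumpType


@pytest.fixture(scope="session")
def dialyser():
    return ds.DialyserSpec.default()


@pytest.fixture(scope="session")
def pump_curves():
    pulsatile, non_pulsatile = ds.synthesize_pump_curves(seed=0)
    return {PumpType.PULSATILE: pulsatile, PumpType.NON_PULSATILE: non_pulsatile}


@pytest.fixture()
def patient():
    """Default 73-kg anuric patient (params, baseline state)."""
    return ds.default_patient()


@pytest.fixture(scope="session")
def fixture_session_clearances(dialyser):
    """Clinical-fixture session: conventional HD, Qb 300, Qd 500, UF 0.5 L/h."""
    return ds.clearances_for_prescribed_uf(
        dialyser, ds.TherapyMode.HDF, qb=300.0, qd=500.0, qf=500.0 / 60.0
    )


def countercurrent_oracle(koa: float, qb: float, qd: float, n: int = 20_000) -> float:
    """Independent fine-grid solution of the 1-D two-stream transport equations.

    Blood flows 0 -> 1 with flow qb and inlet concentration 1; dialysate flows
    1 -> 0 with flow qd and inlet concentration 0.  The local solute flux per
    unit length is koa*(Cb - Cd).  The linear two-point boundary problem is
    solved by shooting from x = 0 with two trial dialysate concentrations and
    combining by linearity; integration is fixed-step RK4 on a fine grid.
    Returns the clearance qb*(1 - Cb(1)).
    """

    def advance(cb0: float, cd0: float) -> tuple[float, float]:
        h = 1.0 / n
        cb, cd = cb0, cd0

        def rhs(b, d):
            j = koa * (b - d)
            return -j / qb, -j / qd

        for _ in range(n):
            k1 = rhs(cb, cd)
            k2 = rhs(cb + 0.5 * h * k1[0], cd + 0.5 * h * k1[1])
            k3 = rhs(cb + 0.5 * h * k2[0], cd + 0.5 * h * k2[1])
            k4 = rhs(cb + h * k3[0], cd + h * k3[1])
            cb += (h / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            cd += (h / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        return cb, cd

    # Cd(1) is affine in Cd(0): find the Cd(0) for which Cd(1) = 0
    _, cd_end0 = advance(1.0, 0.0)
    _, cd_end1 = advance(1.0, 1.0)
    cd0 = -cd_end0 / (cd_end1 - cd_end0)
    cb_end, _ = advance(1.0, cd0)
    return qb * (1.0 - cb_end)
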