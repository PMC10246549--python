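import numpy as np
import pytest

import ventcontrol as vc


def sig4(x: float) -> float:
    """Round to 4 significant figures (the precision of the published values)."""
    return float(f"{x:.4g}")


def dense_centroid(var, weights, n: int = 200001) -> float:
    """Brute-force area-barycenter of the aggregated output set on a dense
    uniform grid; independent of the package's exact piecewise integrator."""
    lo, hi = var.universe
    xs = np.linspace(lo, hi, n)
    agg = np.max(
        [np.minimum(w, mf(xs)) for mf, w in zip(var.mfs, weights)], axis=0
    )
    area = np.trapezoid(agg, xs)
    if area <= 0:
        return 0.5 * (lo + hi)
    return float(np.trapezoid(agg * xs, xs) / area)


@pytest.fixture(scope="session")
def reference_params():
    return vc.LungHoseParams()


@pytest.fixture(scope="session")
def plant_ss(reference_params):
    return vc.build_hose_patient_ss(reference_params)


@pytest.fixture(scope="session")
def plant_tf(plant_ss):
    return vc.ss_to_tf(plant_ss, "p_airway")


@pytest.fixture(scope="session")
def blower():
    return vc.blower_tf(vc.BlowerParams())


@pytest.fixture(scope="session")
def optimal_gains():
    return vc.BENCHMARK_CONTROLLERS["optimal_rule_fuzzy_pid"]


@pytest.fixture(scope="session")
def printed_tfs():
    """Plant, blower and PID transfer functions at the published precision."""
    plant = vc.TransferFunction([0.5063, 5.063], [1.0, 5.443])
    blower = vc.TransferFunction([35530.0], [1.0, 377.0, 35530.0])
    pid = vc.TransferFunction([0.00048, 0.2891, 62.88], [1.0, 0.0])
    return plant, blower, pid


@pytest.fixture
def default_fis():
    return vc.FISConfig()


@pytest.fixture
def step_scenario_factory(optimal_gains):
    """Unit-step tracking scenarios (PIP held from t=0) with fixed gains."""

    def make(duration=0.2, dt=2.5e-4, t_exp=0.01, controller=None, **kw):
        pat = vc.BreathingPattern(
            kind="peep_pip", low=0.0, high=1.0, t_insp=duration - t_exp, t_exp=t_exp
        )
        return vc.ScenarioConfig(
            pattern=pat, duration=duration, dt=dt,
            controller=controller if controller is not None else optimal_gains, **kw,
        )

    return make
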