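import numpy as np
import pytest

import bimast as bm
from bimast.health_econ import ALIVE_STATES, EconConfig


@pytest.fixture(scope="session")
def small_cohort():
    """287-subject primary-care cohort, fixed seed."""
    return bm.generate_cohort(bm.default_spec(n=287, seed=42))


@pytest.fixture(scope="session")
def large_cohort():
    """50k-subject cohort for median/prevalence calibration checks."""
    return bm.generate_cohort(bm.default_spec(n=50_000, seed=7))


@pytest.fixture()
def econ_config():
    return bm.load_default_config()


def random_econ_config(rng: np.random.Generator) -> EconConfig:
    """A random valid parameter set respecting the model's structure.

    Progression runs along the severity chain with undiagnosed disease
    progressing at least as fast as diagnosed, death risk grows with
    severity, and utilities are a valid QALY weight per state.
    """
    cfg = bm.load_default_config()
    u = rng.uniform
    sld_dx_cc = u(0.005, 0.04)
    sld_fn_cc = sld_dx_cc + u(0.0, 0.05)
    sld_dx_d = u(0.0, 0.01)
    sld_fn_d = sld_dx_d + u(0.0, 0.01)
    cc_dx_dc, cc_dx_hcc, cc_dx_d = u(0.01, 0.05), u(0.005, 0.02), u(0.01, 0.03)
    cfg.transitions = {
        "MLD": {"SLD_fn": u(0.0, 0.03)},
        "SLD_dx": {"CC_dx": sld_dx_cc, "DEAD": sld_dx_d},
        "SLD_fn": {"CC_fn": sld_fn_cc, "DEAD": sld_fn_d},
        "CC_dx": {"DC": cc_dx_dc, "HCC": cc_dx_hcc, "DEAD": cc_dx_d},
        "CC_fn": {"DC": cc_dx_dc + u(0.0, 0.05), "HCC": cc_dx_hcc + u(0.0, 0.02),
                  "DEAD": cc_dx_d + u(0.0, 0.02)},
        "DC": {"HCC": u(0.0, 0.04), "LT": u(0.0, 0.05), "DEAD": u(0.08, 0.2)},
        "HCC": {"LT": u(0.0, 0.04), "DEAD": u(0.15, 0.35)},
        "LT": {"DEAD": u(0.02, 0.08)},
    }
    u_sld, u_cc = u(0.75, 0.85), u(0.65, 0.78)  # utility attaches to the
    cfg.state_utilities = {                     # disease state, not dx status
        "MLD": u(0.8, 0.9), "SLD_dx": u_sld, "SLD_fn": u_sld,
        "CC_dx": u_cc, "CC_fn": u_cc, "DC": u(0.4, 0.6),
        "HCC": u(0.35, 0.55), "LT": u(0.5, 0.7), "DEAD": 0.0,
    }
    cfg.state_costs = {s: float(u(0, 5000)) for s in ALIVE_STATES} | {"DEAD": 0.0}
    cfg.background_mortality = float(u(0.005, 0.03))
    cfg.discount_rate = float(u(0.0, 0.06))
    cfg.horizon = int(rng.integers(5, 60))
    cfg.validate()
    return cfg
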