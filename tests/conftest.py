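import numpy as np
import pytest

from protdeg import Condition, DegradationModelParams, ExperimentDesign

# Standard parameter set: unrepressed synthesis 40,000 proteins/cell/h,
# growth 1/h, protease Vmax 15,000 proteins/cell/h, Km 600 proteins/cell,
# starting from the pre-induction steady state.
PAPER = dict(alpha=40000.0, mu=1.0, vmax=15000.0, km=600.0, p0=40000.0)


@pytest.fixture
def paper_params():
    return DegradationModelParams(**PAPER)


@pytest.fixture
def balanced_design_factory():
    """Factory for a two-arm balanced-growth design (test strain vs
    degradation-free control sharing the same synthesis rate)."""

    def make(vmax=15000.0, alpha=40000.0, mu=1.0, km=600.0, noise_cv=0.0,
             replicates=4, seed=0, **kwargs):
        test = Condition("WT", DegradationModelParams(alpha=alpha, mu=mu,
                                                      vmax=vmax, km=km))
        control = Condition("dclpP", DegradationModelParams(alpha=alpha, mu=mu,
                                                            vmax=0.0, km=km),
                            is_control=True)
        return ExperimentDesign(conditions=(test, control),
                                replicates=replicates, noise_cv=noise_cv,
                                seed=seed, **kwargs)

    return make


def recover_beta(tcs, condition="WT", control="dclpP"):
    """Run the full estimation pipeline on generated time courses."""
    from protdeg import estimate_beta, estimate_net_rate

    cond = [estimate_net_rate(tc) for tc in tcs if tc.condition == condition]
    ctrl = [estimate_net_rate(tc) for tc in tcs if tc.condition == control]
    return estimate_beta(cond, ctrl, condition=condition, control=control)
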