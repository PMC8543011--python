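import numpy as np
import pandas as pd
import pytest

from tilreact import flow, synthetic


@pytest.fixture(scope="session")
def small_flow_dataset():
    """5,000-event simulation with default (study-condition) mixtures."""
    config = synthetic.FlowSimConfig(n_events=5000, seed=11)
    tables, truth = synthetic.generate_flow_events(config)
    return config, tables, truth


@pytest.fixture(scope="session")
def gated(small_flow_dataset):
    """Thresholds plus CD8 stimulated/control positivity matrices."""
    _config, tables, _truth = small_flow_dataset
    thresholds = flow.set_thresholds(tables[("alone", "none")])
    stim = flow.split_subsets(tables[("autologous", "none")], thresholds)
    ctrl = flow.split_subsets(tables[("alone", "none")], thresholds)
    pos = flow.call_positivity(stim["CD8"], thresholds)
    ctrl_pos = flow.call_positivity(ctrl["CD8"], thresholds)
    return thresholds, pos, ctrl_pos


def random_positivity(rng, n=1000, p=0.3, markers=flow.MARKER_PANEL):
    """Random boolean positivity matrix with a consistent T-CD137 parent pair."""
    pos = pd.DataFrame(
        {m: rng.random(n) < p for m in (flow.S_CD137, flow.IC_CD137, flow.TNF,
                                        flow.IFNG, flow.CD107A)}
    )
    pos[flow.T_CD137] = pos[flow.S_CD137] | pos[flow.IC_CD137]
    return pos
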