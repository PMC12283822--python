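import numpy as np
import pytest

import kmvar
from kmvar.weibull import arm_summary


def portfolio_to_arms(trials):
    """Fit both arms of every simulated trial into meta-regression observations."""
    arms = []
    for tr in trials:
        arms.append(arm_summary(tr.trial_id, 0, tr.placebo[1]))
        arms.append(arm_summary(tr.trial_id, 1, tr.verum[1]))
    return arms


@pytest.fixture(scope="session")
def small_censored_ipd():
    """20 subjects from Weibull(k=1.4, lam=12) with administrative censoring at 15."""
    truth = kmvar.ArmTruth(shape=1.4, scale=12.0, max_follow_up=15.0, n=20)
    return kmvar.simulate_arm(truth, seed=42)


@pytest.fixture(scope="session")
def medium_arm():
    """A CVOT-like arm: heavy administrative censoring, modest dropout."""
    truth = kmvar.ArmTruth(
        shape=1.2, scale=300.0, max_follow_up=36.0, dropout_rate=0.002, n=2000
    )
    return kmvar.simulate_arm(truth, seed=3)


@pytest.fixture(scope="session")
def small_portfolio_arms():
    """Arm summaries of a 4-trial portfolio with modest arm sizes (fast fits)."""
    truth = kmvar.PortfolioTruth(n_trials=4, n_range=(800, 1200), seed=20)
    return portfolio_to_arms(kmvar.simulate_portfolio(truth))
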