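import numpy as np
import pytest

import ordtree as ot


@pytest.fixture(scope="session")
def htsm():
    return ot.build_2htsm()


@pytest.fixture(scope="session")
def bell_model():
    return ot.build_2htsm_bell(("pleasant", "disgusting"))


@pytest.fixture(scope="session")
def small_design():
    """One-condition source-monitoring design: 10/10/20 items, 30 participants."""
    return ot.StudyDesign(
        items_per_tree={"source_A": 10, "source_B": 10, "new": 20}, n_participants=30
    )


@pytest.fixture(scope="session")
def small_dataset(htsm, small_design):
    truth = ot.illustrative_truth(htsm)
    return ot.generate_dataset(htsm, small_design, truth, seed=42)


@pytest.fixture(scope="session")
def smoke_fit(htsm, small_dataset):
    """A shared posterior fit on the small synthetic dataset."""
    table, _ = small_dataset
    prior = ot.informative_preset(htsm)
    settings = ot.McmcSettings(draws=1200, warmup=800, chains=2, seed=7)
    return ot.fit_posterior(htsm, prior, table, settings)


@pytest.fixture(scope="session")
def binomial_toy():
    """Single binomial tree with a uniform implied prior on p."""
    model = ot.parse_eqn("T h p\nT t (1-p)")
    prior = ot.PriorSpec(
        group_mean={"p": ot.NormalSpec(0.0, 1.0)},
        deviation=ot.FixedSpec(0.0),
        correlation=ot.LKJSpec(1.0),
    )
    return model, prior


def make_binomial_table(successes: int, trials: int):
    return ot.FrequencyTable(
        participants=("p1",),
        categories={"T": ("h", "t")},
        counts={"T": np.array([[successes, trials - successes]])},
    )
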