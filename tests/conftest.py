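import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import critmix as cm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_table(rows):
    """Rows of (participant, category, item, session, response[, provenance])."""
    cols = ["participant", "category", "item", "session", "response", "provenance"]
    rows = [list(r) + ["new"] * (6 - len(r)) for r in rows]
    return cm.ResponseTable(pd.DataFrame(rows, columns=cols))


@pytest.fixture
def tiny_two_session():
    """Two participants, one category, three items, both sessions."""
    rows = []
    answers = {
        ("p1", 1): ["yes", "no", "unknown"],
        ("p1", 2): ["yes", "yes", "no"],
        ("p2", 1): ["no", "no", "yes"],
        ("p2", 2): ["no", "no", "yes"],
    }
    for (pid, sess), resp in answers.items():
        for item, r in zip(["a", "b", "c"], resp):
            rows.append((pid, "Fish", item, sess, r))
    return make_table(rows)


@pytest.fixture(scope="session")
def small_study():
    """A small but informative simulated study used across modules."""
    cfg = cm.SimulationConfig(n_participants=20, n_archival=30, n_items=12,
                              between_group_corr=0.1, seed=42)
    return cfg, cm.generate_study(cfg)


@pytest.fixture(scope="session")
def small_fit(small_study):
    """A short three-chain fit of the small study, relabeled."""
    cfg, study = small_study
    model = cm.CriterionMixtureModel.from_tables(
        study.truth.table, study.archival, cfg.category_id)
    res = model.fit(n_chains=3, n_iter=800, n_burnin=400, seed=7).relabel()
    return study, model, res


@pytest.fixture
def fixed_params():
    """A fully pinned 2-group parameter state on 2 entries x 2 items."""
    return cm.ModelParameters(
        pi=np.array([0.4, 0.6]),
        z=np.array([0, 1]),
        beta=np.array([[0.5, -1.0], [1.5, 0.2]]),
        theta=np.array([0.3, -0.7]),
        mu=np.array([-0.5, 0.5]),
        alpha=np.array([1.2, 0.8]),
    )
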