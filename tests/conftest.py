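"""Shared fixtures: small registry tables and Cox counting-process fixtures.

Everything is generated programmatically with fixed seeds so the suite is
deterministic and carries no data files.
"""

import numpy as np
import pandas as pd
import pytest

from msmtx.events import REGISTRY_COLUMNS


def make_registry_frame(rows: list[dict]) -> pd.DataFrame:
    base = {c: np.nan for c in REGISTRY_COLUMNS}
    out = []
    for r in rows:
        d = dict(base)
        d.update(r)
        out.append(d)
    df = pd.DataFrame(out, columns=REGISTRY_COLUMNS)
    defaults = {"age_gt60": 0, "raebt": 0, "cyto_abnormal": 0, "year_dx": 2000,
                "dead": 0}
    for c, v in defaults.items():
        df[c] = df[c].fillna(v)
    return df


@pytest.fixture
def mixed_table() -> pd.DataFrame:
    """A well-formed 10-record mix of both registries."""
    rows = []
    for i in range(6):
        rows.append({"id": f"n{i}", "cohort": "non_tx_registry",
                     "t_end_days": 100.0 + 50 * i, "dead": i % 2})
    for i in range(4):
        rows.append({"id": f"t{i}", "cohort": "tx_registry",
                     "t_tx_days": 80.0 + 40 * i, "t_end_days": 400.0 + 90 * i,
                     "dead": (i + 1) % 2, "r_trunc_days": 2000.0})
    return make_registry_frame(rows)


def _cox_fixture_basic(rng):
    n = 30
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / np.exp(0.7 * x))
    c = rng.exponential(1.5, n)
    return pd.DataFrame({"entry": 0.0, "exit": np.minimum(t, c),
                         "status": (t <= c).astype(int), "x": x})


def _cox_fixture_delayed(rng):
    n = 25
    x = rng.integers(0, 2, n).astype(float)
    entry = rng.uniform(0, 0.8, n)
    t = entry + rng.exponential(1.0 / np.exp(-0.4 * x))
    c = entry + rng.exponential(2.0, n)
    return pd.DataFrame({"entry": entry, "exit": np.minimum(t, c),
                         "status": (t <= c).astype(int), "x": x})


def _cox_fixture_ties(rng):
    n = 36
    x = rng.integers(0, 2, n).astype(float)
    # integer-valued exits force ties among events
    t = np.ceil(rng.exponential(3.0 / np.exp(0.5 * x)))
    c = np.ceil(rng.exponential(5.0, n)) + 0.5
    return pd.DataFrame({"entry": 0.0, "exit": np.minimum(t, c),
                         "status": (t <= c).astype(int), "x": x})


COX_FIXTURE_MAKERS = {
    "basic-30": (_cox_fixture_basic, 11),
    "delayed-entry-25": (_cox_fixture_delayed, 12),
    "tied-events-36": (_cox_fixture_ties, 13),
}


@pytest.fixture(params=sorted(COX_FIXTURE_MAKERS))
def cox_fixture(request) -> pd.DataFrame:
    """Single-binary-covariate counting-process fixtures, each <= 40 rows."""
    maker, seed = COX_FIXTURE_MAKERS[request.param]
    return maker(np.random.default_rng(seed))


def all_cox_fixtures():
    return {name: maker(np.random.default_rng(seed))
            for name, (maker, seed) in COX_FIXTURE_MAKERS.items()}


def grid_search_argmax(loglik, lo=-5.0, hi=5.0, step=1e-4):
    """Grid-search oracle for a 1-d concave partial likelihood.

    A coarse pass locates the optimum to 0.01; the 1e-4 grid is then
    evaluated on the bracketing interval (the partial likelihood is concave
    in the coefficient, so the restriction is exact).
    """
    coarse = np.arange(lo, hi + 1e-12, 0.01)
    ll = np.array([loglik([b]) for b in coarse])
    b0 = coarse[np.argmax(ll)]
    fine = np.arange(b0 - 0.02, b0 + 0.02 + 1e-12, step)
    llf = np.array([loglik([b]) for b in fine])
    return float(fine[np.argmax(llf)])
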