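"""Shared fixtures: montage, head model, and a fast feature-level dataset.

``make_feature_dataset`` builds a FeatureMatrix directly (Gaussian bin
powers with optional class-dependent mean shifts in chosen components),
so classifier-protocol tests run in milliseconds without simulating EEG.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mwdecode.features import N_BINS, FeatureMatrix
from mwdecode.dipole import HeadModel
from mwdecode.synth.montage import build_montage


@pytest.fixture(scope="session")
def montage():
    return build_montage()


@pytest.fixture(scope="session")
def head_model():
    return HeadModel()


@pytest.fixture(scope="session")
def scalp_positions(montage):
    return montage.analysis_positions


def _trial_table(rng, n_participants, n_blocks_vs, trials_per_block,
                 n_blocks_sart, sart_trials_per_block, mw_rate):
    rows = []
    for p in range(n_participants):
        part = f"P{p:02d}"
        onset = 0
        for task, n_blocks, tpb in (("VS", n_blocks_vs, trials_per_block),
                                    ("SART", n_blocks_sart,
                                     sart_trials_per_block)):
            trial = 0
            for b in range(1, n_blocks + 1):
                if task == "VS":
                    cond = "counting" if (b % 2 == 1) ^ (p % 2) else \
                        "noncounting"
                else:
                    cond = "sart"
                mw = rng.random() < mw_rate
                rating = int(np.clip(round(
                    (-2.5 if mw else 2.5) + rng.normal(0, 1.5)), -5, 5))
                for k in range(tpb):
                    onset += 3000
                    rows.append(dict(
                        participant=part, task=task, condition=cond,
                        block=b, trial=trial, onset_sample=onset,
                        attention="mind_wandering" if mw else "on_task",
                        rating=rating if k >= tpb - 3 else np.nan,
                    ))
                    trial += 1
    return pd.DataFrame(rows)


def make_feature_dataset(
    seed=0,
    n_participants=6,
    n_components=8,
    n_blocks_vs=10,
    trials_per_block=6,
    n_blocks_sart=4,
    sart_trials_per_block=9,
    mw_rate=0.4,
    demand_effect=0.0,
    vigilance_effect=0.0,
    attention_effect=0.0,
    effect_components=(1,),
) -> FeatureMatrix:
    """Gaussian bin-power features with optional injected effects.

    An effect of size ``e`` shifts the post-stimulus bins (7..12) of the
    listed components by ``-e`` standard deviations in the "on" state
    (high demand / high vigilance / on-task), mimicking stronger
    event-related desynchronization.
    """
    rng = np.random.default_rng(seed)
    trials = _trial_table(rng, n_participants, n_blocks_vs, trials_per_block,
                          n_blocks_sart, sart_trials_per_block, mw_rate)
    n = len(trials)
    d = n_components * N_BINS
    X = rng.normal(5.0, 1.0, size=(n, d))

    half = np.zeros(n, dtype=bool)
    for (p, task), grp in trials.groupby(["participant", "task"]):
        half[grp.index[grp["trial"] >= len(grp) / 2.0]] = True

    post = np.zeros(d, dtype=bool)
    for c in effect_components:
        lo = (c - 1) * N_BINS
        post[lo + N_BINS // 2: lo + N_BINS] = True

    on_demand = (trials["condition"] == "counting").to_numpy()
    on_vig = ~half
    on_att = (trials["attention"] == "on_task").to_numpy()
    shift = (demand_effect * on_demand
             + vigilance_effect * on_vig
             + attention_effect * on_att)
    X[:, post] -= shift[:, None]
    X = np.clip(X, 0.0, None)

    columns = pd.MultiIndex.from_product(
        [np.arange(1, n_components + 1), np.arange(1, N_BINS + 1)],
        names=["component", "bin"],
    )
    edges = np.round(np.arange(N_BINS + 1) * 0.1 - 0.6, 10)
    return FeatureMatrix(values=X, columns=columns, bin_edges=edges,
                         trials=trials)


@pytest.fixture()
def feature_dataset():
    return make_feature_dataset(
        seed=3, demand_effect=1.2, vigilance_effect=1.0, attention_effect=1.2,
        effect_components=(1, 2),
    )
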