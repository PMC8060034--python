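"""Shared fixtures: a small simulated subject reused across the suite.

The fixture configuration is a scaled-down MOM session (16 dots per 40-s
block, 6 blocks per condition, 16 sensors) that keeps every structural
property of the full design — colour split, target frequencies, early/late
blocks, both directions — while running in seconds.  Epochs follow the
default acquisition path: generated at 1000 Hz and downsampled to 200 Hz.
"""

import numpy as np
import pytest

import momdecode as m

MASTER_SEED = 20240901


@pytest.fixture(scope="session")
def small_task():
    return m.TaskConfig(
        dots_per_block=16,
        dots_per_colour=8,
        targets_active=4,
        targets_monitoring=1,
        n_blocks_per_condition=6,
        block_duration_s=40.0,
    )


@pytest.fixture(scope="session")
def small_sensors():
    return m.SensorModel(n_sensors=16)


@pytest.fixture(scope="session")
def behaved_schedule(small_task):
    sch = m.generate_schedule(small_task, seed=MASTER_SEED)
    return m.simulate_behaviour(sch, m.BehaviourModel(), seed=MASTER_SEED + 1)


@pytest.fixture(scope="session")
def subject_epochs(behaved_schedule, small_sensors):
    ep = m.simulate_epochs(behaved_schedule, small_sensors, seed=MASTER_SEED + 2)
    return m.downsample(ep, 200.0)


@pytest.fixture(scope="session")
def subject_binned(subject_epochs):
    return m.pool_directions(m.bin_distances(subject_epochs, samples_per_bin=3))


@pytest.fixture(scope="session")
def attended_correct_binned(subject_binned):
    lab = subject_binned.labels
    keep = (
        lab["attended"].to_numpy()
        & (lab["outcome"] != "miss").to_numpy()
        & ~lab["outcome"].str.startswith("false_alarm").to_numpy()
    )
    return subject_binned.select(keep)


@pytest.fixture(scope="session")
def subject_rdm(attended_correct_binned):
    return m.decode_distance_pairwise(
        attended_correct_binned, cv=m.CVScheme(n_folds=10, seed=MASTER_SEED + 3)
    )
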