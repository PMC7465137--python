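"""Shared fixtures: scale tables, synthetic sequences, and the pair of
restrained/unrestrained reference simulations reused across analysis and
acceptance tests (session-scoped because the MC runs dominate runtime).
"""

from __future__ import annotations

import numpy as np
import pytest

from glutencg import (
    EnergyModelParams,
    GlutenSequenceParams,
    MCConfig,
    build_system,
    charge_scheme,
    generate_gluten_like_sequence,
    kyte_doolittle,
    run_mc,
)

# gluten-like test sequence: P/Q-rich repeats, 4 cysteines (3 hydrophobic
# context, 1 hydrophilic), net charge +1 — a scaled-down prolamin
GLUTEN_TEST_PARAMS = GlutenSequenceParams(
    total_length=110,
    n_repeat_motifs=3,
    n_cys_hydrophobic=3,
    n_cys_hydrophilic=1,
    target_net_charge=1,
    n_negative=2,
    seed=11,
)


@pytest.fixture(scope="session")
def kd_table():
    return kyte_doolittle()


@pytest.fixture(scope="session")
def default_scheme():
    return charge_scheme()


@pytest.fixture(scope="session")
def gluten_seq():
    return generate_gluten_like_sequence(GLUTEN_TEST_PARAMS)


@pytest.fixture(scope="session")
def restraint_pairs(gluten_seq):
    cys = gluten_seq.cys_positions
    return [(cys[0], cys[2]), (cys[1], cys[3])]


def _run(seq, pairs, seed=7, salt=80.0, equil=400, prod=1500):
    params = EnergyModelParams(salt_mM=salt)
    system = build_system(seq, params, restraint_pairs=pairs, seed=seed)
    config = MCConfig(
        n_equilibration_sweeps=equil,
        n_production_sweeps=prod,
        thinning=10,
        seed=seed,
    )
    return run_mc(system, config)


@pytest.fixture(scope="session")
def unrestrained_run(gluten_seq):
    return _run(gluten_seq, [])


@pytest.fixture(scope="session")
def restrained_run(gluten_seq, restraint_pairs):
    return _run(gluten_seq, restraint_pairs)
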