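"""Shared simulation fixtures.

The expensive gel ensembles are session-scoped and shared between the
acceptance tests and the property suites.  Problem sizes are scaled-down
study conditions: the composition criteria run at the 128^3 box pinned by
the protocol; trend and percolation ensembles use smaller boxes at the
same heparin concentration.
"""

import numpy as np
import pytest

from bfmgel.builders import SolutionSpec, assemble_solution
from bfmgel.crosslink import crosslink_until, extent_of_reaction
from bfmgel.deswell import aggregate_and_void_stats, deswell_run, extract_bmc
from bfmgel.lattice import EnergyModel, audit
from bfmgel.netgraph import (biggest_molecule_cluster, bmc_metrics,
                             molecule_graph)


def run_gel(gamma, box, seed, p_target=0.9, equilibration_mcs=20_000,
            max_mcs=1_500_000):
    """Assemble, equilibrate and crosslink one replicate; returns
    (state, log, metrics)."""
    spec = SolutionSpec(gamma=gamma, box_edge=box,
                        equilibration_mcs=equilibration_mcs, seed=seed)
    state = assemble_solution(spec)
    ref = state.copy()
    state, log = crosslink_until(state, p_target=p_target, max_mcs=max_mcs,
                                 rng=np.random.default_rng(seed + 9_000))
    audit(state, reference=ref)
    graph = molecule_graph(state)
    bmc = biggest_molecule_cluster(graph)
    metrics = bmc_metrics(graph, bmc, state=state)
    return state, log, metrics


@pytest.fixture(scope="session")
def gel_ensemble_gamma04():
    """Five replicates of the crosslinked gel at gamma = 0.4, c = 1.5 mM,
    128^3 box, p = 0.9 (the composition-benchmark conditions; the
    full-scale protocol averages over at least 20 starting
    conformations)."""
    out = []
    for seed in range(1, 6):
        state, log, metrics = run_gel(0.4, 128, seed)
        assert log.completed, f"seed {seed} did not reach p = 0.9"
        out.append({"seed": seed, "state": state, "log": log,
                    "metrics": metrics})
    return out


@pytest.fixture(scope="session")
def trend_ensemble():
    """gamma in {0.5, 1.0, 1.5} x 5 seeds in a 64^3 box, each crosslinked
    to p = 0.9, BMC-extracted and deswollen in place."""
    energy = EnergyModel(epsilon_pp=-0.30)
    out = {}
    for gamma in (0.5, 1.0, 1.5):
        rows = []
        for seed in range(1, 6):
            state, log, metrics = run_gel(gamma, 64, 100 * seed + 7)
            assert log.completed
            bmc_state = extract_bmc(state)
            pre = aggregate_and_void_stats(bmc_state, energy,
                                           n_probes=4000, rng=seed)
            bmc_state, _ = deswell_run(
                bmc_state, n_mcs=30_000, energy=energy,
                rng=np.random.default_rng(seed + 555))
            audit(bmc_state)
            post = aggregate_and_void_stats(bmc_state, energy,
                                            n_probes=4000, rng=seed)
            rows.append({"seed": seed, "metrics": metrics, "pre": pre,
                         "post": post, "state": bmc_state})
        out[gamma] = rows
    return out


@pytest.fixture(scope="session")
def percolation_ensemble():
    """gamma in {0.3, 0.4, 1.0} x 3 seeds in an 80^3 box: BMC mass
    fractions around the connectivity threshold f_HEP = 2."""
    out = {}
    for gamma in (0.3, 0.4, 1.0):
        rows = []
        for seed in (11, 12, 13):
            _state, log, metrics = run_gel(gamma, 80, seed)
            assert log.completed
            rows.append(metrics)
        out[gamma] = rows
    return out
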