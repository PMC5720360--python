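import numpy as np
import pytest

import nmari as nm


def make_univariate(y, v, treatments=("A", "B"), prefix="s"):
    """A network in which every study compares the same two treatments."""
    blocks = [
        nm.ContrastBlock(f"{prefix}{i:02d}", treatments[0], (treatments[1],),
                         [yi], [[vi]])
        for i, (yi, vi) in enumerate(zip(y, v))
    ]
    return nm.assemble_network(blocks)


def blocks_from_net(net, rename=None):
    """Reconstruct per-study contrast blocks from an assembled network,
    optionally renaming treatments (for relabeling-invariance tests)."""
    rename = rename or (lambda t: t)
    blocks = []
    i = 0
    while i < net.n:
        study = net.row_map[i][0]
        rows = [j for j in range(net.n) if net.row_map[j][0] == study]
        baseline = net.row_map[rows[0]][2][0]
        comparators = tuple(net.row_map[j][2][1] for j in rows)
        blocks.append(
            nm.ContrastBlock(
                study,
                rename(baseline),
                tuple(rename(t) for t in comparators),
                net.Y[rows],
                net.S[np.ix_(rows, rows)],
            )
        )
        i += len(rows)
    # keep one block per study only
    seen = {}
    for b in blocks:
        seen.setdefault(b.study_id, b)
    return list(seen.values())


def simulated_net(seed, n_treatments=5, design_mix=None, vc=(0.3, 0.2), rep=0):
    """A small synthetic network with outcomes drawn from the model."""
    design_mix = design_mix or {2: 8, 3: 2}
    layout = nm.synthetic_layout(
        n_treatments=n_treatments, design_mix=design_mix, seed=seed
    )
    config = nm.SimulationConfig(layout=layout, grid=(vc,), reps=1, seed=seed)
    data = nm.simulate_dataset(config, vc, rep)
    return layout.with_outcomes(data.Y)


@pytest.fixture
def ab_ac_blocks():
    """Two AB studies plus one AC study (the smallest two-design network)."""
    return [
        nm.ContrastBlock("s1", "A", ("B",), [0.5], [[1.0]]),
        nm.ContrastBlock("s2", "A", ("B",), [1.0], [[3.0]]),
        nm.ContrastBlock("s3", "A", ("C",), [0.2], [[2.0]]),
    ]


@pytest.fixture
def ab_ac_net(ab_ac_blocks):
    return nm.assemble_network(ab_ac_blocks)


@pytest.fixture
def abc_net():
    """A single three-arm study: two correlated contrasts."""
    block = nm.ContrastBlock(
        "s1", "A", ("B", "C"), [0.4, -0.1], [[0.5, 0.2], [0.2, 0.7]]
    )
    return nm.assemble_network([block])


@pytest.fixture(scope="session")
def medium_net():
    """A two-variance-component network with data, reused across tests."""
    return simulated_net(seed=9, n_treatments=4, design_mix={2: 8, 3: 3},
                         vc=(0.3, 0.6), rep=0)


@pytest.fixture(scope="session")
def study_layout():
    """The default synthetic layout used for the Monte-Carlo studies."""
    return nm.synthetic_layout(seed=1)
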