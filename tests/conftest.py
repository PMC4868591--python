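import random

import pytest

from cladesort import SimulationSpec, TargetSpec, simulate_set, simulate_tree
from cladesort.tree_simulator import DEFAULT_TARGET_TERM


@pytest.fixture
def default_targets():
    return TargetSpec.from_string("Rhodophyta,Viridiplantae,Stramenopiles")


@pytest.fixture
def sim_targets():
    return TargetSpec((DEFAULT_TARGET_TERM,))


@pytest.fixture
def rng():
    return random.Random(20160512)


@pytest.fixture(scope="session")
def simulated_trees():
    """Ten independent simulated trees at assorted sizes."""
    out = []
    for i, x in enumerate([20, 40, 40, 60, 60, 80, 100, 100, 120, 140]):
        out.append(simulate_tree(SimulationSpec(x=x, seed=100 + i)))
    return out


@pytest.fixture
def mixed_dir(tmp_path):
    """Directory of 10 positive + 5 negative-control tree files."""
    in_dir = tmp_path / "trees"
    simulate_set(
        SimulationSpec(x=40, n=10, seed=1), in_dir, replicate_topology=False
    )
    neg_dir = tmp_path / "neg"
    simulate_set(
        SimulationSpec(x=40, n=5, seed=2, negative_control=True),
        neg_dir,
        replicate_topology=False,
    )
    for i, p in enumerate(sorted(neg_dir.glob("*.tre"))):
        (in_dir / f"neg_{i + 1:02d}.tre").write_text(p.read_text())
    (in_dir / "manifest.tsv").unlink()
    return in_dir
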