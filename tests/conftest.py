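import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from discordia.synthetic_data import SimulationConfig, generate_study
from discordia.treeio import parse_newick


@pytest.fixture
def quartet_conflict():
    """Maximally conflicting pair of 4-tip trees."""
    return (parse_newick("((a,b),(c,d));"),
            parse_newick("((a,c),(b,d));"))


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused across modules (30 tips, 40 loci)."""
    cfg = SimulationConfig(
        n_tips=30,
        clade_blocks={"cladeA": 10, "cladeB": 8, "cladeC": 6, "outgroup": 6},
        n_loci=40,
        depth_cu=8.0,
        clade_crown_cu=2.0,
        error_nni_rate=1.0,
        seed=11,
    )
    return generate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_tree_newick(n_tips: int, rng: np.random.Generator,
                       with_lengths: bool = True,
                       with_support: bool = False) -> str:
    """Random binary topology via sequential joins (test helper)."""
    parts = [f"t{i}" for i in range(n_tips)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), 2, replace=False))
        a, b = parts[i], parts[j]
        sup = f"{rng.uniform():.3f}" if with_support else ""
        la = f":{rng.uniform(0.01, 2):.4f}" if with_lengths else ""
        lb = f":{rng.uniform(0.01, 2):.4f}" if with_lengths else ""
        merged = f"({a}{la},{b}{lb}){sup}"
        parts[i] = merged
        del parts[j]
    # strip the support that would sit on the root
    root = parts[0]
    if with_support:
        k = root.rfind(")")
        root = root[:k + 1]
    return root + ";"
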