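import itertools

import numpy as np
import pytest

from dili_netminer.association import (
    AssociationDB,
    InteractionRecord,
    PathwayHierarchy,
    TargetKind,
    build_association_db,
)
from dili_netminer.refinement import ExperimentDesign
from dili_netminer.simulate import SimulationConfig


def brute_force_itemsets(db: AssociationDB, min_support: float, max_len: int = 3):
    """Exhaustive subset enumeration oracle for frequent-itemset mining."""
    transactions = list(db.transactions.values())
    n = len(transactions)
    if n == 0:
        return {}
    universe = sorted(set().union(*transactions)) if transactions else []
    out = {}
    for k in range(1, max_len + 1):
        for combo in itertools.combinations(universe, k):
            items = frozenset(combo)
            count = sum(1 for t in transactions if items <= t)
            if count >= min_support * n:
                out[items] = count / n
    return out


def random_association_db(rng: np.random.Generator, max_items: int = 12, max_transactions: int = 20):
    """A random transaction DB over a small item universe."""
    n_items = int(rng.integers(2, max_items + 1))
    n_trans = int(rng.integers(1, max_transactions + 1))
    universe = [f"gene:I{i}" for i in range(n_items - 1)] + ["disease:D"]
    transactions = {}
    for c in range(n_trans):
        size = int(rng.integers(1, n_items + 1))
        picked = rng.choice(universe, size=size, replace=False)
        transactions[f"c{c}"] = frozenset(picked.tolist())
    return AssociationDB(transactions=transactions)


@pytest.fixture
def four_transaction_db() -> AssociationDB:
    """c1:{g1,g2,D}, c2:{g1,D}, c3:{g2}, c4:{g1,g2,D} — the worked mining
    instance used across association tests."""
    records = [
        InteractionRecord("c1", "g1", TargetKind.GENE),
        InteractionRecord("c1", "g2", TargetKind.GENE),
        InteractionRecord("c1", "D", TargetKind.DISEASE),
        InteractionRecord("c2", "g1", TargetKind.GENE),
        InteractionRecord("c2", "D", TargetKind.DISEASE),
        InteractionRecord("c3", "g2", TargetKind.GENE),
        InteractionRecord("c4", "g1", TargetKind.GENE),
        InteractionRecord("c4", "g2", TargetKind.GENE),
        InteractionRecord("c4", "D", TargetKind.DISEASE),
    ]
    return build_association_db(records, PathwayHierarchy())


@pytest.fixture
def fast_sim_config() -> SimulationConfig:
    """Reduced design (2 time points, 1 dose, 60 genes) for quick expression
    round trips; planted structure unchanged."""
    return SimulationConfig(
        n_genes=60,
        network_size=40,
        design=ExperimentDesign(
            time_points=("3 h", "1 day"), dose_levels=("high",), replicates_per_cell=3
        ),
    )
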