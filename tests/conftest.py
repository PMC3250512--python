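import numpy as np
import pandas as pd
import pytest

import ventbiogeo as vb


@pytest.fixture
def esr():
    return vb.esr_fixture()


@pytest.fixture
def small_binary_matrix():
    return vb.CommunityMatrix(
        site_ids=["s1", "s2", "s3"],
        species_ids=["a", "b", "c", "d", "e"],
        occurrences=np.array(
            [
                [1, 0, 1, 0, 1],
                [0, 1, 0, 1, 0],
                [1, 1, 1, 0, 0],
            ],
            dtype=float,
        ),
    )


@pytest.fixture
def strong_meta():
    """3 provinces, strong signal — used by several recovery tests."""
    return vb.generate_metacommunity(
        vb.MetacommunityParams(
            n_provinces=3,
            sites_per_province=10,
            endemics_per_province=15,
            cosmopolitan_species=5,
            endemicity=0.9,
            detection_prob=0.9,
        ),
        seed=11,
    )


def brute_force_best_split(Y, X, members, min_node_size):
    """Independent exhaustive split search (plain loops, direct SS formula).

    Mirrors the production tie rule: lower column index first, then smaller
    threshold.  Returns (gain, col, threshold) or None.
    """
    members = np.asarray(members)
    n = len(members)
    Ym = Y[members]

    def ss(rows):
        if len(rows) == 0:
            return 0.0
        c = rows.mean(axis=0)
        return float(((rows - c) ** 2).sum())

    parent = ss(Ym)
    best = None
    for j in range(X.shape[1]):
        x = X[members, j]
        values = np.unique(x)
        for lo, hi in zip(values[:-1], values[1:]):
            thr = (lo + hi) / 2.0
            left = Ym[x <= thr]
            right = Ym[x > thr]
            if len(left) < min_node_size or len(right) < min_node_size:
                continue
            gain = parent - ss(left) - ss(right)
            if best is None or gain > best[0] + 1e-12:
                best = (gain, j, thr)
    if best is None or best[0] <= 1e-12:
        return None
    return best


def assert_tree_splits_optimal(root, Y, X, min_node_size=2):
    """Walk a grown tree and compare every split against the brute-force oracle."""
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            continue
        expected = brute_force_best_split(Y, X, node.members, min_node_size)
        assert expected is not None, "tree split where the oracle finds none"
        gain = node.within_ss - node.left.within_ss - node.right.within_ss
        assert gain == pytest.approx(expected[0], rel=1e-9, abs=1e-12)
        assert node.split_col == expected[1]
        assert node.split_threshold == pytest.approx(expected[2], rel=1e-12)
        stack.extend([node.left, node.right])


@pytest.fixture
def random_instance_factory():
    def make(seed, max_sites=8, max_constraints=2, max_species=6):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, max_sites + 1))
        p = int(rng.integers(1, max_constraints + 1))
        s = int(rng.integers(2, max_species + 1))
        occ = rng.integers(0, 2, size=(n, s)).astype(float)
        occ[occ.sum(axis=1) == 0, 0] = 1  # avoid all-zero rows
        matrix = vb.CommunityMatrix(
            site_ids=[f"s{i}" for i in range(n)],
            species_ids=[f"sp{j}" for j in range(s)],
            occurrences=occ,
        )
        X = pd.DataFrame(
            rng.normal(size=(n, p)),
            index=matrix.site_ids,
            columns=[f"v{k}" for k in range(p)],
        )
        return matrix, X

    return make
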