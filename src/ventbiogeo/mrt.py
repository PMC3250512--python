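"""Geographically constrained multivariate regression trees.

The pipeline is: Hellinger-transform the community matrix, grow a
binary tree on the coordinate constraints minimising within-node sums of
squares of the transformed composition, prune it by weakest-link
cost-complexity, and choose a tree size by repeated v-fold
cross-validation.  Leaves of the selected subtree are the biogeographic
provinces.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityMatrix

__all__ = [
    "HellingerMatrix",
    "MRTreeNode",
    "TreeControl",
    "PruningSequence",
    "CVResult",
    "MultiCVSummary",
    "ConstantResponseError",
    "hellinger",
    "grow_tree",
    "prune",
    "cross_validate",
    "multi_cv",
    "select_size",
    "assign_provinces",
    "encoding_sensitivity_scan",
]


class ConstantResponseError(ValueError):
    """Response has zero total sum of squares; relative errors are undefined."""


# ---------------------------------------------------------------------------
# Hellinger transformation


@dataclass
class HellingerMatrix:
    """Row-wise sqrt(share) transform of a community matrix.

    Each entry is ``sqrt(y_ij / row_total_i)``; rows with a positive total
    therefore have unit sum of squares.  All-zero rows stay all-zero and
    are recorded in ``zero_rows``.
    """

    site_ids: list[str]
    species_ids: list[str]
    values: np.ndarray
    zero_rows: list[str] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.species_ids)


def hellinger(matrix: CommunityMatrix) -> HellingerMatrix:
    """Hellinger-transform a (nonnegative) community matrix."""
    occ = matrix.occurrences
    if (occ < 0).any():
        raise ValueError("negative entries cannot be Hellinger-transformed")
    totals = occ.sum(axis=1)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    values = np.sqrt(occ / safe[:, None])
    zero_rows = [matrix.site_ids[i] for i in np.flatnonzero(zero)]
    if zero_rows:
        warnings.warn(
            f"all-zero rows left untransformed: {', '.join(zero_rows)}",
            UserWarning,
            stacklevel=2,
        )
    return HellingerMatrix(
        site_ids=list(matrix.site_ids),
        species_ids=list(matrix.species_ids),
        values=values,
        zero_rows=zero_rows,
    )


# ---------------------------------------------------------------------------
# Tree growth


@dataclass
class TreeControl:
    """Growth limits: minimum sites per leaf and maximum number of leaves."""

    min_node_size: int = 2
    max_leaves: int | None = None  # None -> number of sites


@dataclass
class MRTreeNode:
    node_id: int
    members: np.ndarray  # row indices into the response matrix
    centroid: np.ndarray
    within_ss: float
    split_var: str | None = None
    split_col: int | None = None
    split_threshold: float | None = None
    left: "MRTreeNode | None" = None
    right: "MRTreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self) -> list["MRTreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def n_leaves(self) -> int:
        return len(self.leaves())

    def leaf_within_ss(self) -> float:
        return sum(leaf.within_ss for leaf in self.leaves())

    def predict_leaf(self, x: np.ndarray) -> "MRTreeNode":
        """Drop a constraint-vector down to its leaf (left if value <= threshold)."""
        node = self
        while not node.is_leaf:
            node = node.left if x[node.split_col] <= node.split_threshold else node.right
        return node

    def copy(self) -> "MRTreeNode":
        clone = MRTreeNode(
            node_id=self.node_id,
            members=self.members,
            centroid=self.centroid,
            within_ss=self.within_ss,
            split_var=self.split_var,
            split_col=self.split_col,
            split_threshold=self.split_threshold,
        )
        if not self.is_leaf:
            clone.left = self.left.copy()
            clone.right = self.right.copy()
        return clone

    def to_dict(self, site_ids: list[str] | None = None) -> dict:
        d: dict = {
            "node_id": self.node_id,
            "n_sites": int(len(self.members)),
            "within_ss": float(self.within_ss),
        }
        if site_ids is not None:
            d["sites"] = [site_ids[i] for i in self.members]
        if not self.is_leaf:
            d["split"] = {
                "variable": self.split_var,
                "threshold": float(self.split_threshold),
            }
            d["left"] = self.left.to_dict(site_ids)
            d["right"] = self.right.to_dict(site_ids)
        return d


def _node_stats(Y: np.ndarray, members: np.ndarray) -> tuple[np.ndarray, float]:
    rows = Y[members]
    centroid = rows.mean(axis=0)
    within = float(((rows - centroid) ** 2).sum())
    return centroid, within


def _best_split(
    Y: np.ndarray, X: np.ndarray, members: np.ndarray, min_node_size: int
) -> tuple[float, int, float] | None:
    """Exhaustive search over variables and midpoint thresholds.

    Returns (gain, column, threshold) for the split maximising the drop in
    within-node SS, or None if no admissible split exists.  Ties are broken
    by lower column index, then by smaller threshold.
    """
    n = len(members)
    if n < 2 * min_node_size:
        return None
    Ym = Y[members]
    total = Ym.sum(axis=0)
    sq_total = float(total @ total)
    best: tuple[float, int, float] | None = None
    for j in range(X.shape[1]):
        x = X[members, j]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        S = np.cumsum(Ym[order], axis=0)  # prefix sums of response rows
        k = np.arange(1, n)
        left_sq = (S[:-1] ** 2).sum(axis=1)
        right = total[None, :] - S[:-1]
        right_sq = (right**2).sum(axis=1)
        gains = left_sq / k + right_sq / (n - k) - sq_total / n
        valid = (
            (xs[1:] > xs[:-1]) & (k >= min_node_size) & ((n - k) >= min_node_size)
        )
        if not valid.any():
            continue
        idx = np.flatnonzero(valid)
        g = gains[idx]
        pos = idx[int(np.argmax(g))]  # argmax keeps first max -> smaller threshold
        gain = float(gains[pos])
        if best is None or gain > best[0] + 1e-12:
            thr = float((xs[pos] + xs[pos + 1]) / 2.0)
            best = (gain, j, thr)
    if best is None or best[0] <= 1e-12:
        return None
    return best


def _align(response: HellingerMatrix, constraints: pd.DataFrame) -> np.ndarray:
    if list(constraints.index) != list(response.site_ids):
        if set(constraints.index) == set(response.site_ids):
            constraints = constraints.loc[response.site_ids]
        else:
            raise ValueError("response and constraint tables list different sites")
    return constraints.to_numpy(dtype=float)


def grow_tree(
    response: HellingerMatrix,
    constraints: pd.DataFrame,
    control: TreeControl | None = None,
) -> MRTreeNode:
    """Grow the constrained tree by best-first greedy splitting.

    At every node the (variable, midpoint threshold) pair maximising the
    reduction in within-node SS of the transformed composition is taken;
    growth stops at ``min_node_size``, ``max_leaves``, or when no split
    improves the fit.
    """
    control = control or TreeControl()
    if control.min_node_size < 1:
        raise ValueError("min_node_size must be >= 1")
    Y = response.values
    X = _align(response, constraints)
    n = Y.shape[0]
    if n == 0:
        raise ValueError("empty response matrix")
    max_leaves = control.max_leaves or n
    var_names = list(constraints.columns)

    root_members = np.arange(n)
    centroid, within = _node_stats(Y, root_members)
    root = MRTreeNode(1, root_members, centroid, within)

    if n > 1 and all(len(np.unique(X[:, j])) == 1 for j in range(X.shape[1])):
        if within > 0:
            warnings.warn(
                "all constraint values identical; returning a single leaf",
                UserWarning,
                stacklevel=2,
            )
        return root

    # best-first expansion: largest SS reduction first, honouring max_leaves
    heap: list[tuple[float, int, MRTreeNode, tuple[float, int, float]]] = []
    counter = 0

    def push(node: MRTreeNode) -> None:
        nonlocal counter
        found = _best_split(Y, X, node.members, control.min_node_size)
        if found is not None:
            heapq.heappush(heap, (-found[0], counter, node, found))
            counter += 1

    push(root)
    leaves = 1
    while heap and leaves < max_leaves:
        _, _, node, (gain, col, thr) = heapq.heappop(heap)
        x = X[node.members, col]
        left_members = node.members[x <= thr]
        right_members = node.members[x > thr]
        lc, lw = _node_stats(Y, left_members)
        rc, rw = _node_stats(Y, right_members)
        node.split_var = var_names[col]
        node.split_col = col
        node.split_threshold = thr
        node.left = MRTreeNode(node.node_id * 2, left_members, lc, lw)
        node.right = MRTreeNode(node.node_id * 2 + 1, right_members, rc, rw)
        leaves += 1
        push(node.left)
        push(node.right)
    return root


# ---------------------------------------------------------------------------
# Cost-complexity pruning


@dataclass
class PrunedTree:
    root: MRTreeNode
    alpha: float
    n_leaves: int
    rel_error: float


@dataclass
class PruningSequence:
    """Nested subtrees from the full tree down to the root-only tree.

    ``entries`` are ordered by strictly increasing complexity ``alpha``
    (first entry: full tree at alpha 0) and strictly decreasing leaf
    count (last entry: root only, relative error 1).
    """

    entries: list[PrunedTree]
    root_ss: float

    @property
    def sizes(self) -> list[int]:
        return [e.n_leaves for e in self.entries]

    def tree_for_alpha(self, alpha: float) -> PrunedTree:
        """Subtree optimal for a given complexity penalty."""
        chosen = self.entries[0]
        for entry in self.entries:
            if entry.alpha <= alpha:
                chosen = entry
            else:
                break
        return chosen

    def tree_for_size(self, size: int) -> PrunedTree:
        for entry in self.entries:
            if entry.n_leaves == size:
                return entry
        raise ValueError(
            f"no subtree with {size} leaves; achievable sizes: {self.sizes}"
        )


def _weakest_links(root: MRTreeNode) -> list[tuple[float, MRTreeNode]]:
    out: list[tuple[float, MRTreeNode]] = []

    def visit(node: MRTreeNode) -> None:
        if node.is_leaf:
            return
        g = (node.within_ss - node.leaf_within_ss()) / (node.n_leaves() - 1)
        out.append((g, node))
        visit(node.left)
        visit(node.right)

    visit(root)
    return out


def prune(root: MRTreeNode) -> PruningSequence:
    """Weakest-link cost-complexity pruning.

    Repeatedly collapses every branch attaining the smallest
    ``alpha = (SS(node) - sum leaf SS) / (leaves - 1)`` until only the root
    remains.  Relative error is total leaf SS over root SS (1 if the root
    SS is zero).
    """
    root_ss = root.within_ss
    current = root.copy()

    def rel(tree: MRTreeNode) -> float:
        if root_ss == 0:
            return 1.0
        return tree.leaf_within_ss() / root_ss

    entries = [PrunedTree(current.copy(), 0.0, current.n_leaves(), rel(current))]
    while not current.is_leaf:
        links = _weakest_links(current)
        alpha = min(g for g, _ in links)
        for g, node in links:
            if g <= alpha + 1e-15 * max(1.0, abs(alpha)):
                node.left = None
                node.right = None
                node.split_var = None
                node.split_col = None
                node.split_threshold = None
        entries.append(
            PrunedTree(current.copy(), max(alpha, 0.0), current.n_leaves(), rel(current))
        )
    return PruningSequence(entries=entries, root_ss=root_ss)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    sizes: list[int]  # descending, aligned with the master pruning sequence
    xerror: np.ndarray
    se: np.ndarray


def _geometric_betas(alphas: list[float]) -> list[float]:
    betas = []
    for k in range(len(alphas) - 1):
        betas.append(float(np.sqrt(alphas[k] * alphas[k + 1])))
    betas.append(np.inf)
    return betas


def _cv_with_rng(
    response: HellingerMatrix,
    constraints: pd.DataFrame,
    folds: int,
    rng: np.random.Generator,
    control: TreeControl,
    master: PruningSequence,
) -> CVResult:
    Y = response.values
    X = _align(response, constraints)
    n = Y.shape[0]
    if not 2 <= folds <= n:
        raise ValueError(f"folds must be in [2, {n}], got {folds}")
    root_ss = master.root_ss
    if root_ss == 0:
        raise ConstantResponseError(
            "root within-SS is zero: cross-validated relative error undefined"
        )
    betas = _geometric_betas([e.alpha for e in master.entries])
    m = len(betas)
    perm = rng.permutation(n)
    assignments = np.array_split(perm, folds)

    contrib = np.zeros((n, m))  # per held-out site, per master size
    for test_idx in assignments:
        if len(test_idx) == 0:
            continue
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        train_idx = np.flatnonzero(mask)
        if len(train_idx) == 0:
            raise ValueError("a fold has no training sites")
        sub = HellingerMatrix(
            site_ids=[response.site_ids[i] for i in train_idx],
            species_ids=response.species_ids,
            values=Y[train_idx],
        )
        sub_constraints = constraints.iloc[train_idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            fold_tree = grow_tree(sub, sub_constraints, control)
        fold_seq = prune(fold_tree)
        for k, beta in enumerate(betas):
            subtree = fold_seq.tree_for_alpha(beta).root
            for i in test_idx:
                leaf = subtree.predict_leaf(X[i])
                err = float(((Y[i] - leaf.centroid) ** 2).sum())
                contrib[i, k] = err
    u = contrib * n / root_ss
    xerror = u.mean(axis=0)
    se = u.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(m)
    return CVResult(sizes=master.sizes, xerror=xerror, se=se)


def cross_validate(
    response: HellingerMatrix,
    constraints: pd.DataFrame,
    folds: int = 10,
    seed: int | np.random.SeedSequence = 0,
    control: TreeControl | None = None,
) -> CVResult:
    """v-fold cross-validated relative error for every pruned tree size.

    Held-out sites are dropped down each training subtree by their
    constraint values and scored against the reached leaf's centroid; the
    pooled error is divided by the full-data root SS.  Sizes are aligned
    across folds with geometric means of consecutive alpha values.
    """
    control = control or TreeControl()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        master = prune(grow_tree(response, constraints, control))
    rng = np.random.default_rng(seed)
    return _cv_with_rng(response, constraints, folds, rng, control, master)


@dataclass
class MultiCVSummary:
    """Aggregate of repeated cross-validations with re-randomised folds."""

    replicates: int
    sizes: list[int]  # descending
    xerror_mean: np.ndarray
    xerror_se: np.ndarray
    optimal_sizes: list[int]  # per-replicate smallest minimiser of xerror
    frequencies: dict[int, int]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"size": self.sizes, "xerror": self.xerror_mean, "se": self.xerror_se}
        )


def multi_cv(
    response: HellingerMatrix,
    constraints: pd.DataFrame,
    replicates: int = 1000,
    folds: int = 10,
    seed: int = 0,
    control: TreeControl | None = None,
) -> MultiCVSummary:
    """Repeat v-fold CV and tabulate how often each tree size is optimal.

    Replicate r draws its folds from a child of ``SeedSequence(seed)``; the
    per-replicate optimal size is the smallest size attaining the minimum
    cross-validated error.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    control = control or TreeControl()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        master = prune(grow_tree(response, constraints, control))
    children = np.random.SeedSequence(seed).spawn(replicates)
    xerrors = []
    ses = []
    optima = []
    for child in children:
        res = _cv_with_rng(
            response, constraints, folds, np.random.default_rng(child), control, master
        )
        xerrors.append(res.xerror)
        ses.append(res.se)
        best = res.xerror.min()
        candidates = [s for s, x in zip(res.sizes, res.xerror) if x == best]
        optima.append(min(candidates))
    freq: dict[int, int] = {}
    for s in optima:
        freq[s] = freq.get(s, 0) + 1
    return MultiCVSummary(
        replicates=replicates,
        sizes=master.sizes,
        xerror_mean=np.mean(xerrors, axis=0),
        xerror_se=np.mean(ses, axis=0),
        optimal_sizes=optima,
        frequencies=dict(sorted(freq.items())),
        seed=seed,
    )


def select_size(summary: MultiCVSummary, rule: str = "most_frequent_min") -> int:
    """Pick a tree size from a multi-CV summary.

    ``most_frequent_min``: modal per-replicate optimal size (ties -> the
    smaller size).  ``one_se``: smallest size whose mean error is within
    one standard error of the minimum mean error.
    """
    if rule == "most_frequent_min":
        top = max(summary.frequencies.values())
        return min(s for s, c in summary.frequencies.items() if c == top)
    if rule == "one_se":
        i_min = int(np.argmin(summary.xerror_mean))
        cutoff = summary.xerror_mean[i_min] + summary.xerror_se[i_min]
        ok = [s for s, x in zip(summary.sizes, summary.xerror_mean) if x <= cutoff]
        return min(ok)
    raise ValueError(f"unknown selection rule {rule!r}")


def assign_provinces(
    sequence: PruningSequence, size: int, site_ids: list[str]
) -> dict[str, int]:
    """Label every site by leaf membership of the subtree with that size.

    Labels are 1-based leaf indices in left-to-right tree order.
    """
    entry = sequence.tree_for_size(size)
    assignment: dict[str, int] = {}
    for label, leaf in enumerate(entry.root.leaves(), start=1):
        for i in leaf.members:
            assignment[site_ids[i]] = label
    if len(assignment) != len(site_ids):
        raise RuntimeError("leaves do not partition the site set")
    return assignment


# ---------------------------------------------------------------------------
# Longitude-encoding sensitivity


@dataclass
class SchemeResult:
    scheme: str
    summary: MultiCVSummary
    selected_size: dict[str, int]  # per selection rule
    assignment: dict[str, int]
    sequence: PruningSequence


def encoding_sensitivity_scan(
    matrix: CommunityMatrix,
    sites,
    schemes,
    replicates: int = 100,
    folds: int = 10,
    seed: int = 0,
    control: TreeControl | None = None,
    rule: str = "most_frequent_min",
) -> dict[str, SchemeResult]:
    """Run the full multi-CV analysis once per longitude encoding scheme."""
    from .encoding import build_constraints, get_scheme

    if not schemes:
        raise ValueError("need at least one encoding scheme")
    control = control or TreeControl()
    response = hellinger(matrix)
    out: dict[str, SchemeResult] = {}
    for scheme in schemes:
        scheme = get_scheme(scheme)
        constraints = build_constraints(sites, scheme)
        summary = multi_cv(response, constraints, replicates, folds, seed, control)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            sequence = prune(grow_tree(response, constraints, control))
        selected = {
            r: select_size(summary, r) for r in ("most_frequent_min", "one_se")
        }
        assignment = assign_provinces(sequence, selected[rule], response.site_ids)
        out[scheme.name] = SchemeResult(
            scheme=scheme.name,
            summary=summary,
            selected_size=selected,
            assignment=assignment,
            sequence=sequence,
        )
    return out
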