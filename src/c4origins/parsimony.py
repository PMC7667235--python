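"""Small-parsimony counting of C3/C4 origin scenarios on a fixed topology.

Given a tree and binary tip states (0 = C3, 1 = C4), the minimum number of
state changes over all internal labelings is computed by dynamic programming
(Sankoff's algorithm; with unit costs this equals Fitch parsimony and
handles polytomies). A constrained variant finds the cheapest labeling whose
number of 0->1 (gain) edges equals a prescribed value, which lets competing
origin scenarios — e.g. two independent gains versus one gain plus two
reversions — be costed against each other directly.

Gains and losses are counted on a rooted tree: the raw change count is
invariant to rooting, but the gain/loss decomposition is not, so unrooted
input should be rooted on a declared outgroup first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io_formats import read_newick

__all__ = [
    "ScenarioResult",
    "fitch_min_changes",
    "constrained_min_changes",
    "sankoff_min_cost",
    "enumerate_labelings",
]

C3_STATE, C4_STATE = 0, 1
_INF = float("inf")


@dataclass
class ScenarioResult:
    min_changes: int
    n_gains: int
    n_losses: int
    labeling: dict  # node (leaf label or internal index) -> state
    feasible: bool = True
    root_tie: bool = False  # root state was a tie, broken toward C3

    def __post_init__(self) -> None:
        if self.feasible and self.min_changes != self.n_gains + self.n_losses:
            raise ValueError("witness labeling inconsistent with change count")


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return read_newick(tree)


def _check_states(tree: dendropy.Tree, states: dict) -> None:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in states:
            raise KeyError(f"no state for leaf {leaf.taxon.label!r}")


def _node_key(node: dendropy.Node, index: dict) -> object:
    if node.is_leaf():
        return node.taxon.label
    return index[id(node)]


def _index_internal(tree: dendropy.Tree) -> dict:
    idx, n = {}, 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            idx[id(node)] = f"node{n}"
            n += 1
    return idx


def sankoff_min_cost(tree, states: dict, cost_matrix) -> float:
    """Minimum total substitution cost under an arbitrary state-change cost
    matrix (rows: parent state, columns: child state). With unit off-diagonal
    costs this equals the Fitch change count."""
    t = _as_tree(tree)
    _check_states(t, states)
    cost = np.asarray(cost_matrix, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError("cost matrix must be square")
    if (cost < 0).any():
        raise ValueError("cost matrix must be non-negative")
    k = cost.shape[0]
    table: dict[int, np.ndarray] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            v = np.full(k, _INF)
            v[states[node.taxon.label]] = 0.0
        else:
            v = np.zeros(k)
            for child in node.child_nodes():
                cv = table[id(child)]
                v += np.min(cost + cv[None, :], axis=1)
        table[id(node)] = v
    return float(table[id(t.seed_node)].min())


def fitch_min_changes(tree, states: dict) -> ScenarioResult:
    """Minimum number of binary state changes, with one optimal labeling.

    Runs unit-cost Sankoff (valid on multifurcations), then backtracks a
    witness labeling: the root takes the cheaper state (tie broken toward
    C3 and flagged) and each child the cheapest state given its parent,
    preferring no change on ties. Gains are 0->1 edges, losses 1->0.
    """
    t = _as_tree(tree)
    _check_states(t, states)
    unit = np.array([[0.0, 1.0], [1.0, 0.0]])
    table: dict[int, np.ndarray] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            v = np.full(2, _INF)
            v[states[node.taxon.label]] = 0.0
        else:
            v = np.zeros(2)
            for child in node.child_nodes():
                cv = table[id(child)]
                v += np.min(unit + cv[None, :], axis=1)
        table[id(node)] = v
    root = t.seed_node
    rv = table[id(root)]
    root_tie = bool(rv[0] == rv[1])
    root_state = int(np.argmin(rv))  # argmin prefers index 0 (C3) on ties
    index = _index_internal(t)
    labeling: dict = {}
    gains = losses = 0
    stack = [(root, root_state)]
    while stack:
        node, s = stack.pop()
        labeling[_node_key(node, index)] = s
        for child in node.child_nodes():
            cv = table[id(child)]
            options = unit[s] + cv
            best = options.min()
            # prefer keeping the parent state on ties
            cs = s if options[s] == best else int(np.argmin(options))
            if cs != s:
                if s == C3_STATE:
                    gains += 1
                else:
                    losses += 1
            stack.append((child, cs))
    return ScenarioResult(
        min_changes=int(rv.min()),
        n_gains=gains,
        n_losses=losses,
        labeling=labeling,
        root_tie=root_tie,
    )


def constrained_min_changes(tree, states: dict, n_gains: int,
                            root_state: int | None = C3_STATE,
                            exhaustive: bool = False) -> ScenarioResult:
    """Cheapest labeling whose number of gain (0->1) edges equals ``n_gains``.

    Origin-scenario semantics: the ancestral state at the root is C3 by
    default (the clade is rooted by C3 outgroups), so every C4 tip must be
    reached through a counted gain; pass ``root_state=None`` to leave the
    root free, or ``C4_STATE`` to cost loss-only scenarios.

    Default is a dynamic program over (node, state, gains-in-subtree);
    ``exhaustive=True`` enumerates every internal labeling instead (only
    allowed for trees with at most 20 internal nodes). Returns an
    infeasibility result when no labeling has exactly ``n_gains`` gains.
    """
    if n_gains < 0:
        raise ValueError("n_gains must be >= 0")
    t = _as_tree(tree)
    _check_states(t, states)
    if exhaustive:
        return _constrained_exhaustive(t, states, n_gains, root_state)
    G = n_gains
    # table[node id][state] = array over g of min changes in subtree
    table: dict[int, np.ndarray] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            v = np.full((2, G + 1), _INF)
            v[states[node.taxon.label], 0] = 0.0
        else:
            v = np.zeros((2, G + 1))
            v[:, 1:] = _INF  # start: zero gains used, zero cost
            for child in node.child_nodes():
                cv = table[id(child)]
                nv = np.full((2, G + 1), _INF)
                for s in (0, 1):
                    for cs in (0, 1):
                        edge_cost = 0.0 if s == cs else 1.0
                        edge_gain = 1 if (s == C3_STATE and cs == C4_STATE) else 0
                        child_col = cv[cs]
                        for g_child in range(G + 1 - edge_gain):
                            if child_col[g_child] == _INF:
                                continue
                            add = child_col[g_child] + edge_cost
                            upper = G + 1 - g_child - edge_gain
                            seg = v[s, :upper] + add
                            tgt = nv[s, g_child + edge_gain :]
                            np.minimum(tgt, seg, out=tgt)
                v = nv
        table[id(node)] = v
    root = t.seed_node
    rv = table[id(root)][:, G].copy()
    if root_state is not None:
        rv[1 - root_state] = _INF
    if not np.isfinite(rv.min()):
        return ScenarioResult(0, 0, 0, {}, feasible=False)
    root_tie = bool(rv[0] == rv[1])
    chosen_root = int(np.argmin(rv))
    # backtrack
    index = _index_internal(t)
    labeling: dict = {}
    gains = losses = 0

    def assign(node, s, g):
        nonlocal gains, losses
        labeling[_node_key(node, index)] = s
        children = node.child_nodes()
        if not children:
            return
        # re-derive per-child allocations greedily by checking feasibility
        remaining = g
        budget = table[id(node)][s, g]
        for i, child in enumerate(children):
            cv = table[id(child)]
            rest = children[i + 1 :]
            done = False
            for cs in (s, 1 - s):  # prefer no change
                edge_cost = 0.0 if s == cs else 1.0
                edge_gain = 1 if (s == C3_STATE and cs == C4_STATE) else 0
                for g_child in range(remaining - edge_gain + 1):
                    if cv[cs, g_child] == _INF:
                        continue
                    rem_g = remaining - edge_gain - g_child
                    rem_cost = budget - edge_cost - cv[cs, g_child]
                    if rem_cost < -1e-9:
                        continue
                    if _rest_feasible(rest, s, rem_g, rem_cost, table):
                        if cs != s:
                            if s == C3_STATE:
                                gains += 1
                            else:
                                losses += 1
                        assign(child, cs, g_child)
                        remaining = rem_g
                        budget = rem_cost
                        done = True
                        break
                if done:
                    break
            if not done:  # pragma: no cover - DP guarantees a witness exists
                raise RuntimeError("backtracking failed")

    def _rest_feasible(rest, s, g_budget, cost_budget, table):
        if not rest:
            return g_budget == 0 and abs(cost_budget) < 1e-9
        # min-cost completion for each possible gain split among the rest
        v = np.zeros(g_budget + 1)
        v[1:] = _INF
        for child in rest:
            cv = table[id(child)]
            nv = np.full(g_budget + 1, _INF)
            for cs in (0, 1):
                edge_cost = 0.0 if s == cs else 1.0
                edge_gain = 1 if (s == C3_STATE and cs == C4_STATE) else 0
                for g_child in range(g_budget + 1 - edge_gain):
                    if cv[cs, g_child] == _INF:
                        continue
                    add = cv[cs, g_child] + edge_cost
                    upper = g_budget + 1 - g_child - edge_gain
                    seg = v[:upper] + add
                    tgt = nv[g_child + edge_gain :]
                    np.minimum(tgt, seg, out=tgt)
            v = nv
        return np.isfinite(v[g_budget]) and v[g_budget] <= cost_budget + 1e-9

    assign(root, chosen_root, G)
    return ScenarioResult(
        min_changes=int(rv[chosen_root]),
        n_gains=gains,
        n_losses=losses,
        labeling=labeling,
        root_tie=root_tie,
    )


def enumerate_labelings(tree, states: dict):
    """Yield (total_changes, n_gains, labeling) for every internal labeling.

    Exhaustive over 2^(number of internal nodes) assignments; intended for
    small trees (verification and the exhaustive constrained mode).
    """
    t = _as_tree(tree)
    _check_states(t, states)
    internal = [n for n in t.preorder_node_iter() if not n.is_leaf()]
    if len(internal) > 20:
        raise ValueError("exhaustive enumeration limited to <= 20 internal nodes")
    index = _index_internal(t)
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        label = {id(n): s for n, s in zip(internal, assignment)}
        changes = gains = 0
        for node in t.preorder_node_iter():
            if node.parent_node is None:
                continue
            ps = label.get(id(node.parent_node))
            cs = label[id(node)] if not node.is_leaf() else states[node.taxon.label]
            if ps != cs:
                changes += 1
                if ps == C3_STATE:
                    gains += 1
        labeling = {_node_key(n, index): s for n, s in zip(internal, assignment)}
        yield changes, gains, labeling


def _constrained_exhaustive(t: dendropy.Tree, states: dict, n_gains: int,
                            root_state: int | None) -> ScenarioResult:
    index = _index_internal(t)
    root_key = _node_key(t.seed_node, index)
    best = None
    for changes, gains, labeling in enumerate_labelings(t, states):
        if gains != n_gains:
            continue
        if root_state is not None and labeling.get(root_key) != root_state:
            continue
        if best is None or changes < best[0]:
            best = (changes, gains, labeling)
    if best is None:
        return ScenarioResult(0, 0, 0, {}, feasible=False)
    changes, gains, labeling = best
    full = dict(labeling)
    for leaf in t.leaf_node_iter():
        full[leaf.taxon.label] = states[leaf.taxon.label]
    return ScenarioResult(changes, gains, changes - gains, full)
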