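"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: parsimony by exhaustive
enumeration over ancestral labelings, Fitch counting, naive microhomology,
and a rooted-tree-shape enumerator.
"""

from __future__ import annotations

import itertools

from intronevo.io_formats import RootedTree, TreeNode

INF = float("inf")


def enumerate_shapes(n: int):
    """All rooted binary tree shapes with n leaves, as nested tuples."""
    if n == 1:
        return [None]  # a leaf
    shapes = []
    seen = set()
    for left in range(1, n // 2 + 1):
        for ls in enumerate_shapes(left):
            for rs in enumerate_shapes(n - left):
                key = repr((ls, rs))
                if key not in seen:
                    seen.add(key)
                    shapes.append((ls, rs))
    return shapes


def shape_to_tree(shape) -> RootedTree:
    """Label leaves L1..Ln left to right."""
    counter = itertools.count(1)

    def build(s) -> TreeNode:
        if s is None:
            return TreeNode(f"L{next(counter)}")
        node = TreeNode()
        node.add(build(s[0]))
        node.add(build(s[1]))
        return node

    return RootedTree(build(shape))


def _edges_and_free(tree: RootedTree, states: dict[str, str]):
    nodes = tree.postorder()
    index = {id(n): i for i, n in enumerate(nodes)}
    edges = [
        (index[id(n.parent)], index[id(n)]) for n in nodes if n.parent is not None
    ]
    fixed = {}
    free = []
    for i, n in enumerate(nodes):
        if n.is_leaf:
            s = states[n.label]
            if s == "P":
                fixed[i] = 0
            elif s == "A":
                fixed[i] = 1
            else:
                free.append(i)
        elif n.parent is None:
            fixed[i] = 0  # root fixed Present
        else:
            free.append(i)
    return nodes, edges, fixed, free


def brute_force_min_cost(
    tree: RootedTree,
    states: dict[str, str],
    cost_loss: float = 1.0,
    cost_gain: float = INF,
) -> float:
    """Minimum total cost over every ancestral labeling (root Present).

    cost_gain=INF forbids gains (the Dollo loss-only model).
    """
    nodes, edges, fixed, free = _edges_and_free(tree, states)
    best = INF
    for bits in itertools.product((0, 1), repeat=len(free)):
        assign = dict(fixed)
        assign.update(zip(free, bits))
        total = 0.0
        for u, v in edges:
            if assign[u] == 0 and assign[v] == 1:
                total += cost_loss
            elif assign[u] == 1 and assign[v] == 0:
                total += cost_gain
            if total >= best:
                break
        best = min(best, total)
    return best


def fitch_changes(tree: RootedTree, states: dict[str, str]) -> int:
    """Fitch small-parsimony change count on {P, A}; ND = both states."""
    count = 0
    sets: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = states[node.label]
            sets[id(node)] = (
                frozenset("PA") if s == "ND" else frozenset(s)
            )
        else:
            inter = None
            for c in node.children:
                cs = sets[id(c)]
                inter = cs if inter is None else inter & cs
            if inter:
                sets[id(node)] = inter
            else:
                union = frozenset()
                for c in node.children:
                    union |= sets[id(c)]
                sets[id(node)] = union
                count += 1
    return count


def naive_microhomology(up: str, intron: str, down: str, cap: int = 8):
    """Direct double loop over all candidate lengths."""
    up, intron, down = up.upper(), intron.upper(), down.upper()
    k5 = 0
    for m in range(1, cap + 1):
        if m <= len(up) and m <= len(intron) and up[-m:] == intron[-m:]:
            k5 = m
    k3 = 0
    for m in range(1, cap + 1):
        if m <= len(down) and m <= len(intron) and intron[:m] == down[:m]:
            k3 = m
    return k5, k3
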