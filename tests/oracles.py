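"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths they check: the Fisher oracle works
in exact rational arithmetic over the full hypergeometric support, and the
Dollo oracle enumerates every single-gain state assignment on the tree.
"""

from fractions import Fraction
from itertools import product
from math import comb


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact enumeration of the hypergeometric support.

    Point probabilities are exact Fractions; a table enters the sum when its
    probability is at most the observed one, allowing the same 1e-7 relative
    tie tolerance the implementation uses (evaluated on exact values, so any
    genuine tie is included exactly).
    """
    n1, n2, k = a + b, c + d, a + c
    total = n1 + n2
    denom = comb(total, k)
    obs = Fraction(comb(n1, a) * comb(n2, c), denom)
    p = Fraction(0)
    for x in range(max(0, k - n2), min(k, n1) + 1):
        px = Fraction(comb(n1, x) * comb(n2, k - x), denom)
        if px <= obs or float(abs(px - obs)) <= 1e-7 * float(obs):
            p += px
    return float(min(p, Fraction(1)))


def enumerate_rooted_binary_shapes(n_tips: int):
    """All rooted binary tree shapes with exactly ``n_tips`` tips, as nested
    tuples (leaves are None).  Counts follow the Wedderburn-Etherington
    numbers: 1, 1, 2, 3, 6, 11, 23 for 2..8 tips."""
    if n_tips == 1:
        return [None]
    shapes = []
    seen = set()
    for left_n in range(1, n_tips // 2 + 1):
        for left in enumerate_rooted_binary_shapes(left_n):
            for right in enumerate_rooted_binary_shapes(n_tips - left_n):
                canon_pair = tuple(sorted([_canon(left), _canon(right)]))
                if canon_pair in seen:
                    continue
                seen.add(canon_pair)
                shapes.append((left, right))
    return shapes


def _canon(shape) -> str:
    if shape is None:
        return "*"
    left, right = (_canon(shape[0]), _canon(shape[1]))
    lo, hi = sorted([left, right])
    return f"({lo},{hi})"


def shape_to_newick(shape, prefix: str = "t") -> str:
    """Label a shape's leaves t0..t{n-1} left to right and render Newick."""
    counter = [0]

    def render(node) -> str:
        if node is None:
            label = f"{prefix}{counter[0]}"
            counter[0] += 1
            return label
        return f"({render(node[0])},{render(node[1])})"

    return render(shape) + ";"


class _Node:
    __slots__ = ("parent", "children", "leaf_label", "index")

    def __init__(self):
        self.parent = None
        self.children = []
        self.leaf_label = None
        self.index = -1


def _build(shape, prefix="t"):
    counter = [0]
    nodes = []

    def rec(s):
        node = _Node()
        node.index = len(nodes)
        nodes.append(node)
        if s is None:
            node.leaf_label = f"{prefix}{counter[0]}"
            counter[0] += 1
        else:
            for child_shape in s:
                ch = rec(child_shape)
                ch.parent = node
                node.children.append(ch)
        return node

    root = rec(shape)
    return root, nodes


def dollo_min_losses_exhaustive(shape, profile: dict) -> int:
    """Minimum loss edges over all single-gain presence assignments.

    Enumerates every assignment of presence states to internal nodes combined
    with every choice of gain node; an assignment is admissible when the
    present node set is exactly the gain node plus parent-connected
    descendants, and tip states match the profile.  Returns the minimal
    number of present-parent -> absent-child edges (0 for an empty profile).
    """
    root, nodes = _build(shape)
    leaves = [n for n in nodes if n.leaf_label is not None]
    internals = [n for n in nodes if n.leaf_label is None]
    tip_state = {n: bool(profile[n.leaf_label]) for n in leaves}
    if not any(tip_state.values()):
        return 0

    best = None
    for bits in product([False, True], repeat=len(internals)):
        state = dict(tip_state)
        for node, bit in zip(internals, bits):
            state[node] = bit
        present = [n for n in nodes if state[n]]
        # single-gain: present set must be connected through parent links,
        # i.e. exactly one present node has an absent (or no) parent
        gains = [
            n for n in present if n.parent is None or not state[n.parent]
        ]
        if len(gains) != 1:
            continue
        losses = sum(
            1 for n in nodes if not state[n] and n.parent is not None and state[n.parent]
        )
        if best is None or losses < best:
            best = losses
    return best
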