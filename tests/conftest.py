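"""Shared fixtures: the embedded worked example, hand-built Lewis structures,
and seeded random corpora."""

from __future__ import annotations

import numpy as np
import pytest

import glycantree as gt

# the GlcNAc worked example: one base + one n-acetyl merged into a single
# composed residue (the canonical two-building-block case)
GLCNAC_ONELINE = "RES 1b:x-dglc-HEX-1:5 2s:n-acetyl LIN 1:1d(2+1)2n"

# hand-written Lewis antigen GlycoCT (fully defined linkages)
LEWIS_A = """RES
1b:b-dglc-HEX-1:5
2s:n-acetyl
3b:b-dgal-HEX-1:5
4b:a-lgal-HEX-1:5|6:d
LIN
1:1d(2+1)2n
2:1o(3+1)3d
3:1o(4+1)4d
"""

LEWIS_X = """RES
1b:b-dglc-HEX-1:5
2s:n-acetyl
3b:b-dgal-HEX-1:5
4b:a-lgal-HEX-1:5|6:d
LIN
1:1d(2+1)2n
2:1o(4+1)3d
3:1o(3+1)4d
"""

LEWIS_B = """RES
1b:b-dglc-HEX-1:5
2s:n-acetyl
3b:b-dgal-HEX-1:5
4b:a-lgal-HEX-1:5|6:d
5b:a-lgal-HEX-1:5|6:d
LIN
1:1d(2+1)2n
2:1o(3+1)3d
3:3o(2+1)4d
4:1o(4+1)5d
"""

LEWIS_Y = """RES
1b:b-dglc-HEX-1:5
2s:n-acetyl
3b:b-dgal-HEX-1:5
4b:a-lgal-HEX-1:5|6:d
5b:a-lgal-HEX-1:5|6:d
LIN
1:1d(2+1)2n
2:1o(4+1)3d
3:3o(2+1)4d
4:1o(3+1)5d
"""

# Lewis B with every glycosidic position and anomer blanked (ambiguous data)
LEWIS_B_BLANKED = """RES
1b:x-dglc-HEX-1:5
2s:n-acetyl
3b:x-dgal-HEX-1:5
4b:x-lgal-HEX-1:5|6:d
5b:x-lgal-HEX-1:5|6:d
LIN
1:1d(2+1)2n
2:1o(-1+1)3d
3:3o(-1+1)4d
4:1o(-1+1)5d
"""

# a structure with three undefined sections (bag items)
THREE_UND = """RES
1b:b-dglc-HEX-1:5
2s:n-acetyl
LIN
1:1d(2+1)2n
UND
UND1:100.0:100.0
ParentIDs:1
SubtreeLinkageID1:o(-1+1)d
RES
3b:a-lgal-HEX-1:5|6:d
UND2:100.0:100.0
ParentIDs:1
SubtreeLinkageID1:o(-1+1)d
RES
4b:b-dgal-HEX-1:5
UND3:100.0:100.0
ParentIDs:1
SubtreeLinkageID1:o(-1+1)d
RES
5b:b-dgal-HEX-1:5
"""

# a disialylated O-linked Core 1: Neu5Ac-Neu5Ac chain on the Gal arm
DISIALYL_CORE1 = """RES
1b:a-dgal-HEX-1:5
2s:n-acetyl
3b:b-dgal-HEX-1:5
4b:a-dgro-dgal-NON-2:6|1:a|2:keto|3:d
5s:n-acetyl
6b:a-dgro-dgal-NON-2:6|1:a|2:keto|3:d
7s:n-acetyl
LIN
1:1d(2+1)2n
2:1o(3+1)3d
3:3o(3+2)4d
4:4d(5+1)5n
5:4o(8+2)6d
6:6d(5+1)7n
"""


@pytest.fixture(scope="session")
def rules():
    return gt.default_rules()


@pytest.fixture(scope="session")
def glcnac_glycan(rules):
    return gt.build_glycan(gt.parse_glycoct(GLCNAC_ONELINE), rules, id="glcnac")


def build(text: str, rules, gid: str = "g") -> gt.Glycan:
    return gt.build_glycan(gt.parse_glycoct(text), rules, id=gid)


@pytest.fixture(scope="session")
def lewis(rules):
    return {
        "a": build(LEWIS_A, rules, "lewis_a"),
        "x": build(LEWIS_X, rules, "lewis_x"),
        "b": build(LEWIS_B, rules, "lewis_b"),
        "y": build(LEWIS_Y, rules, "lewis_y"),
        "b_blanked": build(LEWIS_B_BLANKED, rules, "lewis_b_blanked"),
    }


@pytest.fixture(scope="session")
def small_corpus(rules):
    """120 seeded random structures (built Glycans + GlycoCT text)."""
    params = gt.GeneratorParams(seed=0)
    rng_seeds = np.random.SeedSequence(20240917).generate_state(120)
    out = []
    for i, s in enumerate(rng_seeds):
        g, text, lab = gt.random_glycan(params, seed=int(s) % 2**31, structure_id=f"C{i:03d}")
        out.append((g, text, lab))
    return out


def random_query_pattern(rng: np.random.Generator, **options) -> gt.QueryPattern:
    """A random small constraint tree, built directly (no notation round-trip)."""
    from glycantree.query import ANY, BASETYPE, COMPOSITION, PatternNode

    node_choices = [
        gt.NodeConstraint(),
        gt.NodeConstraint(BASETYPE, "dgal-HEX", ("forbidden", None)),
        gt.NodeConstraint(BASETYPE, "dglc-HEX", ("required", "n-acetyl")),
        gt.NodeConstraint(BASETYPE, "dman-HEX", ("forbidden", None)),
        gt.NodeConstraint(COMPOSITION, "dHex", ("forbidden", None)),
        gt.NodeConstraint(COMPOSITION, "Hex"),
        gt.NodeConstraint(COMPOSITION, "HexNAc"),
        gt.NodeConstraint(BASETYPE, "dgal-HEX", ("forbidden", None), anomer="b"),
        gt.NodeConstraint(substituent=("required", "sulfate")),
    ]
    edge_choices = [
        gt.EdgeConstraint(),
        gt.EdgeConstraint(parent_positions=frozenset({3})),
        gt.EdgeConstraint(parent_positions=frozenset({4})),
        gt.EdgeConstraint(parent_positions=frozenset({3, 6})),
        gt.EdgeConstraint(child_positions=frozenset({1})),
        gt.EdgeConstraint(parent_positions=frozenset({2}), child_positions=frozenset({1})),
    ]
    n_nodes = int(rng.integers(1, 5))
    counter = [0]

    def make_node() -> PatternNode:
        counter[0] += 1
        return PatternNode(counter[0], node_choices[int(rng.integers(len(node_choices)))])

    root = make_node()
    nodes = [root]
    while len(nodes) < n_nodes:
        parent = nodes[int(rng.integers(len(nodes)))]
        child = make_node()
        edge = edge_choices[int(rng.integers(len(edge_choices)))]
        parent.children.append((edge, child))
        nodes.append(child)
    for i, node in enumerate(root.walk(), start=1):
        node.id = i
    opts = dict(
        anchor=["anywhere", "root", "whole"][int(rng.integers(3))],
        ambiguity=["strict", "fuzzy"][int(rng.integers(2))],
        scope=["core", "bag", "both"][int(rng.integers(3))],
    )
    opts.update(options)
    return gt.QueryPattern(root, **opts)
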