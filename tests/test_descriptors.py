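"""Topological and whole-molecule descriptors against independent oracles.

The Wiener and connectivity indices are checked against a hand-written
breadth-first-search / edge-sum oracle on random connected graphs, against
closed forms for paths and stars, and against tiny hand-worked molecules.
"""

from collections import deque

import networkx as nx
import numpy as np
import pytest
from rdkit import Chem

from steroscreen import (compute_descriptors, count_descriptors,
                         first_order_mci, geary_autocorrelation,
                         lipinski_violations, mordred_subset, wiener_index)
from steroscreen.descriptors import DescriptorVector, zmic
from steroscreen.simulate import gen_molecule_graphs


# --- independent oracles ---------------------------------------------------

def bfs_distances(graph, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in graph.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def wiener_oracle(graph):
    total = 0
    for u in graph.nodes():
        total += sum(bfs_distances(graph, u).values())
    return total // 2


def mci_oracle(graph):
    deg = dict(graph.degree())
    return sum(1.0 / (deg[u] * deg[v]) ** 0.5 for u, v in graph.edges())


# --- Wiener index ----------------------------------------------------------

@pytest.mark.parametrize("smiles,expected", [
    ("C", 0),       # methane heavy-atom graph: single vertex
    ("CCC", 4),     # propane: 1+1+2
    ("CCCC", 10),   # n-butane path: n(n^2-1)/6
])
def test_wiener_small_molecules(smiles, expected):
    assert wiener_index(Chem.MolFromSmiles(smiles)) == expected


@pytest.mark.parametrize("n", range(2, 21))
def test_wiener_closed_forms(n):
    assert wiener_index(nx.path_graph(n)) == n * (n * n - 1) // 6
    assert wiener_index(nx.star_graph(n - 1)) == (n - 1) ** 2


def test_wiener_and_mci_match_oracles_on_random_graphs():
    graphs = gen_molecule_graphs(100, (5, 30), seed=20260921)
    for g in graphs:
        assert wiener_index(g) == wiener_oracle(g)
        assert first_order_mci(g) == pytest.approx(mci_oracle(g), abs=1e-12)


def test_adding_edge_never_increases_wiener():
    rng = np.random.default_rng(7)
    for g in gen_molecule_graphs(30, (5, 20), seed=11):
        w_before = wiener_index(g)
        nodes = list(g.nodes())
        non_edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]
                     if not g.has_edge(u, v)]
        if not non_edges:
            continue
        u, v = non_edges[rng.integers(len(non_edges))]
        g.add_edge(u, v)
        assert wiener_index(g) <= w_before


def test_disconnected_graph_rejected_naming_components():
    g = nx.Graph([(0, 1), (2, 3)])
    with pytest.raises(ValueError, match="disconnected"):
        wiener_index(g)


# --- molecular connectivity ------------------------------------------------

@pytest.mark.parametrize("smiles,expected", [
    ("CC", 1.0),                  # one bond between two degree-1 atoms
    ("CCC", 2.0 / 2.0 ** 0.5),    # two bonds, each 1/sqrt(1*2)
    ("C1CCCCC1", 3.0),            # six bonds, each 1/sqrt(2*2)
])
def test_mci_small_molecules(smiles, expected):
    assert first_order_mci(Chem.MolFromSmiles(smiles)) == pytest.approx(expected)


def test_mci_requires_a_bond():
    with pytest.raises(ValueError, match="no bonds"):
        first_order_mci(Chem.MolFromSmiles("C"))


# --- counts and the rule of five -------------------------------------------

def test_count_descriptors_examples():
    benzene = count_descriptors(Chem.MolFromSmiles("c1ccccc1"))
    assert benzene.n_aromatic_heavy == 6
    assert benzene.n_rotatable == 0
    ethanol = count_descriptors(Chem.MolFromSmiles("CCO"))
    assert (ethanol.nhd, ethanol.nha) == (1, 1)
    hexane = count_descriptors(Chem.MolFromSmiles("CCCCCC"))
    assert hexane.n_rotatable == 3  # non-terminal, non-ring single bonds


def test_lipinski_violation_counts():
    all_bad = DescriptorVector(mw=600, nhd=6, nha=11)
    assert lipinski_violations(all_bad, logp_value=6.0) == 4
    fine = DescriptorVector(mw=300, nhd=1, nha=3, logp=2.0)
    assert lipinski_violations(fine) == 0
    with pytest.raises(ValueError, match="logp"):
        lipinski_violations(DescriptorVector(mw=300, nhd=1, nha=3))


# --- Geary autocorrelation -------------------------------------------------

def test_geary_two_atom_hand_example():
    # weights (6, 8) across one bond: numerator (8-6)^2/2 = 2,
    # denominator ((6-7)^2 + (8-7)^2)/1 = 2 -> exactly 1
    g = nx.Graph([(0, 1)])
    assert geary_autocorrelation(g, lag=1, weights=[6.0, 8.0]) == pytest.approx(1.0)


def test_geary_degenerate_cases():
    g = nx.path_graph(4)
    assert geary_autocorrelation(g, 1, weights=[5, 5, 5, 5]) is None  # constant
    assert geary_autocorrelation(g, 7, weights=[1, 2, 3, 4]) is None  # lag > diameter
    with pytest.raises(ValueError):
        geary_autocorrelation(g, 0, weights=[1, 2, 3, 4])
    with pytest.raises(ValueError, match="weights"):
        geary_autocorrelation(g, 1, weights=[1, 2])


def test_geary_matches_naive_pair_sum_on_random_graphs():
    rng = np.random.default_rng(3)
    for g in gen_molecule_graphs(20, (6, 15), seed=5):
        w = rng.normal(size=g.number_of_nodes())
        nodes = sorted(g.nodes())
        for lag in (1, 2, 3):
            pairs = []
            for i, u in enumerate(nodes):
                dist = bfs_distances(g, u)
                pairs += [(i, nodes.index(v)) for v in nodes[i + 1:]
                          if dist.get(v) == lag]
            value = geary_autocorrelation(g, lag, weights=w)
            if not pairs:
                assert value is None
                continue
            num = sum((w[i] - w[j]) ** 2 for i, j in pairs) / (2 * len(pairs))
            den = np.sum((w - w.mean()) ** 2) / (len(w) - 1)
            assert value == pytest.approx(num / den, rel=1e-10)


# --- Mordred-style subset ---------------------------------------------------

def test_zmic1_ethanol_hand_value():
    # H-included order-1 classes for CCO: {CH3 carbon}, {CH2 carbon}, {O},
    # {5 C-bound H}, {O-bound H}; class atomic-number masses (6,6,8,5,1)/26;
    # Shannon entropy of that distribution = 2.137779 bits (hand-derived)
    assert zmic(Chem.MolFromSmiles("CCO"), 1) == pytest.approx(2.1377785, abs=1e-6)


def test_gats7z_degenerate_inputs():
    # all-carbon skeleton: zero variance in atomic number
    _, _, gats, _ = mordred_subset(Chem.MolFromSmiles("C1CCCCC1"))
    assert gats is None
    # hexane: no heavy-atom pair at topological distance 7
    _, _, gats, _ = mordred_subset(Chem.MolFromSmiles("CCCCCC"))
    assert gats is None


def test_mordred_subset_on_a_steroid(structures):
    zmic1, estate_vsa8, gats7z, lipinski_term = mordred_subset(structures["HC"])
    assert zmic1 > 0
    assert estate_vsa8 >= 0
    assert gats7z is not None and gats7z > 0
    assert lipinski_term == 1.0


# --- assembly ---------------------------------------------------------------

def test_counts_invariant_under_atom_reordering(structures):
    for cid in ("HC", "E2-BZ", "SPIRO"):
        mol = structures[cid]
        order = list(range(mol.GetNumAtoms()))[::-1]
        shuffled = Chem.RenumberAtoms(mol, order)
        a, b = compute_descriptors(mol), compute_descriptors(shuffled)
        for fld in ("w", "mci", "mw", "n_heavy", "n_aromatic_heavy",
                    "n_rotatable", "nhd", "nha", "zmic1", "gats7z"):
            assert getattr(a, fld) == pytest.approx(getattr(b, fld)), (cid, fld)


def test_external_descriptor_hierarchy(structures):
    mol = structures["HC"]
    internal = compute_descriptors(mol)
    assert internal.sources == {"logp": "crippen", "surface_area": "labute_asa"}
    assert internal.ilogp is None  # external-only, never computed
    supplied = compute_descriptors(mol, logp=9.9, surface_area=123.0, ilogp=1.5)
    assert supplied.logp == 9.9 and supplied.surface_area == 123.0
    assert supplied.sources == {"logp": "supplied", "surface_area": "supplied"}
    assert supplied.ilogp == 1.5


def test_descriptor_table_shape(desc_frame, structures):
    assert len(desc_frame) == len(structures)
    assert {"w", "mci", "zmic1", "gats7z", "surface_area"} <= set(desc_frame.columns)
    assert (desc_frame["w"] > 0).all()
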