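"""Molecular descriptors consumed by the fixed QSAR equations and the
rule-of-five filter.

Two families live here:

* graph-topological indices computed on the hydrogen-suppressed molecular
  graph — the Wiener index ``W`` (sum of topological distances over all
  unordered heavy-atom pairs) and the first-order molecular connectivity
  (Randić) index ``MCI`` (sum over bonds of ``1/sqrt(deg_i * deg_j)``);
* Mordred-style whole-molecule descriptors computed on the hydrogen-included
  graph — ``GATS7Z`` (Geary autocorrelation at topological lag 7, weighted
  by atomic number), ``ZMIC1`` (atomic-number-weighted information content
  of the order-1 neighbourhood-symmetry classes) and ``EState_VSA8``
  (delegated to RDKit, which implements the published E-state/VSA binning).

Aromaticity, H-bond donor/acceptor counts and the strict rotatable-bond
definition (non-ring single bonds between non-terminal heavy atoms, amide
C–N excluded) follow RDKit's default perception.  ``iLOGP``, ``MDCK`` and
``PAMPA`` are external predictor outputs and are only ever passed through,
never computed here; ``logp`` and ``surface_area`` fall back to internal
estimates (Wildman–Crippen logP, Labute approximate surface area) when no
external value is supplied, and the source used is recorded on the vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, NamedTuple

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

log = logging.getLogger(__name__)

__all__ = [
    "DescriptorVector",
    "CountDescriptors",
    "wiener_index",
    "first_order_mci",
    "count_descriptors",
    "lipinski_violations",
    "geary_autocorrelation",
    "mordred_subset",
    "compute_descriptors",
    "descriptor_table",
]


class CountDescriptors(NamedTuple):
    mw: float
    n_heavy: int
    n_aromatic_heavy: int
    n_rotatable: int
    nhd: int
    nha: int


@dataclass
class DescriptorVector:
    """All descriptors any in-scope equation or rule consumes.

    ``None`` marks an explicitly missing value (external descriptor not
    supplied, or a degenerate case such as ``GATS7Z`` on a molecule with no
    atom pair at topological distance 7).
    """

    w: int | None = None
    mci: float | None = None
    mw: float | None = None
    n_heavy: int | None = None
    n_aromatic_heavy: int | None = None
    n_rotatable: int | None = None
    nhd: int | None = None
    nha: int | None = None
    surface_area: float | None = None
    logp: float | None = None
    ilogp: float | None = None
    mdck: float | None = None
    pampa: float | None = None
    zmic1: float | None = None
    estate_vsa8: float | None = None
    gats7z: float | None = None
    lipinski_term: float | None = None
    sources: dict = field(default_factory=dict, compare=False, repr=False)

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("sources")
        return d


# ---------------------------------------------------------------------------
# graph handling

def _adjacency(structure) -> np.ndarray:
    """Dense 0/1 adjacency of the heavy-atom graph (RDKit Mol) or of a
    networkx graph (nodes taken in sorted order)."""
    if isinstance(structure, Chem.Mol):
        return Chem.GetAdjacencyMatrix(structure).astype(float)
    if isinstance(structure, nx.Graph):
        nodes = sorted(structure.nodes())
        return nx.to_numpy_array(structure, nodelist=nodes, weight=None)
    raise TypeError(f"expected an RDKit Mol or networkx Graph, got {type(structure)!r}")


def _distance_matrix(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    if n == 1:
        return np.zeros((1, 1))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        comps = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise ValueError(f"graph is disconnected; components (by index): {comps}")
    return shortest_path(adj, method="D", directed=False, unweighted=True)


def wiener_index(structure) -> int:
    """Sum of topological distances over all unordered heavy-atom pairs.

    Hydrogens are excluded; a single-atom graph has W = 0; disconnected
    graphs are rejected with the component memberships named.
    """
    dist = _distance_matrix(_adjacency(structure))
    return int(round(dist.sum() / 2.0))


def first_order_mci(structure) -> float:
    """First-order molecular connectivity (Randić) index,
    ``sum over bonds of 1/sqrt(deg_i * deg_j)`` on heavy-atom degrees."""
    adj = _adjacency(structure)
    deg = adj.sum(axis=1)
    ii, jj = np.nonzero(np.triu(adj))
    if ii.size == 0:
        raise ValueError("first-order MCI undefined: graph has no bonds")
    return float(np.sum(1.0 / np.sqrt(deg[ii] * deg[jj])))


# ---------------------------------------------------------------------------
# count and rule-of-five descriptors

def count_descriptors(mol: Chem.Mol) -> CountDescriptors:
    """MW and the heavy-atom / aromatic / rotatable / H-bond donor-acceptor
    counts under RDKit's default aromaticity model and the strict rotatable
    bond definition."""
    if not isinstance(mol, Chem.Mol):
        raise TypeError("count_descriptors expects an RDKit Mol")
    return CountDescriptors(
        mw=Descriptors.MolWt(mol),
        n_heavy=mol.GetNumHeavyAtoms(),
        n_aromatic_heavy=sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()),
        n_rotatable=rdMolDescriptors.CalcNumRotatableBonds(
            mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
        ),
        nhd=Lipinski.NumHDonors(mol),
        nha=Lipinski.NumHAcceptors(mol),
    )


def lipinski_violations(d: DescriptorVector, logp_value: float | None = None) -> int:
    """Number of rule-of-five criteria violated (0-4): MW > 500, logP > 5,
    H-bond donors > 5, H-bond acceptors > 10."""
    logp = logp_value if logp_value is not None else d.logp
    missing = [name for name, v in
               (("mw", d.mw), ("nhd", d.nhd), ("nha", d.nha), ("logp", logp)) if v is None]
    if missing:
        raise ValueError(f"lipinski_violations: missing descriptor(s) {missing}")
    return int(d.mw > 500) + int(logp > 5) + int(d.nhd > 5) + int(d.nha > 10)


# ---------------------------------------------------------------------------
# autocorrelation / information-content descriptors (hydrogen-included graph)

def geary_autocorrelation(structure, lag: int, weights: Iterable[float] | None = None) -> float | None:
    """Geary spatial autocorrelation of per-atom weights at a topological lag.

    ``GATS_k = [sum_{d(i,j)=k} (w_i - w_j)^2 / (2 N_k)] /
    [sum_i (w_i - mean w)^2 / (n - 1)]``

    Returns ``None`` (explicit missing) when the statistic is undefined:
    fewer than two atoms, zero weight variance, or no atom pair at distance
    ``lag``; the reason is logged.  For an RDKit Mol the default weights are
    atomic numbers on the hydrogen-suppressed graph: an all-carbon skeleton
    is degenerate (zero weight variance), and including hydrogens would let
    the C-H contrast dominate any atomic-number weighting.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if isinstance(structure, Chem.Mol) and weights is None:
        weights = [a.GetAtomicNum() for a in structure.GetAtoms()]
    adj = _adjacency(structure)
    w = np.asarray(list(weights), dtype=float)
    if w.shape[0] != adj.shape[0]:
        raise ValueError(f"got {w.shape[0]} weights for {adj.shape[0]} atoms")
    n = w.shape[0]
    if n < 2:
        log.debug("geary lag=%d: fewer than two atoms", lag)
        return None
    denom = np.sum((w - w.mean()) ** 2) / (n - 1)
    if denom == 0.0:
        log.debug("geary lag=%d: zero weight variance", lag)
        return None
    dist = _distance_matrix(adj)
    ii, jj = np.nonzero(np.triu(dist == lag))
    if ii.size == 0:
        log.debug("geary lag=%d: no atom pairs at that distance", lag)
        return None
    numer = np.sum((w[ii] - w[jj]) ** 2) / (2.0 * ii.size)
    return float(numer / denom)


def _neighborhood_classes(mol_h: Chem.Mol, order: int) -> list[int]:
    """Equivalence classes under order-``m`` neighbourhood symmetry: start
    from atomic number and refine ``m`` times by the sorted multiset of
    (bond order, neighbour class) pairs."""
    labels = [a.GetAtomicNum() for a in mol_h.GetAtoms()]
    for _ in range(order):
        keys = []
        for atom in mol_h.GetAtoms():
            env = sorted(
                (b.GetBondTypeAsDouble(), labels[b.GetOtherAtom(atom).GetIdx()])
                for b in atom.GetBonds()
            )
            keys.append((labels[atom.GetIdx()], tuple(env)))
        remap = {k: i for i, k in enumerate(sorted(set(keys)))}
        labels = [remap[k] for k in keys]
    return labels


def zmic(mol: Chem.Mol, order: int = 1) -> float:
    """Atomic-number-weighted information content of the order-``m``
    neighbourhood-symmetry atom partition (hydrogen-included graph):
    Shannon entropy, in bits, of the distribution of total atomic number
    over equivalence classes."""
    mol_h = Chem.AddHs(mol)
    labels = _neighborhood_classes(mol_h, order)
    z = np.array([a.GetAtomicNum() for a in mol_h.GetAtoms()], dtype=float)
    z_class = np.array([z[np.array(labels) == c].sum() for c in sorted(set(labels))])
    p = z_class / z_class.sum()
    return float(-(p * np.log2(p)).sum())


def mordred_subset(mol: Chem.Mol) -> tuple[float, float, float | None, float]:
    """The four descriptors of the placental-transfer equation:
    ``(ZMIC1, EState_VSA8, GATS7Z, Lipinski)``.

    ``Lipinski`` is the rule-of-five pass flag (1.0 when none of the four
    criteria is violated, logP taken from the internal Wildman-Crippen
    estimator), matching the boolean drug-likeness descriptor exposed by
    common descriptor calculators.  ``GATS7Z`` is ``None`` for degenerate
    inputs (constant atomic number, or no atom pair at distance 7).
    """
    zmic1 = zmic(mol, order=1)
    estate_vsa8 = float(Descriptors.EState_VSA8(mol))
    gats7z = geary_autocorrelation(mol, lag=7)
    counts = count_descriptors(mol)
    d = DescriptorVector(mw=counts.mw, nhd=counts.nhd, nha=counts.nha,
                         logp=Crippen.MolLogP(mol))
    lipinski_term = 1.0 if lipinski_violations(d) == 0 else 0.0
    return zmic1, estate_vsa8, gats7z, lipinski_term


# ---------------------------------------------------------------------------
# assembly

def compute_descriptors(
    mol: Chem.Mol,
    *,
    logp: float | None = None,
    surface_area: float | None = None,
    ilogp: float | None = None,
    mdck: float | None = None,
    pampa: float | None = None,
) -> DescriptorVector:
    """Full descriptor vector for one structure.

    External predictor outputs (``ilogp``, ``mdck``, ``pampa``) are
    pass-through only.  ``logp`` and ``surface_area`` follow the source
    hierarchy *supplied value > internal estimate*; the resolved source is
    recorded in ``sources``.
    """
    counts = count_descriptors(mol)
    zmic1, estate_vsa8, gats7z, lipinski_term = mordred_subset(mol)
    sources = {}
    if logp is None:
        logp = float(Crippen.MolLogP(mol))
        sources["logp"] = "crippen"
    else:
        sources["logp"] = "supplied"
    if surface_area is None:
        surface_area = float(rdMolDescriptors.CalcLabuteASA(mol))
        sources["surface_area"] = "labute_asa"
    else:
        sources["surface_area"] = "supplied"
    try:
        mci = first_order_mci(mol)
    except ValueError:
        mci = None
    return DescriptorVector(
        w=wiener_index(mol),
        mci=mci,
        mw=counts.mw,
        n_heavy=counts.n_heavy,
        n_aromatic_heavy=counts.n_aromatic_heavy,
        n_rotatable=counts.n_rotatable,
        nhd=counts.nhd,
        nha=counts.nha,
        surface_area=surface_area,
        logp=logp,
        ilogp=ilogp,
        mdck=mdck,
        pampa=pampa,
        zmic1=zmic1,
        estate_vsa8=estate_vsa8,
        gats7z=gats7z,
        lipinski_term=lipinski_term,
        sources=sources,
    )


def descriptor_table(structures: Mapping[str, Chem.Mol], **external) -> "pd.DataFrame":
    """Descriptor vectors for many structures as a DataFrame (one row per
    compound, columns exactly the DescriptorVector field names).

    ``external`` may carry per-compound mappings for the pass-through
    descriptors, e.g. ``ilogp={"HC": 1.9, ...}``.
    """
    import pandas as pd

    rows = {}
    for cid, mol in structures.items():
        kwargs = {key: values.get(cid) for key, values in external.items()}
        rows[cid] = compute_descriptors(mol, **kwargs).as_dict()
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "compound_id"
    return frame
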