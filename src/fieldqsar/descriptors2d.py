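"""Topological whole-molecule descriptors and MLR-based relevance ranking.

Two descriptors augment the 3D field blocks:

CIC2 — complementary information content of order 2.  Atoms are partitioned
into equivalence classes by their radius-2 rooted neighborhoods (element plus
incident bond orders, refined twice Morgan-style); with class sizes n_g out
of n atoms, IC2 = -sum (n_g/n) log2(n_g/n) and CIC2 = log2(n) - IC2.
Hydrogens are included in the graph.

BEHv2 — the second-largest eigenvalue of the Burden connectivity matrix over
heavy atoms: diagonal entries are atomic van der Waals volumes scaled so
carbon is 1.0; bonded pairs carry 0.1 * conventional bond order (aromatic
1.5); all non-bonded pairs carry 0.001.

``rank_descriptors`` reproduces the selection stage that picked these two
out of a large 2D pool: forward-stepwise multiple linear regression, adding
at each step the descriptor with the largest partial F.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_io import Molecule, default_scheme

Bond = tuple[int, int, float]


class DescriptorError(ValueError):
    pass


# --------------------------------------------------------------------------
# CIC2
# --------------------------------------------------------------------------

def _neighborhood_classes(
    elements: Sequence[str], bonds: Sequence[Bond], radius: int = 2
) -> list[int]:
    """Equivalence-class labels from ``radius`` rounds of neighborhood refinement.

    Two atoms share a class iff their rooted neighborhood trees of the given
    radius (element labels + bond orders along edges) are isomorphic; this is
    the standard iterative-refinement construction of the information indices.
    """
    n = len(elements)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, j, order in bonds:
        if not (0 <= i < n and 0 <= j < n):
            raise DescriptorError(f"bond ({i},{j}) index out of range")
        adj[i].append((j, order))
        adj[j].append((i, order))
    labels = list(elements)
    for _ in range(radius):
        new = []
        for i in range(n):
            env = tuple(sorted((order, labels[j]) for j, order in adj[i]))
            new.append((labels[i], env))
        # compress to hashable canonical strings for the next round
        labels = [repr(x) for x in new]
    index = {lab: k for k, lab in enumerate(sorted(set(labels)))}
    return [index[lab] for lab in labels]


def ic2_from_graph(elements: Sequence[str], bonds: Sequence[Bond]) -> float:
    """Shannon information (bits) of the radius-2 atom-equivalence partition."""
    n = len(elements)
    if n == 0:
        raise DescriptorError("empty molecule")
    counts = Counter(_neighborhood_classes(elements, bonds))
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def cic2_from_graph(elements: Sequence[str], bonds: Sequence[Bond]) -> float:
    n = len(elements)
    if n == 0:
        raise DescriptorError("empty molecule")
    return math.log2(n) - ic2_from_graph(elements, bonds)


def ic2(mol: Molecule) -> float:
    return ic2_from_graph(mol.elements, mol.bonds)


def cic2(mol: Molecule) -> float:
    """Complementary information content of order 2 (hydrogens included)."""
    return cic2_from_graph(mol.elements, mol.bonds)


# --------------------------------------------------------------------------
# BEHv2
# --------------------------------------------------------------------------

def burden_matrix(
    volumes: np.ndarray, bonds: Sequence[Bond], nonbonded: float = 0.001
) -> np.ndarray:
    n = len(volumes)
    B = np.full((n, n), nonbonded)
    np.fill_diagonal(B, np.asarray(volumes, dtype=float))
    for i, j, order in bonds:
        B[i, j] = B[j, i] = 0.1 * order
    return B


def behv2_from_graph(
    elements: Sequence[str], bonds: Sequence[Bond], vdw_radius: dict[str, float] | None = None
) -> float:
    """Second-largest eigenvalue of the vdW-volume-weighted Burden matrix."""
    n = len(elements)
    if n < 2:
        raise DescriptorError("BEHv2 needs at least 2 heavy atoms")
    table = vdw_radius or default_scheme().vdw_radius
    missing = sorted({e for e in elements if e not in table})
    if missing:
        raise DescriptorError(f"elements {missing} absent from vdW radius table")
    r_c = table["C"]
    vols = np.array([(table[e] / r_c) ** 3 for e in elements])
    B = burden_matrix(vols, bonds)
    eig = np.linalg.eigvalsh(B)
    return float(eig[-2])


def behv2(mol: Molecule) -> float:
    """BEHv2 on the hydrogen-suppressed graph (Burden convention)."""
    heavy = np.flatnonzero(mol.heavy_mask)
    remap = {int(a): k for k, a in enumerate(heavy)}
    elements = [mol.elements[a] for a in heavy]
    bonds = [
        (remap[i], remap[j], order)
        for i, j, order in mol.bonds
        if i in remap and j in remap
    ]
    return behv2_from_graph(elements, bonds)


def descriptor_table(mols: Sequence[Molecule]) -> pd.DataFrame:
    """CIC2/BEHv2 per molecule, indexed by id."""
    rows = {m.id: {"CIC2": cic2(m), "BEHv2": behv2(m)} for m in mols}
    return pd.DataFrame.from_dict(rows, orient="index")[["CIC2", "BEHv2"]]


# --------------------------------------------------------------------------
# forward-stepwise MLR ranking
# --------------------------------------------------------------------------

def rank_descriptors(X: pd.DataFrame, y: np.ndarray, k: int) -> list[str]:
    """Rank descriptors by forward-stepwise MLR partial F.

    At each step the candidate whose addition gives the largest partial
    F-statistic (largest residual-sum-of-squares drop) joins the model; ties
    are broken by lexicographic column name.  Constant columns are never
    selected.  Returns the first ``k`` names in selection order.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise DescriptorError("X and y length mismatch")
    if n <= k:
        raise DescriptorError(f"need n > k (n={n}, k={k})")
    if np.std(y) == 0:
        raise DescriptorError("constant activity vector")

    names = list(X.columns)
    vals = X.to_numpy(dtype=float)
    usable = [j for j in range(len(names)) if np.std(vals[:, j]) > 0]

    selected: list[int] = []
    base = np.ones((n, 1))
    for _ in range(k):
        best: tuple[float, str, int] | None = None
        resid0 = y - base @ np.linalg.lstsq(base, y, rcond=None)[0]
        rss0 = float(resid0 @ resid0)
        for j in usable:
            if j in selected:
                continue
            design = np.hstack([base, vals[:, j : j + 1]])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ coef
            rss1 = float(resid @ resid)
            df2 = n - design.shape[1]
            if df2 <= 0 or rss1 <= 0:
                partial_f = math.inf
            else:
                partial_f = (rss0 - rss1) / (rss1 / df2)
            if best is None or partial_f > best[0] + 1e-12 or (
                partial_f >= best[0] - 1e-12 and names[j] < best[1]
            ):
                best = (partial_f, names[j], j)
        if best is None:
            break
        selected.append(best[2])
        base = np.hstack([base, vals[:, best[2] : best[2] + 1]])
    return [names[j] for j in selected]
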