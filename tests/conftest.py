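"""Shared fixtures: tiny molecules and the headline synthetic-series run.

The expensive objects (the n=120 series and its fitted pipeline) are
session-scoped so the recovery, permutation and contour tests share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from fieldqsar.chem_io import Molecule, prepare
from fieldqsar.synthetic import SeriesSpec, build_molecule, generate_series


def mol_from_smiles(smiles: str, mol_id: str = "m", seed: int = 11) -> Molecule:
    """Embed a SMILES in 3D (ETKDG, seeded) — test-fixture helper only."""
    rd = Chem.MolFromSmiles(smiles)
    rd = AllChem.AddHs(rd)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(rd, params) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    rd.SetProp("_Name", mol_id)
    return Molecule(id=mol_id, rd=rd)


@pytest.fixture(scope="session")
def methane():
    return prepare(mol_from_smiles("C", "methane"))


@pytest.fixture(scope="session")
def ethane():
    return prepare(mol_from_smiles("CC", "ethane"))


@pytest.fixture(scope="session")
def scaffold_mol():
    return build_molecule("scaffold", {"C3": "H", "C4": "H", "C5": "H"})


@pytest.fixture(scope="session")
def small_series():
    """A 30-molecule series for cheap end-to-end checks."""
    spec = SeriesSpec(n_molecules=30, n_train=22, n_test=8, seed=7)
    return spec, generate_series(spec)


@pytest.fixture(scope="session")
def headline_series():
    """The reference recovery conditions: n=120, noise 0.15 pKi, seed 7."""
    spec = SeriesSpec(seed=7)
    return spec, generate_series(spec)


@pytest.fixture(scope="session")
def headline_pipeline(headline_series):
    """Full pipeline fit on the reference series (shared across tests)."""
    from fieldqsar.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(seed=7))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def krylov_pls1_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, n_components: int
) -> np.ndarray:
    """Independent single-response PLS oracle via the Krylov subspace.

    For one response, the PLS fitted values with ``a`` components equal the
    least-squares fit of y on the Krylov basis
    K_a = span{X'y, (X'X)X'y, ..., (X'X)^{a-1} X'y} of the centered data.
    Implemented with orthonormalization at every step for stability; no
    NIPALS deflation is used, so it is an independent route.
    """
    Xc = X_train - X_train.mean(axis=0)
    yc = y_train - y_train.mean()
    G = Xc.T @ Xc
    v = Xc.T @ yc
    basis = []
    for _ in range(n_components):
        w = v.copy()
        for b in basis:
            w -= (b @ w) * b
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        basis.append(w)
        v = G @ w
    W = np.column_stack(basis)
    T = Xc @ W
    beta, *_ = np.linalg.lstsq(T, yc, rcond=None)
    coef = W @ beta
    return (X_test - X_train.mean(axis=0)) @ coef + y_train.mean()
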