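"""Molecular interaction fields on a shared 3D lattice.

Two families of descriptor fields are computed for a set of aligned ligands:

*CoMFA* probe energies — a +1-charged sp3-carbon probe placed at every grid
point; steric interaction is a Lennard-Jones 6-12 sum, electrostatic a
Coulomb sum with distance-dependent dielectric eps(r) = r and the constant
332.0636 kcal*A/(mol*e^2).  Both are truncated to +/- an energy cutoff
(default 30 kcal/mol); at sterically excluded points (steric pinned at the
cutoff) the electrostatic value is replaced by the training-column mean.

*CoMSIA* similarity indices — Gaussian-attenuated sums

    A_k(q) = - sum_i  w_probe,k * w_ik * exp(-alpha * r_iq^2)

over all atoms i, for k in {steric, electrostatic, hydrophobic, donor,
acceptor}, with attenuation alpha = 0.3 and all probe properties +1.  No
distance cutoff is applied.

Columns are assembled into a regression block with CoMFA-STD-style scaling:
low-variance columns are dropped, each field block is rescaled so the blocks
contribute equal total variance, and appended whole-molecule descriptors are
autoscaled to unit variance as blocks of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .chem_io import Molecule

COULOMB_CONSTANT = 332.0636  # kcal*A/(mol*e^2)

COMFA_KINDS = ("comfa_steric", "comfa_electrostatic")
COMSIA_KINDS = (
    "comsia_steric",
    "comsia_electrostatic",
    "comsia_hydrophobic",
    "comsia_donor",
    "comsia_acceptor",
)
FIELD_KINDS = COMFA_KINDS + COMSIA_KINDS

_COMSIA_PROPERTY = {
    "comsia_steric": "steric",
    "comsia_electrostatic": "charges",
    "comsia_hydrophobic": "hydrophobic",
    "comsia_donor": "donor",
    "comsia_acceptor": "acceptor",
}


class FieldError(ValueError):
    pass


# --------------------------------------------------------------------------
# grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """A regular 3D lattice: origin, spacing and point counts per axis."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise FieldError("grid spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise FieldError("grid dims must be >= 2 on every axis")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, C-order (x slowest, z fastest), shape (N, 3)."""
        o = np.asarray(self.origin, dtype=float)
        axes = [o[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def max_corner(self) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * (np.asarray(self.dims) - 1)


def make_grid(
    mols: Sequence[Molecule], spacing: float = 2.0, margin: float = 4.0
) -> GridSpec:
    """Lattice enclosing all heavy atoms plus ``margin``, origin snapped to
    a multiple of ``spacing`` (so rigidly translated inputs give rigidly
    translated grids)."""
    if not mols:
        raise FieldError("cannot build a grid for an empty molecule set")
    pts = np.vstack([m.coords[m.heavy_mask] for m in mols])
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    origin = np.floor(lo / spacing) * spacing
    dims = np.ceil((hi - origin) / spacing).astype(int) + 1
    dims = np.maximum(dims, 2)
    return GridSpec(origin=tuple(origin.tolist()), spacing=float(spacing),
                    dims=tuple(int(d) for d in dims))


# --------------------------------------------------------------------------
# probe
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeSpec:
    """Probe-atom properties for the field calculations.

    CoMSIA probe: radius 1.0 A, charge +1, hydrophobicity +1, donor +1,
    acceptor +1, attenuation alpha = 0.3.  CoMFA probe: sp3 carbon with
    charge +1 and a 30 kcal/mol energy cutoff.
    """

    charge: float = 1.0
    radius: float = 1.0
    hydrophobicity: float = 1.0
    donor: float = 1.0
    acceptor: float = 1.0
    steric: float = 1.0
    lj_radius: float = 1.70     # sp3 carbon
    lj_epsilon: float = 0.107   # kcal/mol
    energy_cutoff: float = 30.0
    alpha: float = 0.3

    def __post_init__(self):
        if self.alpha <= 0:
            raise FieldError("alpha must be positive")
        if self.energy_cutoff <= 0:
            raise FieldError("energy cutoff must be positive")

    def comsia_weight(self, kind: str) -> float:
        return {
            "comsia_steric": self.steric,
            "comsia_electrostatic": self.charge,
            "comsia_hydrophobic": self.hydrophobicity,
            "comsia_donor": self.donor,
            "comsia_acceptor": self.acceptor,
        }[kind]


DEFAULT_PROBE = ProbeSpec()


# --------------------------------------------------------------------------
# single-molecule field columns
# --------------------------------------------------------------------------

def _distances(mol: Molecule, grid: GridSpec) -> np.ndarray:
    """(n_points, n_atoms) probe–atom distances."""
    pts = grid.points()
    xyz = mol.coords
    diff = pts[:, None, :] - xyz[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def comsia_field(
    mol: Molecule, grid: GridSpec, probe: ProbeSpec = DEFAULT_PROBE, kind: str = "comsia_steric"
) -> np.ndarray:
    """One CoMSIA similarity-index column: -sum_i w_probe * w_i * exp(-alpha r^2)."""
    if kind not in COMSIA_KINDS:
        raise FieldError(f"unknown CoMSIA field kind {kind!r}")
    prop_name = _COMSIA_PROPERTY[kind]
    w = getattr(mol, prop_name)
    if w is None:
        raise FieldError(f"molecule {mol.id!r} lacks property {prop_name!r}")
    r = _distances(mol, grid)
    return -probe.comsia_weight(kind) * (np.exp(-probe.alpha * r**2) @ w)


def comfa_fields(
    mol: Molecule, grid: GridSpec, probe: ProbeSpec = DEFAULT_PROBE
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CoMFA steric and electrostatic columns plus the steric-exclusion mask.

    steric:  sum_i eps_ij * ((R_ij/r)^12 - 2 (R_ij/r)^6),  R_ij = R_i + R_probe,
             eps_ij = sqrt(eps_i * eps_probe), truncated to [-cutoff, +cutoff].
    elec:    sum_i 332.0636 * q_probe * q_i / (eps(r) * r) with eps(r) = r,
             truncated likewise; excluded points carry the mask for later
             mean substitution.
    A probe sitting exactly on an atom (r = 0) counts as steric exclusion.
    """
    if mol.charges is None or mol.lj_radius is None or mol.lj_epsilon is None:
        raise FieldError(f"molecule {mol.id!r} lacks charges or LJ parameters")
    r = _distances(mol, grid)
    cutoff = probe.energy_cutoff

    tiny = 1e-12
    r_safe = np.maximum(r, tiny)
    rij = mol.lj_radius + probe.lj_radius
    eps = np.sqrt(mol.lj_epsilon * probe.lj_epsilon)
    ratio6 = (rij / r_safe) ** 6
    steric = (eps * (ratio6**2 - 2.0 * ratio6)).sum(axis=1)
    steric = np.clip(steric, -cutoff, cutoff)
    excluded = steric >= cutoff

    elec = (COULOMB_CONSTANT * probe.charge * mol.charges / r_safe**2).sum(axis=1)
    elec = np.clip(elec, -cutoff, cutoff)
    elec[excluded] = 0.0  # placeholder; replaced by training-column mean later
    return steric, elec, excluded


# --------------------------------------------------------------------------
# field tables over a molecule set
# --------------------------------------------------------------------------

@dataclass
class FieldTable:
    """Per-field matrix (molecules x grid points) on a shared grid."""

    grid: GridSpec
    kind: str
    matrix: np.ndarray                    # (n_mols, n_points)
    mol_ids: tuple[str, ...]
    excluded: np.ndarray | None = None    # CoMFA electrostatic only


def compute_field_tables(
    mols: Sequence[Molecule],
    grid: GridSpec,
    probe: ProbeSpec = DEFAULT_PROBE,
    kinds: Sequence[str] = COMSIA_KINDS,
) -> dict[str, FieldTable]:
    """Evaluate the requested field kinds for every molecule."""
    ids = tuple(m.id for m in mols)
    out: dict[str, FieldTable] = {}
    want_comfa = any(k in COMFA_KINDS for k in kinds)
    if want_comfa:
        st, el, ex = [], [], []
        for m in mols:
            s, e, x = comfa_fields(m, grid, probe)
            st.append(s)
            el.append(e)
            ex.append(x)
        if "comfa_steric" in kinds:
            out["comfa_steric"] = FieldTable(grid, "comfa_steric", np.array(st), ids)
        if "comfa_electrostatic" in kinds:
            out["comfa_electrostatic"] = FieldTable(
                grid, "comfa_electrostatic", np.array(el), ids, excluded=np.array(ex)
            )
    for kind in kinds:
        if kind in COMSIA_KINDS:
            mat = np.array([comsia_field(m, grid, probe, kind) for m in mols])
            out[kind] = FieldTable(grid, kind, mat, ids)
    return out


# --------------------------------------------------------------------------
# block assembly: filtering + CoMFA-STD scaling
# --------------------------------------------------------------------------

@dataclass
class BlockInfo:
    """Metadata for one column block of the assembled X-matrix."""

    name: str
    cols: slice                       # columns of this block in X
    grid: GridSpec | None             # None for whole-molecule descriptors
    kept: np.ndarray | None           # grid-point indices retained (field blocks)
    scale: float                      # multiplicative block scale factor
    col_mean: np.ndarray | None = None  # 2D-descriptor autoscaling only
    col_std: np.ndarray | None = None


@dataclass
class DescriptorBlock:
    """The assembled X-matrix with per-block provenance and scaling metadata."""

    X: np.ndarray
    mol_ids: tuple[str, ...]
    blocks: list[BlockInfo]

    def block(self, name: str) -> BlockInfo:
        for b in self.blocks:
            if b.name == name:
                return b
        raise FieldError(f"no block named {name!r}")

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]


class BlockScaler(BaseEstimator, TransformerMixin):
    """Assemble field tables (+ optional 2D descriptors) into a scaled X-matrix.

    fit() learns, from the training set only: the low-variance column filter,
    the CoMFA electrostatic mean-substitution values inside the steric
    envelope, the per-block CoMFA-STD scale factors (each retained block is
    scaled to unit total variance), and the autoscaling of appended
    whole-molecule descriptor columns.  transform() applies the frozen
    parameters, so test molecules are mapped through the training scaling.

    Parameters
    ----------
    min_sigma : dict or float
        Minimum column standard deviation (field units); columns below it are
        dropped.  Defaults: 2.0 kcal/mol for CoMFA blocks, 0.0 for CoMSIA.
    """

    def __init__(self, min_sigma: float | Mapping[str, float] | None = None):
        self.min_sigma = min_sigma

    def _sigma_for(self, kind: str) -> float:
        if self.min_sigma is None:
            return 2.0 if kind in COMFA_KINDS else 0.0
        if isinstance(self.min_sigma, Mapping):
            return float(self.min_sigma.get(kind, 0.0))
        return float(self.min_sigma)

    def fit(
        self,
        tables: Mapping[str, FieldTable],
        extra: pd.DataFrame | None = None,
    ) -> "BlockScaler":
        self.kinds_ = list(tables.keys())
        self.elec_means_: np.ndarray | None = None
        self.kept_: dict[str, np.ndarray] = {}
        self.scales_: dict[str, float] = {}
        mats = self._substituted(tables, training=True)
        total_kept = 0
        for kind in self.kinds_:
            mat = mats[kind]
            sd = mat.std(axis=0, ddof=1)
            kept = np.flatnonzero(sd >= self._sigma_for(kind))
            self.kept_[kind] = kept
            total_kept += kept.size
            if kept.size:
                total_var = (sd[kept] ** 2).sum()
                self.scales_[kind] = 1.0 / np.sqrt(total_var) if total_var > 0 else 1.0
            else:
                self.scales_[kind] = 1.0
        if total_kept == 0:
            raise FieldError("all field columns were filtered out")
        if extra is not None:
            self.extra_names_ = list(extra.columns)
            vals = extra.to_numpy(dtype=float)
            self.extra_mean_ = vals.mean(axis=0)
            sd = vals.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                bad = [n for n, s in zip(self.extra_names_, sd) if s <= 0]
                raise FieldError(f"constant whole-molecule descriptor columns: {bad}")
            self.extra_std_ = sd
        else:
            self.extra_names_ = []
        return self

    def _substituted(
        self, tables: Mapping[str, FieldTable], training: bool
    ) -> dict[str, np.ndarray]:
        """Apply the electrostatic mean substitution inside steric exclusions."""
        mats: dict[str, np.ndarray] = {}
        for kind, tab in tables.items():
            mat = tab.matrix.astype(float).copy()
            if kind == "comfa_electrostatic":
                if tab.excluded is None:
                    raise FieldError("CoMFA electrostatic table lacks exclusion mask")
                ex = tab.excluded
                if training:
                    with np.errstate(invalid="ignore"):
                        masked = np.where(ex, np.nan, mat)
                        means = np.nanmean(masked, axis=0)
                    means = np.where(np.isfinite(means), means, 0.0)
                    self.elec_means_ = means
                if self.elec_means_ is None:
                    raise FieldError("BlockScaler not fitted (no electrostatic means)")
                mat = np.where(ex, self.elec_means_[None, :], mat)
            mats[kind] = mat
        return mats

    def transform(
        self,
        tables: Mapping[str, FieldTable],
        extra: pd.DataFrame | None = None,
    ) -> DescriptorBlock:
        if not hasattr(self, "kept_"):
            raise FieldError("BlockScaler must be fitted before transform")
        mats = self._substituted(tables, training=False)
        cols: list[np.ndarray] = []
        blocks: list[BlockInfo] = []
        start = 0
        ids = tables[self.kinds_[0]].mol_ids
        for kind in self.kinds_:
            kept = self.kept_[kind]
            scaled = mats[kind][:, kept] * self.scales_[kind]
            cols.append(scaled)
            blocks.append(
                BlockInfo(
                    name=kind,
                    cols=slice(start, start + kept.size),
                    grid=tables[kind].grid,
                    kept=kept,
                    scale=self.scales_[kind],
                )
            )
            start += kept.size
        if extra is not None:
            if list(extra.columns) != self.extra_names_:
                raise FieldError("extra descriptor columns differ from fit()")
            vals = extra.to_numpy(dtype=float)
            for j, name in enumerate(self.extra_names_):
                scaled = ((vals[:, j] - self.extra_mean_[j]) / self.extra_std_[j])[:, None]
                cols.append(scaled)
                blocks.append(
                    BlockInfo(
                        name=name,
                        cols=slice(start, start + 1),
                        grid=None,
                        kept=None,
                        scale=1.0 / self.extra_std_[j],
                        col_mean=self.extra_mean_[j : j + 1],
                        col_std=self.extra_std_[j : j + 1],
                    )
                )
                start += 1
        elif self.extra_names_:
            raise FieldError("fitted with extra descriptors but none supplied")
        X = np.hstack(cols) if cols else np.empty((len(ids), 0))
        return DescriptorBlock(X=X, mol_ids=ids, blocks=blocks)

    def fit_transform(
        self,
        tables: Mapping[str, FieldTable],
        extra: pd.DataFrame | None = None,
        **kwargs,
    ) -> DescriptorBlock:
        return self.fit(tables, extra).transform(tables, extra)


def scale_and_filter(
    tables: Mapping[str, FieldTable],
    method: str = "comfa_std",
    min_sigma: float | Mapping[str, float] | None = None,
    extra: pd.DataFrame | None = None,
) -> DescriptorBlock:
    """One-shot fit+transform block assembly (training-set semantics)."""
    if method not in ("comfa_std", "comsia_block"):
        raise FieldError(f"unknown scaling method {method!r}")
    return BlockScaler(min_sigma=min_sigma).fit_transform(tables, extra)
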