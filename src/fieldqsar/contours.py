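"""StDev*Coeff contour fields and their favored/disfavored levels.

After the PLS fit, every retained grid column of a field block is mapped back
to its lattice point as (training column standard deviation) x (PLS
coefficient); filtered columns are 0.  Because the block scale factor cancels
in the product, the map is identical whether computed on raw or scaled
columns.  Positive map values mark regions where raising the field value
raises the predicted activity ("favored"), negative values the opposite.

Contour levels follow a percentile-of-cumulative-|contribution| convention
(stated in the map metadata): the favored level at P% is the smallest
positive map value v such that points with values <= v carry P% of the total
positive contribution — i.e. points above the level carry the top (100-P)%.
The disfavored level mirrors this on the negative values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem_io import Molecule
from .fields import DescriptorBlock, FieldError, GridSpec
from .pls import PLSQSAR

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903

_ELEMENT_Z = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
    "Cl": 17, "Br": 35, "I": 53,
}


class ContourError(ValueError):
    pass


@dataclass
class ContourMap:
    """Per-grid-point StDev*Coeff values for one field kind."""

    grid: GridSpec
    kind: str
    values: np.ndarray            # (n_points,) in grid C-order
    convention: str = "percentile-of-cumulative-|contribution|"
    favored_level: float | None = None
    disfavored_level: float | None = None
    no_negative_values: bool = False

    def reshaped(self) -> np.ndarray:
        return self.values.reshape(self.grid.dims)


def stdev_coeff_map(model: PLSQSAR, block: DescriptorBlock, kind: str) -> ContourMap:
    """Build the StDev*Coeff lattice field for one field block."""
    try:
        info = block.block(kind)
    except FieldError as exc:
        raise ContourError(str(exc)) from exc
    if info.grid is None or info.kept is None:
        raise ContourError(f"block {kind!r} is not a lattice field block")
    weights = model.coef_[info.cols] * model._train_col_std_[info.cols]
    values = np.zeros(info.grid.n_points)
    values[info.kept] = weights
    return ContourMap(grid=info.grid, kind=kind, values=values)


def contour_levels(
    cmap: ContourMap, favored_pct: float = 80.0, disfavored_pct: float = 20.0
) -> tuple[float, float]:
    """Compute (favored_level, disfavored_level) and store them on the map.

    favored_level: points above it carry the top (100 - favored_pct)% of the
    positive |contribution| mass.  disfavored_level: points below it carry
    the top disfavored_pct% of the negative mass (mirror convention).  With
    no negative values the disfavored level is 0 and a warning flag is set.
    """
    v = cmap.values
    if not np.any(v != 0):
        raise ContourError("all-zero contour map has no levels")
    pos = np.sort(v[v > 0])
    neg = -v[v < 0]

    def mass_level(sorted_vals: np.ndarray, pct: float) -> float:
        cum = np.cumsum(sorted_vals)
        total = cum[-1]
        idx = int(np.searchsorted(cum, pct / 100.0 * total))
        idx = min(idx, len(sorted_vals) - 1)
        return float(sorted_vals[idx])

    if pos.size:
        favored = mass_level(pos, favored_pct)
    else:
        favored = 0.0
    if neg.size:
        disfavored = -mass_level(np.sort(neg), 100.0 - disfavored_pct)
        cmap.no_negative_values = False
    else:
        disfavored = 0.0
        cmap.no_negative_values = True
    cmap.favored_level = favored
    cmap.disfavored_level = disfavored
    cmap.convention = (
        f"percentile-of-cumulative-|contribution|: favored {favored_pct:g}%, "
        f"disfavored {disfavored_pct:g}%"
    )
    return favored, disfavored


def favored_center_of_mass(cmap: ContourMap) -> np.ndarray:
    """|value|-weighted centroid of the points at/above the favored level."""
    if cmap.favored_level is None:
        contour_levels(cmap)
    mask = cmap.values >= max(cmap.favored_level, 1e-300)
    if not mask.any():
        raise ContourError("no grid points above the favored level")
    pts = cmap.grid.points()[mask]
    w = cmap.values[mask]
    return (pts * w[:, None]).sum(axis=0) / w.sum()


# --------------------------------------------------------------------------
# Gaussian cube I/O
# --------------------------------------------------------------------------

def export_cube(
    cmap: ContourMap, path: str | Path, mol: Molecule | None = None
) -> None:
    """Write the map as a Gaussian cube file (lengths in Bohr, C-order values).

    If a molecule is given its atoms are written; otherwise a single dummy
    carbon at the grid origin keeps the file valid for standard viewers.
    """
    grid = cmap.grid
    o = np.asarray(grid.origin) * BOHR_PER_ANGSTROM
    step = grid.spacing * BOHR_PER_ANGSTROM
    if mol is not None:
        symbols = mol.elements
        coords = mol.coords * BOHR_PER_ANGSTROM
        atoms = [(_ELEMENT_Z.get(s, 6), c) for s, c in zip(symbols, coords)]
    else:
        atoms = [(6, o)]
    lines = [
        f"fieldqsar StDev*Coeff map: {cmap.kind}",
        cmap.convention,
        f"{len(atoms):5d} {o[0]:11.6f} {o[1]:11.6f} {o[2]:11.6f}",
        f"{grid.dims[0]:5d} {step:11.6f} {0.0:11.6f} {0.0:11.6f}",
        f"{grid.dims[1]:5d} {0.0:11.6f} {step:11.6f} {0.0:11.6f}",
        f"{grid.dims[2]:5d} {0.0:11.6f} {0.0:11.6f} {step:11.6f}",
    ]
    for z, c in atoms:
        lines.append(f"{z:5d} {0.0:11.6f} {c[0]:11.6f} {c[1]:11.6f} {c[2]:11.6f}")
    vals = cmap.values  # already C-order (x slowest, z fastest)
    for start in range(0, len(vals), 6):
        chunk = vals[start : start + 6]
        lines.append(" ".join(f"{x: .5E}" for x in chunk))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path: str | Path) -> ContourMap:
    """Re-import a cube file written by :func:`export_cube`."""
    lines = Path(path).read_text().splitlines()
    kind = lines[0].split(":")[-1].strip()
    natoms = int(lines[2].split()[0])
    origin = np.array([float(x) for x in lines[2].split()[1:4]]) / BOHR_PER_ANGSTROM
    dims = []
    steps = []
    for k in range(3):
        parts = lines[3 + k].split()
        dims.append(int(parts[0]))
        steps.append(float(parts[1 + k]) / BOHR_PER_ANGSTROM)
    if not np.allclose(steps, steps[0], atol=1e-9):
        raise ContourError("anisotropic cube spacing is not supported")
    data_lines = lines[6 + natoms :]
    vals = np.array([float(x) for line in data_lines for x in line.split()])
    grid = GridSpec(origin=tuple(origin.tolist()), spacing=steps[0],
                    dims=tuple(dims))
    if vals.size != grid.n_points:
        raise ContourError("cube data size does not match grid dims")
    return ContourMap(grid=grid, kind=kind, values=vals, convention=lines[1])
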