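"""Lattice molecular-interaction fields and column handling.

Two field families are computed on a shared rectangular lattice around the
aligned series:

* energy fields: a probe atom (+1 charge, sp3-carbon LJ parameters) samples
  the Lennard-Jones steric energy  sum_i [A_ij/r^12 - C_ij/r^6]  and the
  Coulomb electrostatic energy  sum_i k_e q_i q_probe / (D(r) r)  with a
  distance-dependent dielectric D(r) = r by default.  Both are clipped to
  +/- 30 kcal/mol; at points where the steric energy saturates (inside the
  molecular core) the electrostatic value is replaced by the per-molecule
  mean over unsaturated points, so singular values never dominate the
  regression.

* similarity fields: Gaussian-attenuated similarity indices
  A_k(q) = - sum_i W_probe,k W_ik exp(-alpha r_iq^2)  for five property kinds
  (steric, electrostatic, hydrophobic, H-bond donor, H-bond acceptor) with
  attenuation factor alpha = 0.3; these are finite everywhere and need no
  cutoff.

Columns whose variation across compounds falls below a threshold
(0.3 kcal/mol) are masked out; region focusing reweights the surviving
columns by their contribution to a fitted PLS model.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .prep import ATOM_LJ_PARAMS, Molecule3D

COULOMB_CONSTANT = 332.06  # kcal mol^-1 Angstrom e^-2

COMFA_KINDS = ("steric", "electrostatic")
COMSIA_KINDS = ("steric", "electrostatic", "hydrophobic", "hbd", "hba")


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned lattice: points at origin + index * spacing, x fastest."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def indices(self) -> np.ndarray:
        """(N, 3) integer lattice indices in x-fastest order."""
        nx, ny, nz = self.shape
        flat = np.arange(self.n_points)
        return np.stack([flat % nx, (flat // nx) % ny, flat // (nx * ny)], axis=1)

    def points(self) -> np.ndarray:
        """(N, 3) Cartesian lattice coordinates in x-fastest order."""
        return np.asarray(self.origin) + self.indices() * self.spacing


@dataclass(frozen=True)
class ProbeSpec:
    """Probe atom: +1 charge; sp3-carbon LJ parameters for energy fields."""

    charge: float = 1.0
    vdw_radius: float = ATOM_LJ_PARAMS["C"][0]
    well_depth: float = ATOM_LJ_PARAMS["C"][1]
    w_probe: dict[str, float] = dc_field(
        default_factory=lambda: {k: 1.0 for k in COMSIA_KINDS}
    )

    @classmethod
    def comfa_default(cls) -> "ProbeSpec":
        return cls()

    @classmethod
    def comsia_default(cls) -> "ProbeSpec":
        return cls(vdw_radius=1.0)


def make_grid(
    mols: list[Molecule3D], spacing: float = 2.0, margin: float = 4.0
) -> GridSpec:
    """Lattice enclosing all atoms plus a margin, centered on the centroid.

    The half-extent per axis is snapped outward to whole spacing steps so the
    centroid is itself a lattice point.
    """
    if not mols:
        raise ValueError("cannot build a grid for an empty molecule list")
    coords = np.vstack([m.coords for m in mols])
    center = coords.mean(axis=0)
    half = np.maximum(center - (coords.min(axis=0) - margin),
                      (coords.max(axis=0) + margin) - center)
    n_half = np.ceil(np.round(half / spacing, 9)).astype(int)
    origin = center - n_half * spacing
    shape = tuple(int(2 * n + 1) for n in n_half)
    return GridSpec(origin=tuple(float(v) for v in origin), spacing=float(spacing),
                    shape=shape)


def comfa_fields(
    mol: Molecule3D,
    grid: GridSpec,
    probe: ProbeSpec | None = None,
    dielectric: str = "distance",
    cutoff: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Steric (LJ) and electrostatic (Coulomb) probe energies at every point.

    Lorentz-Berthelot combination: r*_ij = r_i + r_probe,
    eps_ij = sqrt(eps_i eps_probe); A = eps r*^12, C = 2 eps r*^6, so the
    pair minimum is exactly -eps_ij at r*.
    """
    probe = probe or ProbeSpec.comfa_default()
    if mol.charges is None:
        raise ValueError("assign partial charges before computing energy fields")
    pts = grid.points()
    r = cdist(pts, mol.coords)
    r = np.maximum(r, 1e-6)
    rstar = mol.vdw_radius + probe.vdw_radius
    eps = np.sqrt(mol.well_depth * probe.well_depth)
    a6 = (rstar / r) ** 6
    steric = np.sum(eps * (a6 * a6 - 2.0 * a6), axis=1)
    steric = np.clip(steric, -cutoff, cutoff)
    if dielectric == "distance":
        elec = COULOMB_CONSTANT * probe.charge * np.sum(mol.charges / r**2, axis=1)
    elif dielectric == "constant":
        elec = COULOMB_CONSTANT * probe.charge * np.sum(mol.charges / r, axis=1)
    else:
        raise ValueError(f"unknown dielectric model {dielectric!r}")
    elec = np.clip(elec, -cutoff, cutoff)
    inside = steric >= cutoff
    if inside.any():
        fill = float(elec[~inside].mean()) if (~inside).any() else 0.0
        elec = np.where(inside, fill, elec)
    return steric, elec


def comsia_fields(
    mol: Molecule3D,
    grid: GridSpec,
    probe: ProbeSpec | None = None,
    alpha: float = 0.3,
    kinds: tuple[str, ...] = COMSIA_KINDS,
) -> dict[str, np.ndarray]:
    """Gaussian similarity indices for the requested property kinds."""
    probe = probe or ProbeSpec.comsia_default()
    pts = grid.points()
    r2 = cdist(pts, mol.coords, metric="sqeuclidean")
    g = np.exp(-alpha * r2)
    out = {}
    for kind in kinds:
        w = mol.property_values(kind)
        out[kind] = -probe.w_probe.get(kind, 1.0) * (g @ w)
    return out


@dataclass
class FieldMatrix:
    """Compounds x (lattice point x field kind) descriptor block.

    ``values`` holds raw field values; ``focus_weights`` rescale columns
    (region focusing); ``filter_mask`` False excludes a column from every
    downstream PLS computation.  The effective design matrix is
    ``values * focus_weights`` restricted to unmasked columns.
    """

    values: np.ndarray
    kinds: np.ndarray  # per-column field kind
    point_index: np.ndarray  # (n_cols, 3) lattice indices
    grid: GridSpec
    filter_mask: np.ndarray | None = None
    focus_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_cols = self.values.shape[1]
        if self.filter_mask is None:
            self.filter_mask = np.ones(n_cols, dtype=bool)
        if self.focus_weights is None:
            self.focus_weights = np.ones(n_cols)

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    def active_indices(self) -> np.ndarray:
        return np.flatnonzero(self.filter_mask)

    def design_matrix(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Weighted, masked matrix used by PLS."""
        X = self.values * self.focus_weights
        X = X[:, self.filter_mask]
        return X if rows is None else X[np.asarray(rows)]

    def column_labels(self) -> list[str]:
        return [
            f"{k}:{ix}:{iy}:{iz}"
            for k, (ix, iy, iz) in zip(self.kinds, self.point_index)
        ]


def build_field_matrix(
    mols: list[Molecule3D],
    grid: GridSpec,
    family: str = "comfa",
    probe: ProbeSpec | None = None,
    dielectric: str = "distance",
    cutoff: float = 30.0,
    alpha: float = 0.3,
) -> FieldMatrix:
    """Stack per-molecule fields into a compounds x columns matrix."""
    if family == "comfa":
        kinds = COMFA_KINDS
        rows = []
        for m in mols:
            s, e = comfa_fields(m, grid, probe, dielectric=dielectric, cutoff=cutoff)
            rows.append(np.concatenate([s, e]))
    elif family == "comsia":
        kinds = COMSIA_KINDS
        rows = []
        for m in mols:
            f = comsia_fields(m, grid, probe, alpha=alpha)
            rows.append(np.concatenate([f[k] for k in kinds]))
    else:
        raise ValueError(f"unknown field family {family!r}")
    values = np.vstack(rows)
    idx = grid.indices()
    kind_col = np.concatenate([np.repeat(k, grid.n_points) for k in kinds])
    point_col = np.vstack([idx] * len(kinds))
    return FieldMatrix(values=values, kinds=kind_col, point_index=point_col, grid=grid)


def column_filter(matrix: FieldMatrix, threshold: float = 0.3,
                  rows: np.ndarray | None = None) -> FieldMatrix:
    """Mask columns whose variation (max - min across compounds) < threshold.

    ``rows`` restricts the variation computation to a subset of compounds
    (e.g. the training set) while keeping the full matrix intact.
    """
    if matrix.n_compounds < 2:
        raise ValueError("column filtering needs at least 2 compounds")
    vals = matrix.values if rows is None else matrix.values[np.asarray(rows)]
    variation = vals.max(axis=0) - vals.min(axis=0)
    mask = matrix.filter_mask & (variation >= threshold)
    return replace(matrix, filter_mask=mask,
                   focus_weights=matrix.focus_weights.copy())


def region_focus(matrix: FieldMatrix, pls_model, exponent: float) -> FieldMatrix:
    """Reweight active columns by (normalized stdev x |coefficient|)^exponent.

    The caller refits PLS on the returned matrix; exponent 0 is the identity.
    """
    if exponent < 0:
        raise ValueError("focusing exponent must be nonnegative")
    X = matrix.design_matrix()
    sd = X.std(axis=0, ddof=1)
    contrib = sd * np.abs(pls_model.coefficients)
    top = contrib.max()
    w_active = np.zeros_like(contrib) if top == 0 else (contrib / top) ** exponent
    weights = matrix.focus_weights.copy()
    weights[matrix.filter_mask] = matrix.focus_weights[matrix.filter_mask] * w_active
    return replace(matrix, filter_mask=matrix.filter_mask.copy(), focus_weights=weights)
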