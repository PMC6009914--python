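"""3D structure preparation: embedding, charges, alignment, orientation search.

Molecules are embedded with seeded ETKDG and minimized with MMFF94 (UFF as a
fallback for atoms MMFF does not cover).  Partial charges are plain Gasteiger
charges.  Superposition onto a template uses the maximum common substructure
and a rigid Kabsch fit, mirroring shared-scaffold template alignment.

The all-orientation search scans a systematic Euler-angle lattice of proper
rotations of the whole aligned aggregate inside the grid frame and returns the
orientation with the highest leave-one-out q^2; ties are broken by the
smallest rotation angle, and the identity is always part of the scan, so the
objective never decreases relative to the input orientation.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdFMCS, rdMolDescriptors

from . import rules

#: per-element van der Waals radius (Angstrom, Bondi) and LJ well depth
#: (kcal/mol, Amber-style); pinned table version 1.0.
ATOM_LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.20, 0.0157),
    "C": (1.70, 0.1094),
    "N": (1.55, 0.1700),
    "O": (1.52, 0.2100),
    "F": (1.47, 0.0610),
    "P": (1.80, 0.2000),
    "S": (1.80, 0.2500),
    "Cl": (1.75, 0.2650),
    "Br": (1.85, 0.3200),
    "I": (1.98, 0.4000),
}


@dataclass
class Molecule3D:
    """A charged, property-typed 3D molecule ready for field computation.

    Per-atom property values feed the similarity fields: ``w_steric``
    (vdW radius cubed), ``w_electrostatic`` (partial charge), ``w_hydrophobic``
    (atomic logP contribution), and donor/acceptor indicator flags.
    """

    rdkit_mol: Chem.Mol | None
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) Angstrom
    charges: np.ndarray | None = None  # elementary charges
    net_charge: int = 0
    vdw_radius: np.ndarray | None = None  # Angstrom
    well_depth: np.ndarray | None = None  # kcal/mol
    w_hydrophobic: np.ndarray | None = None
    is_hbd: np.ndarray | None = None
    is_hba: np.ndarray | None = None
    is_aromatic: np.ndarray | None = None
    name: str = ""
    alignment_rmsd: float | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def w_steric(self) -> np.ndarray:
        if self.vdw_radius is None:
            raise ValueError("vdW radii not populated")
        return self.vdw_radius**3

    @property
    def w_electrostatic(self) -> np.ndarray:
        if self.charges is None:
            raise ValueError("partial charges not assigned")
        return self.charges

    def property_values(self, kind: str) -> np.ndarray:
        """Per-atom W_ik for one similarity-field kind."""
        table = {
            "steric": lambda: self.w_steric,
            "electrostatic": lambda: self.w_electrostatic,
            "hydrophobic": lambda: self.w_hydrophobic,
            "hbd": lambda: None if self.is_hbd is None else self.is_hbd.astype(float),
            "hba": lambda: None if self.is_hba is None else self.is_hba.astype(float),
        }
        if kind not in table:
            raise KeyError(f"unknown field kind {kind!r}")
        vals = table[kind]()
        if vals is None:
            raise ValueError(f"per-atom property table {kind!r} not populated")
        return np.asarray(vals, dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule3D":
        """Rigidly transformed copy: x -> R x + t."""
        new_coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        mol = replace(self, coords=new_coords)
        if self.rdkit_mol is not None:
            rd = Chem.Mol(self.rdkit_mol)
            conf = rd.GetConformer()
            for i, xyz in enumerate(new_coords):
                conf.SetAtomPosition(i, [float(v) for v in xyz])
            mol.rdkit_mol = rd
        return mol


def _populate_atom_properties(mol: Molecule3D) -> None:
    rd = mol.rdkit_mol
    radii, eps = [], []
    unknown = []
    for a in rd.GetAtoms():
        sym = a.GetSymbol()
        if sym not in ATOM_LJ_PARAMS:
            unknown.append(f"{sym}{a.GetIdx()}")
            radii.append(1.7)
            eps.append(0.1)
        else:
            r, e = ATOM_LJ_PARAMS[sym]
            radii.append(r)
            eps.append(e)
    if unknown:
        raise ValueError(f"no LJ parameters for atoms: {', '.join(unknown)}")
    mol.vdw_radius = np.array(radii)
    mol.well_depth = np.array(eps)
    contribs = rdMolDescriptors._CalcCrippenContribs(rd)
    mol.w_hydrophobic = np.array([c[0] for c in contribs])
    donors = rules.donor_atom_ids(rd)
    acceptors = rules.acceptor_atom_ids(rd)
    n = rd.GetNumAtoms()
    mol.is_hbd = np.array([i in donors for i in range(n)])
    mol.is_hba = np.array([i in acceptors for i in range(n)])
    mol.is_aromatic = np.array([a.GetIsAromatic() for a in rd.GetAtoms()])


def from_rdkit(rd: Chem.Mol, name: str = "") -> Molecule3D:
    """Wrap an RDKit molecule (with a conformer) as a Molecule3D."""
    if rd.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformer")
    coords = rd.GetConformer().GetPositions().copy()
    mol = Molecule3D(
        rdkit_mol=rd,
        elements=[a.GetSymbol() for a in rd.GetAtoms()],
        coords=coords,
        net_charge=Chem.GetFormalCharge(rd),
        name=name,
    )
    _populate_atom_properties(mol)
    return mol


def embed_and_minimize(smiles: str, seed: int = 2024, name: str = "") -> Molecule3D:
    """One seeded low-energy 3D conformer with explicit hydrogens."""
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    rd = Chem.AddHs(rd)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    if AllChem.EmbedMolecule(rd, params) != 0:
        # retry with random coordinates before giving up
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(rd, params) != 0:
            raise ValueError(f"3D embedding failed for SMILES: {smiles!r}")
    try:
        if AllChem.MMFFHasAllMoleculeParams(rd):
            AllChem.MMFFOptimizeMolecule(rd, maxIters=500)
        else:
            AllChem.UFFOptimizeMolecule(rd, maxIters=500)
    except Exception:  # minimization failure leaves the embedded geometry
        pass
    return from_rdkit(rd, name=name or smiles)


def assign_partial_charges(mol: Molecule3D) -> Molecule3D:
    """Populate Gasteiger partial charges (conserving the net formal charge)."""
    rd = Chem.Mol(mol.rdkit_mol)
    AllChem.ComputeGasteigerCharges(rd)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in rd.GetAtoms()])
    bad = [i for i, v in enumerate(q) if not np.isfinite(v)]
    if bad:
        raise ValueError(f"Gasteiger charges undefined for atoms {bad}")
    out = replace(mol, charges=q, rdkit_mol=rd)
    total = q.sum()
    if abs(total - mol.net_charge) > 1e-3:
        raise ValueError(
            f"charge conservation violated: sum(q)={total:.5f}, net={mol.net_charge}"
        )
    return out


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of points P onto Q.

    Returns (R, t, rmsd) such that ``P @ R.T + t`` best matches Q and R is a
    proper rotation.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


@functools.lru_cache(maxsize=2048)
def _mcs_smarts_cached(smiles_a: str, smiles_b: str, timeout: int) -> str:
    res = rdFMCS.FindMCS(
        [Chem.MolFromSmiles(smiles_a), Chem.MolFromSmiles(smiles_b)],
        timeout=timeout,
        ringMatchesRingOnly=True,
        completeRingsOnly=False,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrder,
    )
    return res.smartsString or ""


def _mcs_query(a: Chem.Mol, b: Chem.Mol, timeout: int = 10) -> Chem.Mol:
    # MCS depends only on topology; cache on heavy-atom canonical SMILES
    sa = Chem.MolToSmiles(Chem.RemoveHs(a))
    sb = Chem.MolToSmiles(Chem.RemoveHs(b))
    smarts = _mcs_smarts_cached(sa, sb, timeout)
    return Chem.MolFromSmarts(smarts) if smarts else None


def align_to_template(
    mol: Molecule3D, template: Molecule3D, max_matches: int = 16
) -> Molecule3D:
    """Rigidly superpose ``mol`` onto ``template`` over their MCS atoms.

    All combinations of substructure matches (capped) are tried and the one
    with the lowest RMSD wins; the RMSD is stored on the returned molecule.
    """
    query = _mcs_query(mol.rdkit_mol, template.rdkit_mol)
    if query is None or query.GetNumAtoms() < 3:
        raise ValueError("no common substructure of >= 3 atoms for alignment")
    m_matches = mol.rdkit_mol.GetSubstructMatches(
        query, uniquify=True, maxMatches=max_matches
    )
    t_matches = template.rdkit_mol.GetSubstructMatches(
        query, uniquify=True, maxMatches=max_matches
    )
    if not m_matches or not t_matches:
        raise ValueError("common substructure match failed during alignment")
    best = None
    for mm, tm in itertools.product(m_matches, t_matches):
        R, t, rmsd = kabsch(mol.coords[list(mm)], template.coords[list(tm)])
        if best is None or rmsd < best[2]:
            best = (R, t, rmsd)
    R, t, rmsd = best
    out = mol.transformed(R, t)
    out.alignment_rmsd = rmsd
    return out


def embed_constrained(
    smiles: str, template: Molecule3D, seed: int = 2024, name: str = ""
) -> Molecule3D:
    """Embed a conformer with the template's MCS core frozen at its coordinates.

    This is the tight-superposition analogue of field-fit alignment for a
    shared-scaffold series: the common substructure inherits the template's
    geometry exactly and only the variable substituents are embedded freely
    (then force-field relaxed under core restraints).  Falls back to free
    embedding plus rigid MCS alignment when constrained embedding fails.
    """
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    molH = Chem.AddHs(rd)
    query = _mcs_query(molH, template.rdkit_mol)
    if query is None or query.GetNumAtoms() < 3:
        raise ValueError("no common substructure of >= 3 atoms for alignment")
    tmatch = template.rdkit_mol.GetSubstructMatch(query)
    core = Chem.RWMol(query)
    conf = Chem.Conformer(core.GetNumAtoms())
    for i, ti in enumerate(tmatch):
        conf.SetAtomPosition(i, [float(v) for v in template.coords[ti]])
    core.AddConformer(conf)
    try:
        AllChem.ConstrainedEmbed(molH, core, randomseed=int(seed) & 0x7FFFFFFF)
        out = from_rdkit(molH, name=name or smiles)
    except Exception:
        free = embed_and_minimize(smiles, seed=seed, name=name)
        out = align_to_template(free, template)
    return out


@dataclass
class Orientation:
    """A proper rotation (plus translation) of the aggregate in the grid frame."""

    rotation: np.ndarray
    translation: np.ndarray
    objective_value: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-8):
            raise ValueError("rotation must be proper (det +1)")


def _euler_rotations(step_degrees: float) -> list[np.ndarray]:
    """Deduplicated proper rotations on a systematic z-y-z Euler lattice."""
    if step_degrees <= 0 or (360.0 / step_degrees) % 1 > 1e-9:
        raise ValueError("step must be positive and divide 360")
    angles = np.arange(0.0, 360.0, step_degrees)
    seen: dict[tuple, np.ndarray] = {}
    for a, b, c in itertools.product(angles, angles, angles):
        R = _rot_z(c) @ _rot_y(b) @ _rot_z(a)
        key = tuple(np.round(R, 6).ravel())
        if key not in seen:
            seen[key] = R
    return list(seen.values())


def _rot_z(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_angle(R: np.ndarray) -> float:
    """Geodesic rotation angle of a rotation matrix, in degrees."""
    c = (float(np.trace(R)) - 1.0) / 2.0
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def orientation_search(
    mols: list[Molecule3D],
    y: np.ndarray,
    descriptor_fn,
    step_degrees: float = 30.0,
    n_components: int = 3,
    tol: float = 1e-12,
) -> Orientation:
    """Scan aggregate rotations and return the one maximizing LOO q^2.

    ``descriptor_fn(mols) -> X`` recomputes the descriptor block for a rotated
    aggregate (typically a fresh grid plus lattice fields).  Rotations are
    applied about the aggregate centroid; the identity is always scanned, and
    exact ties are broken by the smallest rotation angle.
    """
    from .pls import loo_q2  # late import to avoid a cycle

    if len(mols) < 6:
        raise ValueError("orientation search needs at least 6 molecules")
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("activity vector has zero variance")
    centroid = np.vstack([m.coords for m in mols]).mean(axis=0)
    best: tuple[float, float, np.ndarray] | None = None
    for R in _euler_rotations(step_degrees):
        t = centroid - R @ centroid
        rotated = [m.transformed(R, t) for m in mols]
        X = descriptor_fn(rotated)
        q2, _ = loo_q2(X, y, n_components)
        ang = rotation_angle(R)
        if (
            best is None
            or q2 > best[0] + tol
            or (abs(q2 - best[0]) <= tol and ang < best[1])
        ):
            best = (q2, ang, R)
    q2, _, R = best
    return Orientation(rotation=R, translation=centroid - R @ centroid, objective_value=q2)
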