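"""Pinned substructure rules for chemical feature typing (version 1.0).

Shared between the field engine (per-atom donor/acceptor/hydrophobe property
values) and the pharmacophore module (feature point detection), so that a
lattice field and a pharmacophore built from the same molecule agree on what
counts as a donor or acceptor.

Rules (deliberately simple, indicator-based):

* donor      - any N or O carrying at least one hydrogen;
* acceptor   - any O; aromatic N without H (pyridine-type); sp2/sp3 N without
               H that is not an amide/sulfonamide nitrogen and not positively
               charged; nitrile N;
* aromatic   - ring whose atoms are all flagged aromatic (feature at centroid);
* hydrophobe - connected cluster of >= 3 carbon atoms, plus halogens attached
               to aromatic carbons.
"""

from rdkit import Chem

RULES_VERSION = "1.0"

DONOR_SMARTS = "[#7!H0,#8!H0]"

ACCEPTOR_SMARTS = (
    "[$([#8]),"
    "$([nX2H0]),"
    "$([NX3H0;!$([NX3][CX3]=[OX1]);!$([NX3][SX4](=[OX1])=[OX1]);!$([N+])]),"
    "$([NX2H0;!$([N+])]),"
    "$([NX1])]"
)

AROMATIC_HALOGEN_SMARTS = "[F,Cl,Br,I;$(*c)]"

_DONOR_Q = Chem.MolFromSmarts(DONOR_SMARTS)
_ACCEPTOR_Q = Chem.MolFromSmarts(ACCEPTOR_SMARTS)
_AR_HALOGEN_Q = Chem.MolFromSmarts(AROMATIC_HALOGEN_SMARTS)


def donor_atom_ids(mol: Chem.Mol) -> set[int]:
    return {m[0] for m in mol.GetSubstructMatches(_DONOR_Q)}


def acceptor_atom_ids(mol: Chem.Mol) -> set[int]:
    return {m[0] for m in mol.GetSubstructMatches(_ACCEPTOR_Q)}


def aromatic_halogen_ids(mol: Chem.Mol) -> set[int]:
    return {m[0] for m in mol.GetSubstructMatches(_AR_HALOGEN_Q)}


def hydrophobe_clusters(mol: Chem.Mol, min_size: int = 3) -> list[list[int]]:
    """Connected components of the carbon-only subgraph with >= min_size atoms."""
    carbon = {a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "C"}
    seen: set[int] = set()
    clusters = []
    for start in sorted(carbon):
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            idx = stack.pop()
            comp.append(idx)
            for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
                j = nbr.GetIdx()
                if j in carbon and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(comp) >= min_size:
            clusters.append(sorted(comp))
    return clusters


def aromatic_rings(mol: Chem.Mol) -> list[tuple[int, ...]]:
    info = mol.GetRingInfo()
    rings = []
    for ring in info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            rings.append(ring)
    return rings
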