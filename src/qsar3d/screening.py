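"""Virtual-screening funnel: descriptors, rule filters, pharmacophores.

The funnel mirrors a classical ligand-based screening cascade for zinc-binding
sulfonamide inhibitors: a common-feature pharmacophore built from the most
active aligned compounds is used as a 3D query; candidates passing it are
checked against Lipinski's rule of five, against drug-like descriptor ranges,
and finally triaged in PCA chemical space by Euclidean similarity.

Feature detection follows the pinned substructure rules in
:mod:`qsar3d.rules` (donors, acceptors, aromatic ring centroids, hydrophobic
carbon clusters and aromatic halogens).  Molecular weight is computed from a
pinned table of standard atomic masses (CIAAW 2021 abridged values); logP is
Crippen's atomic-contribution scheme, TPSA the fragment-contribution polar
surface area, and H-bond donor/acceptor counts the N,O-based rule-of-five
counting rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Lipinski as rdLipinski, rdMolDescriptors
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from . import rules
from .prep import Molecule3D

#: standard atomic masses (CIAAW 2021 abridged), pinned for reproducible MW.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.90,
    "B": 10.81, "Si": 28.085,
}

PRIMARY_SULFONAMIDE_SMARTS = "[SX4](=O)(=O)[NX3H2]"
_PRIMARY_SULFONAMIDE_Q = Chem.MolFromSmarts(PRIMARY_SULFONAMIDE_SMARTS)


def _as_rdkit(mol) -> Chem.Mol:
    if isinstance(mol, Molecule3D):
        return mol.rdkit_mol
    if isinstance(mol, Chem.Mol):
        return mol
    rd = Chem.MolFromSmiles(mol)
    if rd is None:
        raise ValueError(f"unparsable SMILES: {mol!r}")
    return rd


@dataclass(frozen=True)
class DescriptorVector:
    """Drug-likeness descriptors for one molecule."""

    mw: float  # Da
    logp: float
    hbd_count: int
    hba_count: int
    tpsa: float  # Angstrom^2
    rotatable_bonds: int
    has_primary_sulfonamide: bool

    def as_dict(self) -> dict[str, float]:
        return {
            "mw": self.mw,
            "logp": self.logp,
            "hbd_count": self.hbd_count,
            "hba_count": self.hba_count,
            "tpsa": self.tpsa,
            "rotatable_bonds": self.rotatable_bonds,
        }


def molecular_weight(rd: Chem.Mol) -> float:
    """MW from the pinned standard atomic masses, hydrogens included."""
    total = 0.0
    for atom in rd.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ATOMIC_MASS:
            raise ValueError(f"no standard mass for element {sym!r}")
        total += ATOMIC_MASS[sym] + atom.GetTotalNumHs() * ATOMIC_MASS["H"]
    return total


def compute_descriptors(mol) -> DescriptorVector:
    """Descriptor vector for a Molecule3D, RDKit mol, or SMILES."""
    rd = _as_rdkit(mol)
    return DescriptorVector(
        mw=molecular_weight(rd),
        logp=float(Crippen.MolLogP(rd)),
        hbd_count=int(rdLipinski.NumHDonors(rd)),
        hba_count=int(rdLipinski.NumHAcceptors(rd)),
        tpsa=float(rdMolDescriptors.CalcTPSA(rd)),
        rotatable_bonds=int(rdMolDescriptors.CalcNumRotatableBonds(rd)),
        has_primary_sulfonamide=rd.HasSubstructMatch(_PRIMARY_SULFONAMIDE_Q),
    )


@dataclass
class FilterReport:
    """Per-rule outcomes; overall pass is the conjunction of all rules."""

    rules: dict[str, tuple[bool, float, str]] = dc_field(default_factory=dict)

    def add(self, name: str, passed: bool, value: float, threshold: str) -> None:
        self.rules[name] = (bool(passed), float(value), threshold)

    @property
    def overall_pass(self) -> bool:
        return all(passed for passed, _, _ in self.rules.values())


def lipinski_filter(d: DescriptorVector) -> FilterReport:
    """Rule of five: MW < 500; logP <= 5; HBD <= 5; HBA <= 10 (no short-circuit)."""
    report = FilterReport()
    report.add("mw", d.mw < 500.0, d.mw, "< 500")
    report.add("logp", d.logp <= 5.0, d.logp, "<= 5")
    report.add("hbd", d.hbd_count <= 5, d.hbd_count, "<= 5")
    report.add("hba", d.hba_count <= 10, d.hba_count, "<= 10")
    return report


def default_descriptor_ranges() -> dict[str, tuple[float, float]]:
    """Shipped drug-like ranges for locally computable descriptors."""
    path = resources.files("qsar3d.data").joinpath("descriptor_ranges.csv")
    df = pd.read_csv(path)
    return {
        str(r.descriptor): (float(r.lower), float(r.upper))
        for r in df.itertuples(index=False)
    }


def range_filter(
    d: DescriptorVector | dict, ranges: dict[str, tuple[float, float]] | None = None
) -> FilterReport:
    """Inclusive-interval check for every descriptor present in both tables.

    ``d`` may carry extra externally supplied descriptors (e.g. logBB) as a
    dict; unknown names in the ranges table raise a configuration error only
    when they collide with nothing computable and nothing supplied is fine.
    """
    values = d.as_dict() if isinstance(d, DescriptorVector) else dict(d)
    if ranges is None:
        ranges = default_descriptor_ranges()
    report = FilterReport()
    for name, (lo, hi) in ranges.items():
        if name not in values:
            continue
        v = float(values[name])
        report.add(name, lo <= v <= hi, v, f"[{lo}, {hi}]")
    return report


# ---------------------------------------------------------------------------
# pharmacophore model
# ---------------------------------------------------------------------------

FEATURE_KINDS = ("HBD", "HBA", "aromatic", "hydrophobe")


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    center: tuple[float, float, float]
    tolerance: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class PharmacophoreModel:
    features: list[PharmacophoreFeature]
    min_features_required: int = 4
    max_features: int = 10

    def __post_init__(self) -> None:
        if not (
            self.min_features_required <= len(self.features) <= self.max_features
        ):
            raise ValueError(
                f"model must carry between {self.min_features_required} and "
                f"{self.max_features} features, got {len(self.features)}"
            )


def detect_features(mol: Molecule3D) -> list[PharmacophoreFeature]:
    """Feature points for one aligned 3D molecule (pinned rule set)."""
    rd = mol.rdkit_mol
    coords = mol.coords
    feats: list[PharmacophoreFeature] = []
    for idx in sorted(rules.donor_atom_ids(rd)):
        feats.append(PharmacophoreFeature("HBD", tuple(coords[idx])))
    for idx in sorted(rules.acceptor_atom_ids(rd)):
        feats.append(PharmacophoreFeature("HBA", tuple(coords[idx])))
    for ring in rules.aromatic_rings(rd):
        feats.append(PharmacophoreFeature("aromatic", tuple(coords[list(ring)].mean(axis=0))))
    for cluster in rules.hydrophobe_clusters(rd):
        feats.append(
            PharmacophoreFeature("hydrophobe", tuple(coords[cluster].mean(axis=0)))
        )
    for idx in sorted(rules.aromatic_halogen_ids(rd)):
        feats.append(PharmacophoreFeature("hydrophobe", tuple(coords[idx])))
    return feats


def build_pharmacophore(
    actives: list[Molecule3D],
    merge_radius: float = 1.5,
    min_features: int = 4,
    max_features: int = 10,
    tolerance: float = 1.0,
) -> PharmacophoreModel:
    """Common-feature model from aligned actives.

    Features of the same kind across molecules are single-linkage clustered
    at the merge radius; only clusters populated by every active survive.
    Cluster centroids become feature centers; if more than ``max_features``
    clusters survive, the tightest (smallest spread) are kept.
    """
    if len(actives) < 2:
        raise ValueError("need at least 2 aligned actives")
    candidates: list[tuple[float, PharmacophoreFeature]] = []
    for kind in FEATURE_KINDS:
        pts, owner = [], []
        for mi, mol in enumerate(actives):
            for f in detect_features(mol):
                if f.kind == kind:
                    pts.append(f.center)
                    owner.append(mi)
        if not pts:
            continue
        pts_arr = np.asarray(pts)
        owner_arr = np.asarray(owner)
        if len(pts_arr) == 1:
            labels = np.array([1])
        else:
            labels = fcluster(
                linkage(pts_arr, method="single"), t=merge_radius, criterion="distance"
            )
        for lab in np.unique(labels):
            sel = labels == lab
            if set(owner_arr[sel]) != set(range(len(actives))):
                continue  # not common to all actives
            center = pts_arr[sel].mean(axis=0)
            spread = float(np.max(np.linalg.norm(pts_arr[sel] - center, axis=1)))
            candidates.append(
                (spread, PharmacophoreFeature(kind, tuple(center), tolerance))
            )
    if len(candidates) < min_features:
        raise ValueError(
            f"only {len(candidates)} common feature clusters found; "
            "consider a larger merge radius"
        )
    candidates.sort(key=lambda sf: sf[0])
    features = [f for _, f in candidates[:max_features]]
    return PharmacophoreModel(
        features=features,
        min_features_required=min_features,
        max_features=max_features,
    )


def match_pharmacophore(
    mol: Molecule3D, model: PharmacophoreModel
) -> tuple[bool, int, dict[int, int]]:
    """Greedy nearest-first one-to-one matching of molecule vs model features.

    A pair matches when the molecule feature lies within the model feature's
    tolerance (closed ball).  Returns (pass, matched count, mapping of model
    feature index -> molecule feature index).
    """
    mol_feats = detect_features(mol)
    pairs = []
    for i, mf in enumerate(model.features):
        for j, f in enumerate(mol_feats):
            if f.kind != mf.kind:
                continue
            dist = float(np.linalg.norm(np.array(f.center) - np.array(mf.center)))
            if dist <= mf.tolerance:
                pairs.append((dist, i, j))
    pairs.sort()
    used_model: set[int] = set()
    used_mol: set[int] = set()
    mapping: dict[int, int] = {}
    for _, i, j in pairs:
        if i in used_model or j in used_mol:
            continue
        used_model.add(i)
        used_mol.add(j)
        mapping[i] = j
    matched = len(mapping)
    return matched >= model.min_features_required, matched, mapping


def chemical_space_select(
    descriptors: np.ndarray | pd.DataFrame,
    k_similar: int,
    k_dissimilar: int,
) -> tuple[list, list]:
    """Similar / dissimilar selection in 2D PCA score space.

    Rows are standardized, projected onto the first two principal axes;
    "similar" compounds are members of the closest pairs (deduplicated in
    rank order), "dissimilar" ones lie farthest from the score centroid.
    Ties break by row id.
    """
    from sklearn.decomposition import PCA

    if isinstance(descriptors, pd.DataFrame):
        ids = list(descriptors.index)
        X = descriptors.to_numpy(dtype=float)
    else:
        X = np.asarray(descriptors, dtype=float)
        ids = list(range(len(X)))
    if len(X) < k_similar + k_dissimilar:
        raise ValueError("not enough rows for the requested selection sizes")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("constant descriptor matrix has no principal axes")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    scores = PCA(n_components=min(2, Z.shape[1])).fit_transform(Z)
    D = squareform(pdist(scores))
    iu = np.triu_indices(len(X), k=1)
    order = np.lexsort((iu[1], iu[0], D[iu]))  # distance, then row ids
    similar: list = []
    for idx in order:
        for member in (iu[0][idx], iu[1][idx]):
            if ids[member] not in similar:
                similar.append(ids[member])
            if len(similar) >= k_similar:
                break
        if len(similar) >= k_similar:
            break
    centroid = scores.mean(axis=0)
    dist_c = np.linalg.norm(scores - centroid, axis=1)
    far_order = np.lexsort((np.arange(len(X)), -dist_c))
    dissimilar = [ids[i] for i in far_order[:k_dissimilar]]
    return similar, dissimilar
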