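import numpy as np


def single_atom(element="C", coords=(0.0, 0.0, 0.0), charge=0.0, w=None):
    """Minimal Molecule3D stub for closed-form field checks."""
    from qsar3d.prep import ATOM_LJ_PARAMS, Molecule3D

    r, e = ATOM_LJ_PARAMS[element]
    return Molecule3D(
        rdkit_mol=None,
        elements=[element],
        coords=np.asarray([coords], dtype=float),
        charges=np.array([charge]),
        vdw_radius=np.array([r]),
        well_depth=np.array([e]),
        w_hydrophobic=np.zeros(1) if w is None else np.array([w]),
        is_hbd=np.zeros(1, dtype=bool),
        is_hba=np.zeros(1, dtype=bool),
        is_aromatic=np.zeros(1, dtype=bool),
    )
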