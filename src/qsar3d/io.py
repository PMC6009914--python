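"""Readers and writers for the interchange formats.

Formats: activity CSV (compound identity, Ki in nM, split flags), SDF for
molecule ensembles (partial charges in atom properties), field-matrix CSV
with ``kind:ix:iy:iz`` column keys plus a JSON grid sidecar, JSON for PLS
models and pharmacophores, OpenDX scalar fields and PDB pseudo-atoms for
contour visualization.  Every artifact embeds the pipeline config hash in a
header comment (CSV/PDB/DX) or a top-level field (JSON); numeric output is
printed at 6 decimals so runs are diff-able.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .datasets import CompoundRecord, compose_smiles
from .fields import FieldMatrix, GridSpec
from .pls import ContourSet, PLSModelState
from .prep import Molecule3D, from_rdkit
from .screening import PharmacophoreFeature, PharmacophoreModel


def read_activity_csv(path) -> list[CompoundRecord]:
    """Parse an activity table into CompoundRecords.

    Requires ``compound_id`` and ``ki_nM`` columns; structures come from a
    ``smiles`` column or are composed from ``scaffold_id`` + ``r1_name``.
    Errors name the offending line.
    """
    path = Path(path)
    records = []
    with path.open(newline="") as fh:
        rows = [r for r in csv.DictReader(filter(lambda l: not l.startswith("#"), fh))]
    if not rows:
        raise ValueError(f"{path}: empty activity table")
    required = {"compound_id", "ki_nM"}
    missing = required - set(rows[0])
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for lineno, row in enumerate(rows, start=2):
        try:
            ki = float(row["ki_nM"])
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: non-numeric Ki {row['ki_nM']!r}"
            ) from None
        if ki <= 0:
            raise ValueError(f"{path}:{lineno}: Ki must be positive, got {ki}")
        if row.get("smiles"):
            smiles = row["smiles"]
        elif row.get("scaffold_id") and row.get("r1_name"):
            smiles = compose_smiles(row["scaffold_id"], row["r1_name"])
        else:
            raise ValueError(
                f"{path}:{lineno}: need a smiles column or scaffold_id + r1_name"
            )
        records.append(
            CompoundRecord(
                compound_id=int(row["compound_id"]),
                scaffold_id=row.get("scaffold_id", ""),
                r1_name=row.get("r1_name", ""),
                smiles=smiles,
                ki_nM=ki,
                split={
                    "comfa": row.get("comfa_split", "train"),
                    "comfarf": row.get("comfarf_split", "train"),
                    "comsia": row.get("comsia_split", "train"),
                },
            )
        )
    return records


def write_activity_csv(path, records: list[CompoundRecord],
                       config_hash: str = "") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        w = csv.writer(fh)
        w.writerow(
            ["compound_id", "scaffold_id", "r1_name", "smiles", "ki_nM",
             "comfa_split", "comfarf_split", "comsia_split"]
        )
        for r in records:
            w.writerow(
                [r.compound_id, r.scaffold_id, r.r1_name, r.smiles, r.ki_nM,
                 r.split["comfa"], r.split["comfarf"], r.split["comsia"]]
            )


def write_sdf(path, mols: list[Molecule3D], config_hash: str = "") -> None:
    """Multi-molecule SDF with Gasteiger charges as an atom property list."""
    writer = Chem.SDWriter(str(path))
    try:
        for m in mols:
            rd = Chem.Mol(m.rdkit_mol)
            if m.charges is not None:
                rd.SetProp(
                    "partial_charges",
                    " ".join(f"{q:.6f}" for q in m.charges),
                )
            if config_hash:
                rd.SetProp("config_hash", config_hash)
            rd.SetProp("_Name", m.name)
            writer.write(rd)
    finally:
        writer.close()


def read_sdf(path) -> list[Molecule3D]:
    out = []
    for rd in Chem.SDMolSupplier(str(path), removeHs=False):
        if rd is None:
            continue
        mol = from_rdkit(rd, name=rd.GetProp("_Name") if rd.HasProp("_Name") else "")
        if rd.HasProp("partial_charges"):
            mol.charges = np.array(
                [float(v) for v in rd.GetProp("partial_charges").split()]
            )
        out.append(mol)
    return out


def write_field_matrix(path, fm: FieldMatrix, ids=None, config_hash: str = "") -> None:
    """Field matrix CSV (kind:ix:iy:iz columns) + JSON grid sidecar."""
    path = Path(path)
    df = pd.DataFrame(np.round(fm.values, 6), columns=fm.column_labels())
    df.insert(0, "compound_id", ids if ids is not None else range(fm.n_compounds))
    with path.open("w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.6f")
    sidecar = {
        "config_hash": config_hash,
        "grid": {"origin": list(fm.grid.origin), "spacing": fm.grid.spacing,
                 "shape": list(fm.grid.shape)},
        "filter_mask": fm.filter_mask.astype(int).tolist(),
        "focus_weights": np.round(fm.focus_weights, 6).tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_field_matrix(path) -> tuple[FieldMatrix, list]:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    ids = df["compound_id"].tolist()
    cols = [c for c in df.columns if c != "compound_id"]
    kinds, pts = [], []
    for c in cols:
        kind, ix, iy, iz = c.split(":")
        kinds.append(kind)
        pts.append((int(ix), int(iy), int(iz)))
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = GridSpec(
        origin=tuple(sidecar["grid"]["origin"]),
        spacing=sidecar["grid"]["spacing"],
        shape=tuple(sidecar["grid"]["shape"]),
    )
    fm = FieldMatrix(
        values=df[cols].to_numpy(dtype=float),
        kinds=np.array(kinds),
        point_index=np.array(pts),
        grid=grid,
        filter_mask=np.array(sidecar["filter_mask"], dtype=bool),
        focus_weights=np.array(sidecar["focus_weights"], dtype=float),
    )
    return fm, ids


def write_opendx(path, grid: GridSpec, values: np.ndarray,
                 config_hash: str = "") -> None:
    """Scalar lattice field as OpenDX (x-fastest data reordered to DX's z-fastest)."""
    nx, ny, nz = grid.shape
    vol = np.asarray(values, dtype=float).reshape((nz, ny, nx)).transpose(2, 1, 0)
    lines = [f"# config_hash={config_hash}",
             f"object 1 class gridpositions counts {nx} {ny} {nz}",
             "origin {:.6f} {:.6f} {:.6f}".format(*grid.origin),
             f"delta {grid.spacing:.6f} 0 0",
             f"delta 0 {grid.spacing:.6f} 0",
             f"delta 0 0 {grid.spacing:.6f}",
             f"object 2 class gridconnections counts {nx} {ny} {nz}",
             f"object 3 class array type double rank 0 items {nx * ny * nz} data follows"]
    flat = vol.ravel()
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6f}" for v in flat[i:i + 3]))
    lines.append('object "field" class field')
    Path(path).write_text("\n".join(lines) + "\n")


def write_contours_pdb(path, contours: dict[str, ContourSet], grid: GridSpec,
                       config_hash: str = "") -> None:
    """Contour lattice points as HETATM pseudo-atoms, occupancy = contribution."""
    origin = np.asarray(grid.origin)
    lines = [f"REMARK config_hash={config_hash}"]
    serial = 1
    chain = {"favored": "F", "disfavored": "D"}
    for kind, cs in contours.items():
        for label, pts in (("favored", cs.favored_points),
                           ("disfavored", cs.disfavored_points)):
            for (ix, iy, iz), contrib in pts:
                x, y, z = origin + np.array([ix, iy, iz]) * grid.spacing
                lines.append(
                    f"HETATM{serial:5d}  C   {kind[:3].upper():<3s} "
                    f"{chain[label]}{serial % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{min(abs(contrib), 999.0):6.2f}  0.00"
                )
                serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_model_json(path, model: PLSModelState, config_hash: str = "") -> None:
    payload = {
        "config_hash": config_hash,
        "n_components": model.n_components,
        "y_mean": model.y_mean,
        "x_mean": np.round(model.x_mean, 6).tolist(),
        "coefficients": np.round(model.coefficients, 6).tolist(),
        "active_columns": (
            model.active_columns.tolist() if model.active_columns is not None else None
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_pharmacophore_json(path, model: PharmacophoreModel,
                             config_hash: str = "") -> None:
    payload = {
        "config_hash": config_hash,
        "min_features_required": model.min_features_required,
        "max_features": model.max_features,
        "features": [
            {"kind": f.kind, "center": [round(v, 6) for v in f.center],
             "tolerance": f.tolerance}
            for f in model.features
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_pharmacophore_json(path) -> PharmacophoreModel:
    payload = json.loads(Path(path).read_text())
    return PharmacophoreModel(
        features=[
            PharmacophoreFeature(
                kind=f["kind"], center=tuple(f["center"]), tolerance=f["tolerance"]
            )
            for f in payload["features"]
        ],
        min_features_required=payload["min_features_required"],
        max_features=payload["max_features"],
    )


def write_validation_report(path, result, config_hash: str = "") -> None:
    """BenchmarkModelResult as JSON (and a flat CSV next to it)."""
    path = Path(path)

    def _ext(ev):
        return None if ev is None else {
            k: round(v, 6) for k, v in asdict(ev).items()
        }

    payload = {
        "config_hash": config_hash,
        "model": result.model_name,
        "q2": round(result.q2, 6),
        "rmsecv": round(result.rmsecv, 6),
        "n_components": result.n_components,
        "r2_ncv": round(result.training.r2_ncv, 6),
        "see": round(result.training.see, 6),
        "f_value": round(result.training.f_value, 6),
        "rmsec": round(result.training.rmsec, 6),
        "test": _ext(result.test),
        "validation": _ext(result.validation),
        "fractions": {k: round(v, 6) for k, v in result.fractions.items()},
        "focus_exponent": result.focus_exponent,
        "q2_unfocused": (
            None if result.q2_unfocused is None else round(result.q2_unfocused, 6)
        ),
    }
    path.write_text(json.dumps(payload, indent=1))
    flat = {"model": result.model_name, "q2": result.q2, "rmsecv": result.rmsecv,
            "r2_ncv": result.training.r2_ncv, "see": result.training.see,
            "f_value": result.training.f_value, "rmsec": result.training.rmsec}
    if result.test is not None:
        flat["rmsep"] = result.test.rmsep
        flat["r2_pred_test"] = result.test.r2_pred
    if result.validation is not None:
        flat["r2_pred_validation"] = result.validation.r2_pred
    for k, v in result.fractions.items():
        flat[f"fraction_{k}"] = v
    pd.DataFrame([flat]).round(6).to_csv(path.with_suffix(".csv"), index=False)
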