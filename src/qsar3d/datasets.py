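"""Benchmark dataset of 41 diarylpyrazole-benzenesulfonamide hCA II inhibitors.

The series comprises eight pyrazole scaffolds (I-VIII) that share an
N1-aryl primary-sulfonamide anchor (the zinc-binding group of classical
carbonic anhydrase inhibitors) and vary in the C3 substituent and in the
aryl group R1 on the pyrazole ring.  Inhibition constants Ki are in nM;
the modeled activity is pKi = -log10(Ki in M).  Each compound carries a
train/test/validation flag for each of the three published field models
(CoMFA, region-focused CoMFA, CoMSIA).

Scaffold connectivity is curated here as SMILES templates with an
attachment point for R1; substituent names in the activity table are
unambiguous chemistry and are composed onto the templates at load time.
pKi is always recomputed from Ki rather than read from disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import pandas as pd
from rdkit import Chem

MODELS = ("comfa", "comfarf", "comsia")
Split = Literal["train", "test", "validation"]

#: pyrazole cores; "{R}" marks the R1 attachment point.
SCAFFOLD_SMILES: dict[str, str] = {
    "I": "Cc1cc({R})n(-c2ccc(S(N)(=O)=O)cc2)n1",
    "II": "FC(F)(F)c1cc({R})n(-c2ccc(S(N)(=O)=O)cc2)n1",
    "III": "N#Cc1cc({R})n(-c2ccc(S(N)(=O)=O)cc2)n1",
    "IV": "Cc1cc({R})n(-c2cccc(S(N)(=O)=O)c2)n1",
    "V": "CC(=O)c1cc({R})n(-c2ccc(S(N)(=O)=O)cc2)n1",
    "VI": "NC(=O)c1cc({R})n(-c2ccc(S(N)(=O)=O)cc2)n1",
    "VII": "NC(=O)c1cc({R})nn1-c1ccc(S(N)(=O)=O)cc1",
    "VIII": "NNC(=O)c1cc({R})n(-c2ccc(S(N)(=O)=O)cc2)n1",
}

#: R1 substituents keyed by the names used in the activity table.
R1_SMILES: dict[str, str] = {
    "Phenyl": "-c4ccccc4",
    "Pyridyl": "-c4ccncc4",
    "Tolyl": "-c4ccc(C)cc4",
    "Bromophenyl": "-c4ccc(Br)cc4",
    "4-Bromophenyl": "-c4ccc(Br)cc4",
    "Cyanophenyl": "-c4ccc(C#N)cc4",
    "4-Methoxyphenyl": "-c4ccc(OC)cc4",
    "3-Methoxyphenyl": "-c4cccc(OC)c4",
    "2-Methoxyphenyl": "-c4ccccc4OC",
    "1-Naphthalenyl": "-c4cccc5ccccc45",
    "2-Naphthalenyl": "-c4ccc5ccccc5c4",
    "6-Methoxy-2-naphthalenyl": "-c4ccc5cc(OC)ccc5c4",
    "Biphenyl": "-c4ccc(-c5ccccc5)cc4",
    "4-Chlorophenyl": "-c4ccc(Cl)cc4",
    "4-Fluorophenyl": "-c4ccc(F)cc4",
    "4-Nitrophenyl": "-c4ccc([N+](=O)[O-])cc4",
    "Thienyl": "-c4cccs4",
}

PRIMARY_SULFONAMIDE = Chem.MolFromSmarts("[SX4](=O)(=O)[NX3H2]")


def ki_to_pki(ki_nM: float) -> float:
    """Convert an inhibition constant in nM to pKi = -log10(Ki in M)."""
    if ki_nM <= 0:
        raise ValueError(f"Ki must be positive, got {ki_nM!r} nM")
    return -math.log10(ki_nM * 1e-9)


def compose_smiles(scaffold_id: str, r1_name: str) -> str:
    """Canonical SMILES for a scaffold/substituent combination."""
    try:
        template = SCAFFOLD_SMILES[scaffold_id]
    except KeyError:
        raise KeyError(f"unknown scaffold {scaffold_id!r}") from None
    try:
        frag = R1_SMILES[r1_name]
    except KeyError:
        raise KeyError(f"unknown R1 substituent {r1_name!r}") from None
    smiles = template.replace("({R})", f"({frag})").replace("{R}", frag)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - curated tables
        raise ValueError(f"composed SMILES failed to parse: {smiles}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class CompoundRecord:
    """One benchmark ligand: identity, structure, activity and model splits."""

    compound_id: int
    scaffold_id: str
    r1_name: str
    smiles: str
    ki_nM: float
    split: dict[str, Split] = field(default_factory=dict)

    @property
    def pki(self) -> float:
        return ki_to_pki(self.ki_nM)


def _data_path(name: str):
    return resources.files("qsar3d.data").joinpath(name)


def load_benchmark() -> list[CompoundRecord]:
    """Load the 41-compound benchmark (structures, Ki, split flags).

    pKi is recomputed from Ki on access, never stored.
    """
    try:
        df = pd.read_csv(_data_path("benchmark.csv"))
    except (FileNotFoundError, pd.errors.ParserError) as exc:  # pragma: no cover
        raise RuntimeError(f"packaged benchmark table unreadable: {exc}") from exc
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CompoundRecord(
                compound_id=int(row.compound_id),
                scaffold_id=str(row.scaffold_id),
                r1_name=str(row.r1_name),
                smiles=compose_smiles(str(row.scaffold_id), str(row.r1_name)),
                ki_nM=float(row.ki_nM),
                split={
                    "comfa": row.comfa_split,
                    "comfarf": row.comfarf_split,
                    "comsia": row.comsia_split,
                },
            )
        )
    if len(records) != 41:  # pragma: no cover - packaged data
        raise RuntimeError(f"benchmark should have 41 records, got {len(records)}")
    return records


def load_published_predictions() -> pd.DataFrame:
    """Published per-compound predicted pKi for the three field models.

    Returns a DataFrame indexed by compound_id with the experimental pKi as
    printed (full precision) and one prediction column per model
    (comfa_pred, comfarf_pred, comsia_pred).  Residuals are experimental
    minus predicted.
    """
    df = pd.read_csv(_data_path("published_predictions.csv"))
    return df.set_index("compound_id")


def split_ids(records: list[CompoundRecord], model: str, split: Split) -> list[int]:
    """Compound ids belonging to a model's train/test/validation subset."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    return [r.compound_id for r in records if r.split[model] == split]
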