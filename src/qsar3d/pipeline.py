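"""End-to-end benchmark pipeline and published-table statistics.

``prepare_benchmark`` embeds, charges and aligns the 41-compound series onto
the most active compound (26).  ``fit_benchmark_model`` computes the lattice
fields, filters columns on the training rows, fits the 3-component PLS model
(optionally with region focusing chosen by a small exponent grid search),
and assembles the full validation report: LOO q^2, training statistics,
external test/validation statistics, field fractions and contour maps.

``published_split_statistics`` recomputes the external statistics directly
from the published per-compound predictions, which is pure table arithmetic
and independent of any structure rebuilding.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field

import numpy as np

from . import datasets, prep
from .fields import FieldMatrix, build_field_matrix, column_filter, make_grid, region_focus
from .pls import (
    ContourSet,
    ExternalValidation,
    PLSModelState,
    TrainingStatistics,
    external_validate,
    extract_contours,
    field_fractions,
    fit_pls,
    loo_q2,
    summary_statistics,
)


@dataclass
class PipelineConfig:
    """Settings shared by the grid, PLS, alignment and screening stages."""

    grid_spacing: float = 2.0  # Angstrom
    grid_margin: float = 4.0  # Angstrom
    steric_cutoff: float = 30.0  # kcal/mol
    column_filter_threshold: float = 0.3  # kcal/mol
    dielectric: str = "distance"
    comsia_alpha: float = 0.3
    n_components: int = 3
    focus_exponents: tuple[float, ...] = (0.3, 0.6, 1.0)
    template_compound_id: int = 26
    template_conformers: int = 12
    fieldfit_tries: int = 8
    block_scale: bool = True
    aos_step_degrees: float = 30.0
    run_aos: bool = False
    pharmacophore_tolerance: float = 1.0  # Angstrom
    pharmacophore_merge_radius: float = 1.5  # Angstrom
    min_features: int = 4
    max_features: int = 10
    seed: int = 2024

    def __post_init__(self) -> None:
        for name in ("grid_spacing", "grid_margin", "steric_cutoff",
                     "column_filter_threshold", "pharmacophore_tolerance",
                     "pharmacophore_merge_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["focus_exponents"] = list(self.focus_exponents)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "focus_exponents" in d:
            d["focus_exponents"] = tuple(d["focus_exponents"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _template_ensemble(smiles: str, config: PipelineConfig) -> list[prep.Molecule3D]:
    """Seeded, MMFF-relaxed conformer ensemble for the template compound."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rd = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = config.seed & 0x7FFFFFFF
    params.pruneRmsThresh = 0.5
    ids = AllChem.EmbedMultipleConfs(rd, numConfs=config.template_conformers, params=params)
    out = []
    for cid in ids:
        single = Chem.Mol(rd, confId=cid)
        try:
            AllChem.MMFFOptimizeMolecule(single, maxIters=500)
        except Exception:
            pass
        out.append(prep.assign_partial_charges(prep.from_rdkit(single)))
    if not out:
        raise ValueError(f"template embedding failed for {smiles!r}")
    return out


def _fieldfit_align(
    records: list[datasets.CompoundRecord],
    template: prep.Molecule3D,
    config: PipelineConfig,
) -> dict[int, prep.Molecule3D]:
    """Constrained-embed every compound onto one template conformer.

    For each compound, several core-constrained embeddings are generated and
    the conformer whose steric+electrostatic fields (on the template's own
    grid) agree best with the template's fields is kept -- a label-free
    surrogate for field-fit alignment.
    """
    tgrid = make_grid([template], spacing=config.grid_spacing, margin=config.grid_margin)
    ts, te = comfa_fields_pair(template, tgrid, config)
    tref = np.concatenate([ts, te])
    aligned: dict[int, prep.Molecule3D] = {}
    for r in records:
        if r.compound_id == config.template_compound_id:
            aligned[r.compound_id] = template
            continue
        best: tuple[float, prep.Molecule3D] | None = None
        for k in range(max(1, config.fieldfit_tries)):
            try:
                m = prep.embed_constrained(
                    r.smiles, template, seed=config.seed + 101 * k,
                    name=str(r.compound_id),
                )
                m = prep.assign_partial_charges(m)
            except ValueError as exc:
                raise ValueError(f"compound {r.compound_id}: {exc}") from exc
            s, e = comfa_fields_pair(m, tgrid, config)
            score = float(np.mean((np.concatenate([s, e]) - tref) ** 2))
            if best is None or score < best[0]:
                best = (score, m)
        aligned[r.compound_id] = best[1]
    return aligned


def comfa_fields_pair(mol, grid, config: PipelineConfig):
    from .fields import comfa_fields

    return comfa_fields(mol, grid, dielectric=config.dielectric,
                        cutoff=config.steric_cutoff)


@dataclass
class PreparedBenchmark:
    """Aligned benchmark plus the outcome of the template-conformer search."""

    records: list[datasets.CompoundRecord]
    molecules: dict[int, prep.Molecule3D]
    template_conformer: int
    alignment_q2: float

    def __iter__(self):  # unpack like (records, molecules)
        return iter((self.records, self.molecules))


def prepare_benchmark(
    config: PipelineConfig | None = None,
    records: list[datasets.CompoundRecord] | None = None,
) -> PreparedBenchmark:
    """Embed, charge and align the benchmark onto the template compound.

    Mirroring the orientation-search philosophy (systematically vary the
    geometry, keep the variant with the highest cross-validated q^2), a
    seeded ensemble of template conformers is scanned; for each candidate
    the whole series is constrained-embedded onto it and the template whose
    aligned series gives the best 3-component LOO q^2 on the training split
    is retained.
    """
    config = config or PipelineConfig()
    records = records or datasets.load_benchmark()
    by_id = {r.compound_id: r for r in records}
    if config.template_compound_id not in by_id:
        raise ValueError(
            f"template compound {config.template_compound_id} not in dataset"
        )
    ids = [r.compound_id for r in records]
    row_of = {cid: i for i, cid in enumerate(ids)}
    train_rows = np.array(
        [row_of[i] for i in datasets.split_ids(records, "comfa", "train")]
    )
    y = np.array([r.pki for r in records])
    templates = _template_ensemble(by_id[config.template_compound_id].smiles, config)
    best: tuple[float, int, dict[int, prep.Molecule3D]] | None = None
    for ti, template in enumerate(templates):
        aligned = _fieldfit_align(records, template, config)
        ordered = [aligned[i] for i in ids]
        grid = make_grid(ordered, spacing=config.grid_spacing, margin=config.grid_margin)
        fm = build_field_matrix(ordered, grid, family="comfa",
                                dielectric=config.dielectric,
                                cutoff=config.steric_cutoff)
        fm = column_filter(fm, config.column_filter_threshold, rows=train_rows)
        fm = _block_scaled(fm, train_rows, config)
        if len(train_rows) >= 3:
            q2, _ = loo_q2(fm.design_matrix(train_rows), y[train_rows],
                           config.n_components)
        else:  # degenerate split: fall back to the first template
            q2 = 0.0
        if best is None or q2 > best[0] + 1e-12:
            best = (q2, ti, aligned)
    q2, ti, aligned = best
    return PreparedBenchmark(
        records=records, molecules=aligned, template_conformer=ti, alignment_q2=q2
    )


def _block_scaled(fm: FieldMatrix, train_rows: np.ndarray,
                  config: PipelineConfig) -> FieldMatrix:
    """Equalize field-kind blocks by their pooled training standard deviation."""
    from dataclasses import replace

    if not config.block_scale:
        return fm
    weights = fm.focus_weights.copy()
    for kind in np.unique(fm.kinds):
        sel = (fm.kinds == kind) & fm.filter_mask
        if not sel.any():
            continue
        sd = float(fm.values[np.ix_(train_rows, np.flatnonzero(sel))].std())
        if sd > 0:
            weights[sel] = weights[sel] / sd
    return replace(fm, filter_mask=fm.filter_mask.copy(), focus_weights=weights)


@dataclass
class BenchmarkModelResult:
    """Everything the published summary table reports, recomputed."""

    model_name: str
    q2: float
    rmsecv: float
    n_components: int
    training: TrainingStatistics
    test: ExternalValidation | None
    validation: ExternalValidation | None
    fractions: dict[str, float]
    contours: dict[str, ContourSet]
    pls_model: PLSModelState
    field_matrix: FieldMatrix
    focus_exponent: float | None = None
    q2_unfocused: float | None = None
    predictions: dict[str, np.ndarray] = dc_field(default_factory=dict)


def fit_benchmark_model(
    records: list[datasets.CompoundRecord],
    mols: dict[int, prep.Molecule3D],
    model_name: str = "comfa",
    config: PipelineConfig | None = None,
) -> BenchmarkModelResult:
    """Fields -> filter -> (optional focusing) -> PLS -> validation report."""
    config = config or PipelineConfig()
    if model_name not in datasets.MODELS:
        raise ValueError(f"model must be one of {datasets.MODELS}")
    family = "comsia" if model_name == "comsia" else "comfa"
    ids = [r.compound_id for r in records]
    ordered = [mols[i] for i in ids]
    grid = make_grid(ordered, spacing=config.grid_spacing, margin=config.grid_margin)
    fm = build_field_matrix(
        ordered, grid, family=family, dielectric=config.dielectric,
        cutoff=config.steric_cutoff, alpha=config.comsia_alpha,
    )
    y = np.array([r.pki for r in records])
    row_of = {cid: i for i, cid in enumerate(ids)}
    train_rows = np.array(
        [row_of[i] for i in datasets.split_ids(records, model_name, "train")]
    )
    test_rows = np.array(
        [row_of[i] for i in datasets.split_ids(records, model_name, "test")]
    )
    val_rows = np.array(
        [row_of[i] for i in datasets.split_ids(records, model_name, "validation")]
    )
    fm = column_filter(fm, config.column_filter_threshold, rows=train_rows)
    fm = _block_scaled(fm, train_rows, config)
    y_train = y[train_rows]

    q2, rmsecv = loo_q2(fm.design_matrix(train_rows), y_train, config.n_components)
    model = fit_pls(_train_view(fm, train_rows), y_train, config.n_components)
    focus_exponent = None
    q2_unfocused = None
    if model_name == "comfarf":
        q2_unfocused = q2
        best = (q2, None, fm, model)
        for expo in config.focus_exponents:
            fm_f = region_focus(fm, model, expo)
            q2_f, rmsecv_f = loo_q2(
                fm_f.design_matrix(train_rows), y_train, config.n_components
            )
            if q2_f > best[0] + 1e-12:
                model_f = fit_pls(_train_view(fm_f, train_rows), y_train,
                                  config.n_components)
                best = (q2_f, expo, fm_f, model_f)
        q2, focus_exponent, fm, model = best
        if focus_exponent is not None:
            _, rmsecv = loo_q2(fm.design_matrix(train_rows), y_train,
                               config.n_components)

    training = summary_statistics(model, fm.design_matrix(train_rows), y_train)
    preds = {
        "train": model.predict(fm.design_matrix(train_rows)),
        "test": model.predict(fm.design_matrix(test_rows)) if len(test_rows) else None,
        "validation": (
            model.predict(fm.design_matrix(val_rows)) if len(val_rows) else None
        ),
    }
    test_stats = (
        external_validate(preds["test"], y[test_rows], float(y_train.mean()))
        if len(test_rows) >= 3 else None
    )
    val_stats = (
        external_validate(preds["validation"], y[val_rows], float(y_train.mean()))
        if len(val_rows) >= 3 else None
    )
    return BenchmarkModelResult(
        model_name=model_name,
        q2=q2,
        rmsecv=rmsecv,
        n_components=model.n_components,
        training=training,
        test=test_stats,
        validation=val_stats,
        fractions=field_fractions(model),
        contours=extract_contours(model),
        pls_model=model,
        field_matrix=fm,
        focus_exponent=focus_exponent,
        q2_unfocused=q2_unfocused,
        predictions=preds,
    )


def _train_view(fm: FieldMatrix, rows: np.ndarray) -> FieldMatrix:
    """FieldMatrix restricted to training rows (keeps column metadata)."""
    from dataclasses import replace

    return replace(fm, values=fm.values[rows])


def published_split_statistics(
    model_name: str, split: str = "test"
) -> ExternalValidation:
    """External statistics recomputed from the published per-compound table."""
    records = datasets.load_benchmark()
    preds = datasets.load_published_predictions()
    ids = datasets.split_ids(records, model_name, split)
    col = f"{model_name}_pred"
    sub = preds.loc[ids]
    return external_validate(sub[col].to_numpy(), sub["pki_exp"].to_numpy())


def published_residual(compound_id: int, model_name: str = "comfa") -> float:
    """Experimental minus predicted pKi for one compound, from the table."""
    preds = datasets.load_published_predictions()
    row = preds.loc[compound_id]
    return float(row["pki_exp"] - row[f"{model_name}_pred"])


def planted_recovery_experiment(
    n_replicates: int = 50,
    base_seed: int = 0,
    n_train: int = 30,
    n_holdout: int = 10,
    noise_sd: float = 0.1,
    n_components: int = 5,
) -> dict:
    """Replicate study of signal recovery from planted synthetic datasets.

    For each replicate: generate an aligned series with activities planted on
    field columns, fit PLS on ``n_train`` compounds, and record (a) the
    squared Pearson correlation on the held-out compounds and (b) whether all
    planted columns fall inside the 80%-level favored contour set.
    """
    from .synthetic import SyntheticSpec, generate_synthetic

    holdout_r2 = []
    contour_hits = []
    for rep in range(n_replicates):
        spec = SyntheticSpec(
            n_compounds=n_train + n_holdout,
            noise_sd=noise_sd,
            seed=(base_seed + rep) % (2**31),
        )
        data = generate_synthetic(spec)
        fm = data.field_matrix
        train = np.arange(n_train)
        hold = np.arange(n_train, n_train + n_holdout)
        model = fit_pls(_train_view(fm, train), data.activities[train], n_components)
        pred = model.predict(fm.design_matrix(hold))
        obs = data.activities[hold]
        r = np.corrcoef(pred, obs)[0, 1]
        holdout_r2.append(float(r * r))
        contours = extract_contours(model)
        favored = {
            (cs.field_kind, tuple(pt))
            for cs in contours.values()
            for pt, _ in cs.favored_points
        }
        planted_pts = {
            (data.spec.signal_kind, tuple(p))
            for p in fm.point_index[data.planted_indices]
        }
        contour_hits.append(planted_pts <= favored)
    return {
        "holdout_r2": np.array(holdout_r2),
        "contour_hit": np.array(contour_hits),
        "mean_holdout_r2": float(np.mean(holdout_r2)),
        "contour_recovery_rate": float(np.mean(contour_hits)),
    }
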