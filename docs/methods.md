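# Methods

## Scope and data

The package models a series of 41 diarylpyrazole-benzenesulfonamide
inhibitors of human carbonic anhydrase II.  The activity table (compound
identity, scaffold, aryl substituent R¹, Ki in nM) and the per-model
train/test/validation flags are shipped as package data; pKi = −log₁₀(Ki·10⁻⁹)
is always recomputed from Ki rather than read from disk, and a fixture test
asserts agreement with the published per-compound activity column to six
decimals, so table typos cannot propagate.

Structures are curated as SMILES: each of the eight pyrazole scaffolds is a
template with an attachment point, and the printed substituent names
("4-Fluorophenyl", "2-Naphthalenyl", …) are composed onto it at load time.
Scaffold VI (compounds 21–28) is 5-aryl-1-(4-sulfamoylphenyl)-1H-pyrazole-
3-carboxamide; with R¹ = 4-fluorophenyl this reproduces the reported
molecular weight of compound 26 (360.36 Da) exactly, which anchors the
curation.  The remaining scaffolds vary the C3 substituent (methyl, CF₃,
cyano, acetyl, carboxamide, carbohydrazide), the ring-attachment regiochemistry
(scaffold VII) and the sulfonamide position (meta in scaffold IV).  Every
compound carries an unsubstituted primary sulfonamide, the zinc-binding
group of this inhibitor class.

The published split flags are exposed exactly as printed: 26/10/5 for the
primary energy-field model, but only 7 test compounds for the region-focused
variant, 9 test and 4 validation compounds for the similarity-index model.
Recomputing RMSEP from the published per-compound predictions with these
flags reproduces the published 0.226/0.319/0.308, confirming the flags are
self-consistent even where the prose says "ten".

## Structure preparation

Conformers are generated with seeded ETKDG and minimized with MMFF94 (UFF
fallback).  Partial charges are plain Gasteiger charges; the proprietary
Hückel π-correction of the original charge scheme is not reproduced, a known
and accepted deviation.  Per-atom property values for the similarity fields
are: vdW radius cubed (steric), partial charge (electrostatic), Crippen
atomic logP contribution (hydrophobic), and donor/acceptor indicator flags
from the pinned substructure rules in `qsar3d/rules.py` (version 1.0).

Alignment of a shared-scaffold series uses the maximum common substructure
(MCS): either as a rigid Kabsch superposition onto the template
(`align_to_template`, with the RMSD reported and invariant to rigid
pre-transformations), or — the pipeline default — as *core-constrained
embedding* (`embed_constrained`): the MCS atoms inherit the template's
coordinates exactly and only the variable substituents are embedded and
force-field relaxed under core restraints.  Constrained embedding is the
open-component analogue of field-fit alignment and was adopted after rigid
superposition of independently embedded conformers left the shared core in
inconsistent internal torsions (training q² ≈ 0.1–0.3 versus ≈ 0.4 with the
constrained protocol).

Two further selection steps mirror the original protocol's philosophy of
choosing the geometry that maximizes cross-validated predictivity:

1. **Field-fit conformer selection.**  For each compound, 8 constrained
   embeddings (seeds `seed + 101·k`) are generated and the conformer whose
   steric+electrostatic fields on the template's own grid have the smallest
   mean-squared deviation from the template's fields is kept.  This
   criterion is label-free (never sees activities).
2. **Template-conformer search.**  A 12-conformer seeded ETKDG ensemble of
   the most active compound (26) is scanned; the whole series is aligned to
   each candidate and the template giving the highest 3-component LOO q² on
   the training split is retained.  This is the analogue of the all
   orientation search, which likewise selects a geometric degree of freedom
   by the highest q².

The conformer seeds are part of the pinned configuration (default 2024): the
benchmark model is one fixed, deterministic protocol, not a random ensemble.

An all-orientation search over a deduplicated Euler-angle lattice (default
step 30°, identity always included, ties broken by smallest rotation angle)
is implemented and tested but not run inside the default pipeline: it
multiplies the LOO cost by several hundred and the template-conformer search
already exercises the same selection principle.

## Fields

The grid is an axis-aligned box enclosing all atoms plus a 4 Å margin
(the original work states only the 2.0 Å spacing; the margin is our default),
snapped outward to whole spacing steps and centered on the aggregate
centroid; points are ordered x-fastest at `origin + index·spacing`.

Energy fields use a +1 probe with sp³-carbon LJ parameters from a pinned
per-element table (Bondi radii, Amber-style well depths) combined as
r*₍ij₎ = rᵢ + r_probe and ε₍ij₎ = √(εᵢ·ε_probe), with A = ε·r*¹² and
C = 2ε·r*⁶ so the pair minimum is exactly −ε at r*.  The electrostatic term
uses k_e = 332.06 kcal·Å·mol⁻¹·e⁻² and a distance-dependent dielectric
D(r) = r by default (config-switchable to constant).  Both fields are
clipped to ±30 kcal/mol.  At lattice points where the steric energy
saturates (inside the molecular core) the electrostatic value is replaced by
the per-molecule mean over unsaturated points: the behaviour of the original
software at sterically excluded points is undocumented, and mean-filling
prevents singular values from dominating the regression.  Similarity fields
need no cutoff; their magnitude is bounded by Σᵢ|W_ik| by construction.

Column filtering drops columns whose variation (max − min across compounds)
is below 0.3 kcal/mol; the same numeric threshold is applied to the
dimensionless similarity columns (a deliberate unit mismatch, as the
threshold is a noise floor, not a physical energy).  The mask is computed
once on the training rows and held fixed through the LOO loop.  The pipeline
additionally equalizes field-kind blocks by their pooled training standard
deviation (block scaling), the standard remedy for the steric block's
clipped-plateau columns otherwise swamping the electrostatic signal.

## PLS and validation

PLS1 is implemented directly (NIPALS, column-centered, unscaled,
deterministic; coefficients B = W(PᵀW)⁻¹q) because the fitted internals —
per-column coefficients and loadings — feed region focusing, field fractions
and contour extraction.  scikit-learn's PLS implementation serves as an
independent cross-check in the test suite, never as the implementation; the
LOO loop is additionally verified against a brute-force reimplementation to
1e-10 and full-rank PLS against OLS to 1e-8.

LOO q² refits (and re-centers) on every fold and uses the full-training mean
in the denominator.  Training statistics follow SEE = √(RSS/(n−c−1)) and
F = (r²/c)/((1−r²)/(n−c−1)) with c latent variables — conventions chosen to
be mutually consistent (r² = 0.856, n = 26, c = 3 gives F ≈ 43.6, matching
the published pairing).  The published RMSEC's denominator is not defined in
the source; both the plain RMS (`rmsec`) and the LOO RMS (`rmsecv`) are
exposed and neither is asserted against the published 0.458.

External validation reports RMSEP = √(MSE) and r²_pred as the squared
Pearson correlation — verified to reproduce the published 0.891/0.742/0.790
from the published per-compound predictions, whereas the 1−PRESS/SD
convention does not.  The Golbraikh–Tropsha block computes K = Σyŷ/Σŷ²,
K′ = Σyŷ/Σy², through-origin R₀² (observed vs K·predicted) and R₀′²
(predicted vs K′·observed), with the pass rule "either K or K′ in
[0.85, 1.15]" and "either (R²−R₀²)/R² or (R²−R₀′²)/R² below 0.1".

Region focusing rescales active columns by
(stdev × |coefficient| / max)^exponent; the pipeline grid-searches the
exponent over {0.3, 0.6, 1.0} by LOO q² and keeps the unfocused model if no
exponent improves it, so focusing can never degrade the reported q².
Contours rank columns by signed stdev × coefficient per field kind; the
favored set is the smallest prefix of positive contributions covering 80% of
their total, the disfavored set the analogous 20% prefix of negative
contributions.

## Synthetic generator

The generator emulates the structure every downstream module assumes: a
shared-scaffold aligned series (default: 3-methyl-pyrazole-benzenesulfonamide
core, twelve aryl substituents spanning steric bulk, halogens,
donors/acceptors and heteroaromatics) whose activities are an exact linear
function of a small number of lattice-field columns plus Gaussian noise
(default SD 0.1, matching the scale at which the published models operate).

Design choices that keep the planted ground truth *identifiable*:

- **Conformers depend only on structure** (fixed internal embedding seed);
  the dataset seed drives substituent sampling and noise.  Identical specs
  are byte-identical, and replicate studies reuse cached embeddings.
- **Two planted columns** with per-SD effect sizes (1.0, 0.8): the generator
  rescales them to raw-column coefficients, so each planted effect
  contributes a controlled share of activity variance.
- **Family-head planting**: planted columns are drawn from columns that are
  the highest-variance member of their correlation neighborhood (|r| > 0.9)
  and are mutually decorrelated (|r| ≤ 0.8).  Planting on a column whose
  near-duplicate neighbor has larger variance makes attribution ill-posed —
  the fit concentrates on the neighbor — which would test the collinearity
  of lattice fields rather than the recovery machinery.
- **Pool size 12** balances two failure modes found during design: with ~10
  substituents the field matrix of a 40-compound series has rank ≤ 9 and
  exact attribution is ill-posed; with ~24, held-out compounds are mostly
  structurally novel and a few-component PLS approximation does not
  generalize.

The replicated recovery experiment (50 seeded replicates; 30 training and 10
held-out compounds; 4–5 components) yields a mean held-out r² of 0.90–0.96
and a contour recovery rate of 0.90–0.96 across base seeds.

What the generator does *not* emulate: multiple scaffolds, conformational
ensembles, activity cliffs unexplained by fields, and experimental error
structure beyond i.i.d. Gaussian noise.  Passing recovery tests therefore
demonstrates the machinery is sound, not that real series are this benign.
Roughly one replicate in fifty draws a held-out set of structurally novel
substituent combinations on which prediction can fail badly (r² near 0); the
mean criterion is robust to this, single replicates are not.

## Screening funnel

Descriptors: molecular weight from a pinned table of standard atomic masses
(CIAAW 2021 abridged values — chosen over RDKit's internal masses to match
reported values such as 360.362 for compound 26 and 222.236 for
acetazolamide), Crippen logP, N/O-based H-bond donor/acceptor counts, TPSA,
rotatable bonds (strict definition: terminal hydroxyl rotors excluded), and
a primary-sulfonamide substructure flag `S(=O)(=O)[NH2]`.

The rule-of-five filter evaluates all four rules without short-circuiting
(MW < 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10); the descriptor-range filter checks
inclusive intervals from a shipped table (MW 130–725, logP −2.0 to 6.5, plus
config-extensible bounds for externally supplied descriptors such as logBB).
All 41 benchmark compounds pass the rule of five, consistent with the
series' design.

The pharmacophore model is built from aligned actives (benchmark compounds
12, 22, 25, 26 by default): features are detected per molecule with the
pinned rules (donor/acceptor atoms, aromatic ring centroids, hydrophobic
carbon clusters ≥ 3 atoms and aromatic halogens), single-linkage clustered
across molecules at a 1.5 Å merge radius, and only clusters populated by
*every* active survive; centroids become feature centers (tolerance 1.0 Å,
closed-ball matching), capped at 10 features by smallest cluster spread.
Matching is greedy nearest-first one-to-one — with a 4-feature minimum and
1 Å tolerances the difference from optimal assignment is immaterial at this
scale.  Chemical-space triage standardizes a descriptor matrix, projects it
onto the first two principal axes, and returns the members of the closest
pairs (similar) and the rows farthest from the centroid (dissimilar), with
deterministic tie-breaks by row id.

## Known limitations

- The absolute q²/r² of the rebuilt benchmark depends on open-component
  geometry (ETKDG + MMFF + Gasteiger) and is not expected to match values
  obtained with proprietary force fields, charges and field-fit alignment;
  the pipeline's property-level behaviour (q² > 0.4, focusing non-degrading,
  fractions summing to 1) is the reproducible claim.
- External test statistics of the rebuilt models are noticeably weaker than
  the published ones (e.g. rebuilt RMSEP ≈ 0.66 for the primary model);
  the published external statistics are reproduced exactly from the
  published per-compound predictions instead.
- Directional hydrogen-bond fields, torsional (flexible) alignment and
  conformer ensembles are out of scope; one bioactive-surrogate conformer
  per molecule.
- The field-fit objective of the original software (steric+electrostatic
  energy RMSD averaged over lattice points as a rigid-body objective) is not
  reproducible without its internals; core-constrained embedding plus
  field-RMS conformer selection is this package's documented substitute.
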