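"""Planted-signal recovery: does the pipeline find known ground truth?

Generates an aligned series whose activities are a known linear function of
two lattice-field columns plus noise, fits PLS, and checks that the planted
columns fall inside the 80%-level favored contour set.
"""

import numpy as np

import qsar3d as q
from qsar3d.synthetic import SyntheticSpec, generate_synthetic

data = generate_synthetic(SyntheticSpec(n_compounds=30, noise_sd=0.1, seed=7))
fm = data.field_matrix
print("planted columns (global ids):", data.planted_indices.tolist())
print("raw coefficients:", np.round(data.planted_coefficients, 4).tolist())

model = q.fit_pls(fm, data.activities, 4)
contours = q.extract_contours(model)
favored = {(cs.field_kind, pt) for cs in contours.values()
           for pt, _ in cs.favored_points}
for g in data.planted_indices:
    pt = tuple(int(v) for v in fm.point_index[g])
    hit = ("steric", pt) in favored
    print(f"planted column at lattice point {pt}: "
          f"{'recovered in' if hit else 'MISSING from'} the favored contour set")

rep = q.planted_recovery_experiment(n_replicates=20, base_seed=7)
print(f"20 replicates: mean held-out r2 = {rep['mean_holdout_r2']:.3f}, "
      f"contour recovery rate = {rep['contour_recovery_rate']:.2f}")
print("Recovery means the contour map points at the lattice region that "
      "truly drives activity, not a correlated artifact.")
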