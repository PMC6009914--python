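"""Full benchmark rebuild: embed, align, fields, PLS, external validation.

Reproduces the modeling protocol on the packaged series: a template-26
conformer ensemble is scanned, every compound is core-constrained-embedded
onto the winning template (field-fit conformer selection), and the three
models are fitted and validated.  Takes a couple of minutes.
"""

import qsar3d as q

prepared = q.prepare_benchmark()
print(f"alignment selected template conformer {prepared.template_conformer} "
      f"with training LOO q2 = {prepared.alignment_q2:.3f}")

for name in ("comfa", "comfarf", "comsia"):
    res = q.fit_benchmark_model(prepared.records, prepared.molecules, name)
    line = (f"{name:8s} q2={res.q2:.3f} r2_ncv={res.training.r2_ncv:.3f} "
            f"SEE={res.training.see:.3f}")
    if res.test is not None:
        line += f" RMSEP={res.test.rmsep:.3f} r2_pred={res.test.r2_pred:.3f}"
    if res.focus_exponent is not None:
        line += (f" (region focusing exponent {res.focus_exponent}, "
                 f"q2 before {res.q2_unfocused:.3f})")
    print(line)
print("q2 > 0.4 marks an internally predictive lattice model; RMSEP and "
      "r2_pred measure how well held-out compounds are predicted.")
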