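"""The 41-compound hCA II inhibitor benchmark: activities and splits.

Loads the packaged series of diarylpyrazole-benzenesulfonamides, shows how
Ki (nM) maps to the modeled activity pKi = -log10(Ki in M), and lists the
train/test/validation membership used by each field model.
"""

import qsar3d as q

records = q.load_benchmark()
print(f"{len(records)} compounds across scaffolds "
      f"{sorted({r.scaffold_id for r in records})}")

most_active = min(records, key=lambda r: r.ki_nM)
least_active = max(records, key=lambda r: r.ki_nM)
for label, r in (("most active", most_active), ("least active", least_active)):
    print(f"{label}: compound {r.compound_id} ({r.r1_name} on scaffold "
          f"{r.scaffold_id}), Ki = {r.ki_nM} nM, pKi = {r.pki:.3f}")
print("pKi is recomputed from Ki; e.g. 420 nM ->", round(q.ki_to_pki(420), 6))

for model in ("comfa", "comfarf", "comsia"):
    sizes = {s: len(q.split_ids(records, model, s))
             for s in ("train", "test", "validation")}
    print(f"{model:8s} split sizes: {sizes}")
print("Splits follow the published per-compound flags; the activity span of "
      "~2.3 log units is what the lattice models must explain.")
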