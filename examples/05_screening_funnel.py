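"""Virtual-screening funnel: pharmacophore, rule of five, descriptor ranges.

Aligns the four most active benchmark compounds (12, 22, 25, 26), builds a
common-feature pharmacophore, and pushes a few molecules through the filter
cascade.
"""

import qsar3d as q
from qsar3d.screening import (
    build_pharmacophore,
    compute_descriptors,
    lipinski_filter,
    match_pharmacophore,
    range_filter,
)

records = q.load_benchmark()
by_id = {r.compound_id: r for r in records}

# align the actives onto compound 26 (most active) by constrained embedding
template = q.assign_partial_charges(
    q.embed_and_minimize(by_id[26].smiles, seed=2024, name="26")
)
actives = [template]
for cid in (12, 22, 25):
    m = q.embed_constrained(by_id[cid].smiles, template, seed=2024, name=str(cid))
    actives.append(q.assign_partial_charges(m))

model = build_pharmacophore(actives)
kinds = [f.kind for f in model.features]
print(f"common-feature pharmacophore: {len(model.features)} features "
      f"({', '.join(sorted(set(kinds)))})")
for mol in actives:
    ok, count, _ = match_pharmacophore(mol, model)
    print(f"  compound {mol.name}: matches {count} features -> "
          f"{'pass' if ok else 'fail'}")

print("\nrule-of-five + descriptor-range cascade:")
for name, smiles in [
    ("compound 26", by_id[26].smiles),
    ("acetazolamide", "CC(=O)Nc1nnc(S(N)(=O)=O)s1"),
    ("triacontane", "C" * 30),
]:
    d = compute_descriptors(smiles)
    ro5 = lipinski_filter(d)
    ranges = range_filter(d)
    print(f"  {name}: MW={d.mw:.1f} logP={d.logp:.2f} HBD={d.hbd_count} "
          f"HBA={d.hba_count} | rule-of-five "
          f"{'pass' if ro5.overall_pass else 'FAIL'}, ranges "
          f"{'pass' if ranges.overall_pass else 'FAIL'}")
print("Only candidates passing every stage would go on to docking or assay.")
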