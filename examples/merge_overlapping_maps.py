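"""Merge two maps that describe overlapping chemistry.

Two maps are built from overlapping reaction subsets of one network, so
three processes (and their participant pools) are semantically identical
across the pair.  The merge unifies entities by their borne-entity
annotation and processes by their full participant signature: shared
content appears once, everything else is carried over with provenance.
"""

import copy

import physiomap as pm
from physiomap import fixtures as fx

model, _ = fx.make_random_network(n_species=8, n_reactions=8, p_modifier=0.2, seed=11)
m1 = copy.deepcopy(model)
m1.reactions = model.reactions[:5]      # reactions r0..r4
m2 = copy.deepcopy(model)
m2.reactions = model.reactions[2:]      # reactions r2..r7 (overlap r2..r4)

a = pm.infer_from_reactions(m1)
b = pm.infer_from_reactions(m2)
merged, report = pm.merge_physiomaps(a, b)

print(f"map A: {len(a.entities)} entities, {len(a.processes)} processes")
print(f"map B: {len(b.entities)} entities, {len(b.processes)} processes")
print(f"merged: {len(merged.entities)} entities, {len(merged.processes)} processes")
print(f"shared processes unified: {len(report.process_matches)}")
print(f"conflicts: {len(report.conflicts)}")
origins = sorted(set(report.provenance.values()))
print(f"provenance tags used: {origins}")
# Merged process count = |A| + |B| - shared: each semantically identical
# process (same kind, participants, roles, stoichiometry) appears once.
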