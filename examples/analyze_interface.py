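"""Analyse a single complex: interface, sub-regions, contacts, anchors.

Builds a synthetic two-chain complex with planted features, runs the full
per-complex stage and prints what the detectors find.  The same call chain
works on a real PDB file via ``ifevol.read_structure(path, ("A", "B"))``.
"""

from collections import Counter

from ifevol import analyze_complex, build_toy_complex
from ifevol.synth import ToySpec

structure, truth = build_toy_complex(ToySpec(seed=1))
analysis = analyze_complex(structure)
model = analysis.interface_model

print(f"interface residues per chain: "
      f"{ {cid: len(r) for cid, r in model.interface.items()} }")
print(f"sub-regions: {dict(Counter(model.regions.values()))}")
print(f"atomic contacts: {len(analysis.atomic)} "
      f"({len(analysis.residue_graph)} residue pairs)")
print(f"salt bridges: {len(analysis.salt_bridges)}, "
      f"hydrogen bonds: {len(analysis.hbonds)}, "
      f"apolar residue contacts: {len(analysis.apolar)}")
print(f"apolar patches: { {cid: [p.size for p in pl] for cid, pl in analysis.patches.items()} }")
for rid in model.anchors:
    print(f"anchor {rid}: buries {model.delta_rasa[rid]:.0f} A^2, "
          f"{model.n_contacts[rid]} atomic contacts "
          f"(planted anchor was {truth.anchor})")

# The anchor buries far more surface than the 80 A^2 threshold and makes
# several times more atomic contacts than a typical interface residue --
# exactly the behaviour that makes anchors conserved across evolution.
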