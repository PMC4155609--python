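"""Score the structural impact of mutations with a comparison network.

A parent helix and a mutant carrying one substitution and one deletion are
turned into RINs; the comparison network over their aligned residue pairs
labels each interaction conserved / lost / gained, and scores every residue
with the fraction of its interactions that survived the mutation (1.0 = no
local change).  Substituted residues also carry their BLOSUM62 score —
negative values flag chemically drastic replacements.
"""

from rinmap import build_comparison_network, build_rin, fixtures
from rinmap.fixtures import MutationSpec, make_mutant_pair, mutant_structure

parent = fixtures.make_helix(15)
spec = MutationSpec(substitutions=[(5, "W")], deletions=[10])
_, _, alignment = make_mutant_pair(parent, spec)
mutant = mutant_structure(parent, spec)

rin_parent = build_rin(parent)
rin_mutant = build_rin(mutant)
alignment.attach_node_ids([r.node_id for r in parent.residues],
                          [r.node_id for r in mutant.residues])

cn = build_comparison_network(rin_parent, rin_mutant, alignment)
counts = cn.status_counts()
print(f"conserved {counts['conserved']}, lost {counts['lost']}, gained {counts['gained']}")
for col in sorted(cn.graph.nodes):
    a = cn.graph.nodes[col]
    if a["mutated"] or a["unaligned"] or a["unchanged_fraction"] < 1.0:
        print(f"  column {col:2d}  {a.get('aa_a') or '-'}->{a.get('aa_b') or '-'}"
              f"  unchanged={a['unchanged_fraction']:.2f}"
              f"  blosum62={a['blosum62']}")
# Residues near the deletion lose interactions (fraction < 1); the W
# substitution keeps most contacts because only the residue name changed.
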