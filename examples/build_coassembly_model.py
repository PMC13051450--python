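"""Build a co-assembly-like complex from synthetic structures.

Constructs a five-monomer in-register parallel amyloid-beta fibril whose
edge monomer has a flexible (hinged-out) N-terminal strand, and a binder
protein exposing the sequence-similar strand DGEYRHDS.  The binder strand's
backbone is superposed onto the displaced fibril strand, extending the
beta-sheet the way a joining monomer would.
"""

from coassembler.coassemble import assemble_complex, scan_similarity
from coassembler.fixtures import (
    DEFAULT_BINDER_START,
    BinderSpec,
    FibrilSpec,
    build_binder,
    build_fibril,
)
from coassembler.structio import write_pdb

fibril = build_fibril(FibrilSpec())
binder = build_binder(BinderSpec())

matches = scan_similarity(binder.sequence("X"), fibril.sequence("A")[:20],
                          window=8, min_identity=0.5,
                          binder_start=DEFAULT_BINDER_START)
best = matches[0]
print(f"best segment match: binder {best.binder_range} ~ fibril "
      f"{best.fibril_range}, identity {best.identity:.2f}, "
      f"class similarity {best.similarity:.3f}")
# identity 0.75: six of eight residues identical between DGEYRHDS and
# DAEFRHDS; similarity 0.875 adds the apolar G~A pair.

model = assemble_complex(binder, fibril, best)
print(f"backbone superposition RMSD: {model.superposition.rmsd:.3f} Å "
      f"over {model.superposition.n_atoms} atoms")
print(f"steric clashes outside the matched segments: {model.clash_count} "
      f"(flagged: {model.flagged})")
# RMSD ~0 because both strands are ideal beta geometry; clash count 0 means
# the docked binder extends the sheet without colliding with the fibril.

write_pdb(model.structure, "coassembly_complex.pdb")
print("wrote coassembly_complex.pdb")
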