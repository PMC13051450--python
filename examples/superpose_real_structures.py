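"""Superpose a real binder strand onto a real fibril strand (user-supplied).

Given PDB files for a binder (e.g. the AlphaFold delta-COP model, using its
mu-homology domain) and an amyloid fibril, superposes the backbone of a
chosen binder segment onto a chosen segment of a fibril chain and reports
the RMSD.  With delta-COP residues 428-433 against amyloid-beta residues 3-8
of a fibril edge monomer this measures the structural similarity that
motivates the co-assembly hypothesis.

Usage:
    python superpose_real_structures.py BINDER.pdb B_CHAIN B_START B_END \
        FIBRIL.pdb F_CHAIN F_START F_END
"""

import sys

from coassembler.coassemble import superpose_segments
from coassembler.structio import read_pdb

if len(sys.argv) != 9:
    print(__doc__)
    raise SystemExit(1)

binder_path, b_chain, b_start, b_end, fibril_path, f_chain, f_start, f_end = \
    sys.argv[1:]
binder = read_pdb(binder_path)
fibril = read_pdb(fibril_path)
result = superpose_segments(binder, b_chain, (int(b_start), int(b_end)),
                            fibril, f_chain, (int(f_start), int(f_end)),
                            atom_selection="backbone")
print(f"backbone RMSD: {result.rmsd:.2f} Å over {result.n_atoms} atoms")
# Values well below ~1 Å indicate the two strands share backbone geometry
# closely enough to pair within one beta-sheet.
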