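"""Co-assembly-like complex construction.

Finds sequence-similar segment pairs between a binder and the edge strand of
an amyloid assembly, rigidly superposes the binder segment's backbone onto
the assembly segment (Kabsch least squares), and assembles a candidate
complex with a steric-clash census.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from coassembler._geom import apply_rigid, kabsch
from coassembler.structio import Structure, classify_residue, ONE_TO_THREE

BACKBONE_SELECTION = ("N", "CA", "C", "O")
CA_SELECTION = ("CA",)


@dataclass
class SegmentMatch:
    binder_range: tuple[int, int]   # author resseq interval, inclusive
    fibril_range: tuple[int, int]
    identity: float
    similarity: float
    window: int

    def __post_init__(self):
        if not 0.0 <= self.identity <= self.similarity <= 1.0:
            raise ValueError("need 0 <= identity <= similarity <= 1")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    atom_selection: str

    def __post_init__(self):
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"rotation determinant {det} != +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")


@dataclass
class ComplexModel:
    structure: Structure
    clash_count: int
    match: SegmentMatch
    superposition: SuperpositionResult
    flagged: bool


def scan_similarity(binder_seq: str, target_seq: str, window: int = 8,
                    min_identity: float = 0.0,
                    binder_start: int = 1, target_start: int = 1,
                    his_charged: bool = False) -> list[SegmentMatch]:
    """All gapless window alignments between two sequences.

    Identity counts exact matches / window; similarity counts matches within
    the same polarity class / window.  Results are sorted by identity then
    similarity (descending), ties broken by lower binder start index, and
    filtered by ``min_identity``.  Ranges are author-numbered, starting at
    ``binder_start`` / ``target_start``.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    binder_seq, target_seq = binder_seq.upper(), target_seq.upper()
    if window > len(binder_seq) or window > len(target_seq):
        raise ValueError("window exceeds a sequence length")

    def cls(letter: str) -> str:
        return classify_residue(ONE_TO_THREE[letter], his_charged=his_charged)

    matches = []
    for i in range(len(binder_seq) - window + 1):
        for j in range(len(target_seq) - window + 1):
            a = binder_seq[i:i + window]
            b = target_seq[j:j + window]
            ident = sum(x == y for x, y in zip(a, b)) / window
            simil = sum(x == y or cls(x) == cls(y)
                        for x, y in zip(a, b)) / window
            if ident >= min_identity:
                matches.append(SegmentMatch(
                    binder_range=(binder_start + i, binder_start + i + window - 1),
                    fibril_range=(target_start + j, target_start + j + window - 1),
                    identity=ident, similarity=simil, window=window))
    matches.sort(key=lambda m: (-m.identity, -m.similarity,
                                m.binder_range[0], m.fibril_range[0]))
    return matches


def _segment_coords(s: Structure, chain_id: str, resrange: tuple[int, int],
                    atom_names: tuple[str, ...], frame: int = 0) -> np.ndarray:
    lo, hi = resrange
    coords = []
    fr = s.frame(frame)
    chain = s.chain(chain_id)
    found = set()
    for r in chain.residues:
        if lo <= r.resseq <= hi:
            found.add(r.resseq)
            for name in atom_names:
                coords.append(fr[r.atom(name).index])
    missing = set(range(lo, hi + 1)) - found
    if missing:
        raise KeyError(f"chain {chain_id} lacks residues {sorted(missing)}")
    return np.stack(coords)


def superpose_segments(mobile: Structure, mobile_chain: str,
                       mobile_range: tuple[int, int],
                       reference: Structure, reference_chain: str,
                       reference_range: tuple[int, int],
                       atom_selection: str = "backbone") -> SuperpositionResult:
    """Optimal rigid superposition (Kabsch) of one segment's backbone (or CA)
    atoms onto an equal-length segment of another structure."""
    if atom_selection not in ("backbone", "CA"):
        raise ValueError("atom_selection must be 'backbone' or 'CA'")
    names = BACKBONE_SELECTION if atom_selection == "backbone" else CA_SELECTION
    if (mobile_range[1] - mobile_range[0]) != (reference_range[1] - reference_range[0]):
        raise ValueError("segments must have equal residue counts")
    p = _segment_coords(mobile, mobile_chain, mobile_range, names)
    q = _segment_coords(reference, reference_chain, reference_range, names)
    if len(p) < 3:
        raise ValueError("need at least 3 atom pairs for a rigid fit")
    rot, trans, rmsd = kabsch(p, q)
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd,
                               n_atoms=len(p), atom_selection=atom_selection)


def find_edge_chain(assembly: Structure) -> str:
    """Edge monomer heuristic: protein chain whose centroid is extremal along
    the first principal axis of the chain-centroid cloud (the open face of a
    stacked sheet); honours ``metadata['edge_chain']`` when the generator
    recorded it."""
    if "edge_chain" in assembly.metadata:
        return str(assembly.metadata["edge_chain"])
    chains = assembly.protein_chains
    if len(chains) == 1:
        return chains[0].chain_id
    fr = assembly.frame(0)
    cents = np.stack([fr[[a.index for r in c.residues for a in r.atoms]].mean(axis=0)
                      for c in chains])
    centered = cents - cents.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    proj = centered @ vt[0]
    return chains[int(np.argmax(proj))].chain_id


def assemble_complex(binder: Structure, assembly: Structure,
                     match: SegmentMatch,
                     binder_chain: str | None = None,
                     edge_chain: str | None = None,
                     atom_selection: str = "backbone",
                     clash_threshold: float = 2.5,
                     reject_limit: int = 5,
                     segment_buffer: int = 1) -> ComplexModel:
    """Transform the binder onto the assembly's edge-monomer segment and
    count inter-partner heavy-atom clashes.

    The assembly's coordinates are untouched; only the binder moves.  Atom
    pairs where both residues lie in the superposed segments (padded by
    ``segment_buffer`` residues to cover the chain junctions) are excluded
    from the clash census: that region is a near-duplicate by construction.
    A model whose clash count exceeds ``reject_limit`` is flagged, not
    dropped.
    """
    if binder.n_models != 1 or assembly.n_models != 1:
        raise ValueError("assemble_complex expects single-model inputs")
    if binder_chain is None:
        binder_chain = binder.protein_chains[0].chain_id
    if edge_chain is None:
        edge_chain = find_edge_chain(assembly)

    sup = superpose_segments(binder, binder_chain, match.binder_range,
                             assembly, edge_chain, match.fibril_range,
                             atom_selection=atom_selection)
    moved = binder.with_coords(
        apply_rigid(binder.coords[0], sup.rotation, sup.translation)[None])

    complex_structure = moved.merge(assembly, metadata={
        "generator": "assemble_complex",
        "binder_chains": [c.chain_id for c in moved.chains],
        "assembly_chains": [c.chain_id for c in assembly.chains],
        "edge_chain": edge_chain,
        "match": {"binder_range": list(match.binder_range),
                  "fibril_range": list(match.fibril_range),
                  "identity": match.identity,
                  "similarity": match.similarity},
        "superposition_rmsd": sup.rmsd,
    })

    # clash census (heavy atoms, excluding the superposed segment pair)
    fr = complex_structure.frame(0)
    b_lo, b_hi = match.binder_range[0] - segment_buffer, \
        match.binder_range[1] + segment_buffer
    f_lo, f_hi = match.fibril_range[0] - segment_buffer, \
        match.fibril_range[1] + segment_buffer

    def collect(chain_ids, skip_chain, skip_range):
        idx = []
        for cid in chain_ids:
            for r in complex_structure.chain(cid).residues:
                if cid == skip_chain and skip_range[0] <= r.resseq <= skip_range[1]:
                    continue
                idx.extend(a.index for a in r.atoms if a.element != "H")
        return np.array(idx, dtype=int)

    binder_ids = [c.chain_id for c in moved.chains]
    assembly_ids = [c.chain_id for c in assembly.chains]
    seg_b = np.array([a.index
                      for r in complex_structure.chain(binder_chain).residues
                      if b_lo <= r.resseq <= b_hi
                      for a in r.atoms if a.element != "H"], dtype=int)
    seg_a = np.array([a.index
                      for r in complex_structure.chain(edge_chain).residues
                      if f_lo <= r.resseq <= f_hi
                      for a in r.atoms if a.element != "H"], dtype=int)
    rest_b = collect(binder_ids, binder_chain, (b_lo, b_hi))
    rest_a = collect(assembly_ids, edge_chain, (f_lo, f_hi))

    clash_count = 0
    # every inter-partner block except (binder segment) x (assembly segment)
    for p_idx, q_idx in ((rest_b, rest_a), (seg_b, rest_a), (rest_b, seg_a)):
        if len(p_idx) and len(q_idx):
            d = fr[p_idx][:, None, :] - fr[q_idx][None, :, :]
            dist = np.sqrt((d ** 2).sum(axis=2))
            clash_count += int((dist < clash_threshold).sum())

    return ComplexModel(structure=complex_structure, clash_count=clash_count,
                        match=match, superposition=sup,
                        flagged=clash_count > reject_limit)
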