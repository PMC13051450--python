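"""Independent brute-force / closed-form oracles used only by the tests.

These deliberately avoid the library's optimised code paths: plain O(n^2)
loops and Horn's quaternion method, so agreement is a genuine cross-check.
"""

import numpy as np

from coassembler.structio import Structure


def brute_force_contacts(s: Structure, chains_a, chains_b, cutoff, frame=0):
    """Set of residue-pair keys with any heavy-atom distance <= cutoff."""
    fr = s.frame(frame)
    res_a = [r for cid in chains_a for r in s.chain(cid).residues]
    res_b = [r for cid in chains_b for r in s.chain(cid).residues]
    pairs = set()
    for ra in res_a:
        for rb in res_b:
            hit = False
            for aa in ra.atoms:
                if aa.element == "H":
                    continue
                for ab in rb.atoms:
                    if ab.element == "H":
                        continue
                    d = np.linalg.norm(fr[aa.index] - fr[ab.index])
                    if d <= cutoff:
                        hit = True
            if hit:
                pairs.add((ra.key, rb.key))
    return pairs


def brute_force_salt_bridges(s: Structure, cutoff, frame=0):
    from coassembler.interfaces import ACIDIC_GROUP_ATOMS, BASIC_GROUP_ATOMS

    fr = s.frame(frame)
    residues = list(s.residues())
    out = set()
    for ra in residues:
        if ra.resname not in ACIDIC_GROUP_ATOMS:
            continue
        for rb in residues:
            if rb.resname not in ("LYS", "ARG"):
                continue
            hit = False
            for na in ACIDIC_GROUP_ATOMS[ra.resname]:
                for nb in BASIC_GROUP_ATOMS[rb.resname]:
                    if not (ra.has_atom(na) and rb.has_atom(nb)):
                        continue
                    d = np.linalg.norm(fr[ra.atom(na).index]
                                       - fr[rb.atom(nb).index])
                    if d <= cutoff:
                        hit = True
            if hit:
                out.add((ra.key, rb.key))
    return out


def brute_force_ion_proximity(s: Structure, cutoff, frame=0):
    from coassembler.interfaces import ACIDIC_GROUP_ATOMS, BASIC_GROUP_ATOMS

    fr = s.frame(frame)
    out = set()
    for ic in s.ion_chains:
        for ion in ic.residues:
            for r in s.residues():
                group = ACIDIC_GROUP_ATOMS.get(r.resname) \
                    or BASIC_GROUP_ATOMS.get(r.resname)
                if not group:
                    continue
                dmin = np.inf
                for name in group:
                    if not r.has_atom(name):
                        continue
                    for a in ion.atoms:
                        dmin = min(dmin, np.linalg.norm(
                            fr[a.index] - fr[r.atom(name).index]))
                if dmin <= cutoff:
                    out.add((ion.key, r.key))
    return out


def horn_quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD by Horn's closed-form quaternion method."""
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e = (np.sum(p ** 2) + np.sum(q ** 2) - 2.0 * lam) / len(p)
    return float(np.sqrt(max(e, 0.0)))
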