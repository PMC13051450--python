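"""Ensemble interface forensics.

Hydrogen bonds and β-bridges follow the Kabsch–Sander electrostatic model
(DSSP), with amide hydrogens placed geometrically when absent.  Pairwise
interaction maps are a documented contact/H-bond/salt-bridge-weighted
surrogate for force-field interaction free energies: identical output shape
(time averages and SDs over frames, negative = favorable) but non-physical
units.  Binding interfaces are labelled residue-pair sets whose persistence
(fraction of frames with at least one member pair in contact) classifies them
as maintained, partial, or lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from coassembler._geom import kabsch, apply_rigid
from coassembler.structio import Residue, Structure

HBOND_ENERGY_CUTOFF = -0.5   # kcal/mol (DSSP convention)
KS_COUPLING = 0.084 * 332.0  # Kabsch-Sander q1*q2*f, kcal*Å/mol
NH_BOND_LENGTH = 1.01

# surrogate interaction-map weights (non-physical, configurable)
W_HBOND = 1.0
W_SALT_BRIDGE = 1.5
W_NONPOLAR = 0.2
NONPOLAR_SATURATION = 10
NONPOLAR_CUTOFF = 4.5

CONTACT_CUTOFF = 4.5          # persistence contact criterion (min heavy atom)
MAINTAINED_THRESHOLD = 0.75
PARTIAL_THRESHOLD = 0.25

ACIDIC_GROUP_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_GROUP_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
                     "HIS": ("ND1", "NE2")}


@dataclass
class HBond:
    donor: tuple[str, int, str]     # residue key providing N-H
    acceptor: tuple[str, int, str]  # residue key providing C=O
    energy: float                   # kcal/mol
    frame: int


@dataclass
class BetaBridge:
    res_i: tuple[str, int, str]
    res_j: tuple[str, int, str]
    kind: str                       # parallel | antiparallel
    frame: int


@dataclass
class InteractionMap:
    rows: list[tuple[str, int, str]]       # binder residue keys
    cols: list[tuple[str, int, str]]       # partner-monomer residue keys
    polar_mean: np.ndarray
    polar_sd: np.ndarray
    nonpolar_mean: np.ndarray
    nonpolar_sd: np.ndarray
    n_frames: int


@dataclass
class BindingInterface:
    label: str
    pair_set: list[tuple[tuple[str, int, str], tuple[str, int, str]]]
    persistence: float
    status: str

    @staticmethod
    def status_from_persistence(p: float,
                                maintained: float = MAINTAINED_THRESHOLD,
                                partial: float = PARTIAL_THRESHOLD) -> str:
        if p >= maintained:
            return "maintained"
        if p >= partial:
            return "partial"
        return "lost"


@dataclass
class IonProximityRecord:
    ion: tuple[str, int, str]
    ion_element: str
    residue: tuple[str, int, str]
    min_distance: float
    frame: int
    sign_compatible: bool


@dataclass
class OrderMetrics:
    p2_nematic: float
    p1_polar: float
    interstrand_hbond_count: float
    p2_series: np.ndarray
    p1_series: np.ndarray
    hbond_series: np.ndarray


# ---------------------------------------------------------------------------
# hydrogen bonds & bridges
# ---------------------------------------------------------------------------

def _amide_hydrogens(chain_residues: list[Residue], fr: np.ndarray) -> dict:
    """Geometric N-H placement: H on N, along the preceding C=O direction
    (DSSP convention), 1.01 Å.  First residues and prolines get no H."""
    h = {}
    for prev, res in zip(chain_residues, chain_residues[1:]):
        if res.resname == "PRO":
            continue
        try:
            n = fr[res.atom("N").index]
            c_prev = fr[prev.atom("C").index]
            o_prev = fr[prev.atom("O").index]
        except KeyError:
            continue
        direction = c_prev - o_prev
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            continue
        h[res.key] = n + NH_BOND_LENGTH * direction / norm
    return h


def kabsch_sander_energy(c: np.ndarray, o: np.ndarray,
                         n: np.ndarray, h: np.ndarray) -> float:
    """Electrostatic H-bond energy for acceptor C=O and donor N-H (kcal/mol)."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # atom overlap: DSSP clamps to a strongly negative value
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def detect_hbonds(s: Structure, frame: int = 0,
                  cutoff: float = HBOND_ENERGY_CUTOFF,
                  max_ca_distance: float = 9.0) -> list[HBond]:
    """Backbone Kabsch–Sander hydrogen bonds within one frame.

    Donor and acceptor must be distinct residues, not sequence-adjacent in
    the same chain, with CA atoms within ``max_ca_distance``.
    """
    fr = s.frame(frame)
    residues = []
    h_pos: dict = {}
    for ch in s.protein_chains:
        usable = [r for r in ch.residues
                  if all(r.has_atom(x) for x in ("N", "CA", "C", "O"))]
        h_pos.update(_amide_hydrogens(usable, fr))
        residues.extend(usable)
    if not residues:
        return []
    ca = np.stack([fr[r.atom("CA").index] for r in residues])
    tree = cKDTree(ca)
    pairs = tree.query_pairs(r=max_ca_distance)
    bonds: list[HBond] = []
    for i, j in sorted(pairs):
        for don, acc in ((i, j), (j, i)):
            rd, ra = residues[don], residues[acc]
            if rd.chain_id == ra.chain_id and abs(rd.resseq - ra.resseq) < 2 \
                    and rd.icode == ra.icode:
                continue
            if rd.key not in h_pos:
                continue
            e = kabsch_sander_energy(fr[ra.atom("C").index],
                                     fr[ra.atom("O").index],
                                     fr[rd.atom("N").index],
                                     h_pos[rd.key])
            if e < cutoff:
                bonds.append(HBond(donor=rd.key, acceptor=ra.key,
                                   energy=float(e), frame=frame))
    return bonds


def _sequence_neighbors(s: Structure):
    """Maps key -> key of the previous/next residue within its chain."""
    prev_of, next_of = {}, {}
    for ch in s.protein_chains:
        for a, b in zip(ch.residues, ch.residues[1:]):
            prev_of[b.key] = a.key
            next_of[a.key] = b.key
    return prev_of, next_of


def detect_beta_bridges(s: Structure, frame: int = 0,
                        hbonds: list[HBond] | None = None) -> list[BetaBridge]:
    """Kabsch–Sander β-bridges from the backbone H-bond pattern.

    With Hbond(a, b) meaning "C=O of a accepts from N-H of b":
    parallel(i, j) iff [Hbond(i-1, j) and Hbond(j, i+1)] or
                       [Hbond(j-1, i) and Hbond(i, j+1)];
    antiparallel(i, j) iff [Hbond(i, j) and Hbond(j, i)] or
                       [Hbond(i-1, j+1) and Hbond(j-1, i+1)].
    """
    if hbonds is None:
        hbonds = detect_hbonds(s, frame=frame)
    hb = {(b.acceptor, b.donor) for b in hbonds}  # (CO residue, NH residue)
    prev_of, next_of = _sequence_neighbors(s)

    def hbond(a, b):
        return a is not None and b is not None and (a, b) in hb

    keys = set()
    for b in hbonds:
        keys.add(b.donor)
        keys.add(b.acceptor)
    # candidate pairs: any two residues connected by an H-bond or whose
    # neighbourhood is; scanning pairs appearing in hb with ±1 shifts suffices
    candidates = set()
    for co, nh in hb:
        for i in (prev_of.get(co), co, next_of.get(co)):
            for j in (prev_of.get(nh), nh, next_of.get(nh)):
                if i and j and i != j and not (
                        i[0] == j[0] and abs(i[1] - j[1]) < 2):
                    candidates.add((min(i, j), max(i, j)))

    bridges = []
    for i, j in sorted(candidates):
        im, ip = prev_of.get(i), next_of.get(i)
        jm, jp = prev_of.get(j), next_of.get(j)
        parallel = (hbond(im, j) and hbond(j, ip)) or \
                   (hbond(jm, i) and hbond(i, jp))
        antiparallel = (hbond(i, j) and hbond(j, i)) or \
                       (hbond(im, jp) and hbond(jm, ip))
        if parallel:
            bridges.append(BetaBridge(res_i=i, res_j=j, kind="parallel",
                                      frame=frame))
        elif antiparallel:
            bridges.append(BetaBridge(res_i=i, res_j=j, kind="antiparallel",
                                      frame=frame))
    return bridges


def detect_salt_bridges(s: Structure, frame: int = 0,
                        cutoff: float = 4.0) -> list[tuple]:
    """Residue pairs whose opposite-charge side-chain group atoms come within
    ``cutoff`` Å (Lys/Arg/His-basic vs Asp/Glu-acidic)."""
    fr = s.frame(frame)
    acidic, basic = [], []
    for r in s.residues():
        names = ACIDIC_GROUP_ATOMS.get(r.resname)
        if names:
            idx = [r.atom(n).index for n in names if r.has_atom(n)]
            if idx:
                acidic.append((r, np.array(idx, int)))
        names = BASIC_GROUP_ATOMS.get(r.resname)
        if names and (r.resname != "HIS" or r.his_charged):
            idx = [r.atom(n).index for n in names if r.has_atom(n)]
            if idx:
                basic.append((r, np.array(idx, int)))
    out = []
    for ra, ia in acidic:
        for rb, ib in basic:
            d = fr[ia][:, None, :] - fr[ib][None, :, :]
            if np.sqrt((d ** 2).sum(axis=2)).min() <= cutoff:
                out.append((ra.key, rb.key))
    return out


# ---------------------------------------------------------------------------
# interaction maps & binding interfaces
# ---------------------------------------------------------------------------

def _residue_min_distance(fr, idx_a, idx_b) -> float:
    d = fr[idx_a][:, None, :] - fr[idx_b][None, :, :]
    return float(np.sqrt((d ** 2).sum(axis=2).min()))


def interaction_map(ensemble: Structure, binder_chain: str,
                    target_chain: str,
                    w_hb: float = W_HBOND, w_sb: float = W_SALT_BRIDGE,
                    w_np: float = W_NONPOLAR,
                    n_max: int = NONPOLAR_SATURATION,
                    nonpolar_cutoff: float = NONPOLAR_CUTOFF) -> InteractionMap:
    """Time-averaged pairwise polar/non-polar interaction scores with SDs.

    Per frame and residue pair, the polar score is -(w_hb * H-bonds +
    w_sb * salt bridges) and the non-polar score is -w_np * (number of
    apolar-carbon pairs within ``nonpolar_cutoff``, saturated at ``n_max``).
    Scores are kcal/mol-scaled surrogate units, not force-field energies.
    """
    if ensemble.n_models < 1:
        raise ValueError("ensemble has no frames")
    rows = [r for r in ensemble.chain(binder_chain).residues]
    cols = [r for r in ensemble.chain(target_chain).residues]
    row_index = {r.key: i for i, r in enumerate(rows)}
    col_index = {r.key: j for j, r in enumerate(cols)}

    carbon_idx = {r.key: np.array([a.index for a in r.atoms
                                   if a.element == "C"], int)
                  for r in rows + cols}

    n_frames = ensemble.n_models
    polar = np.zeros((n_frames, len(rows), len(cols)))
    nonpolar = np.zeros_like(polar)

    for f in range(n_frames):
        fr = ensemble.frame(f)
        for hb in detect_hbonds(ensemble, frame=f):
            for a, b in ((hb.donor, hb.acceptor), (hb.acceptor, hb.donor)):
                if a in row_index and b in col_index:
                    polar[f, row_index[a], col_index[b]] -= w_hb
        for ka, kb in detect_salt_bridges(ensemble, frame=f):
            for a, b in ((ka, kb), (kb, ka)):
                if a in row_index and b in col_index:
                    polar[f, row_index[a], col_index[b]] -= w_sb
        for r in rows:
            ia = carbon_idx[r.key]
            if not len(ia):
                continue
            for c in cols:
                ib = carbon_idx[c.key]
                if not len(ib):
                    continue
                d = fr[ia][:, None, :] - fr[ib][None, :, :]
                n_close = int((np.sqrt((d ** 2).sum(axis=2))
                               <= nonpolar_cutoff).sum())
                if n_close:
                    nonpolar[f, row_index[r.key], col_index[c.key]] = \
                        -w_np * min(n_close, n_max)

    ddof = 1 if n_frames > 1 else 0
    return InteractionMap(
        rows=[r.key for r in rows], cols=[c.key for c in cols],
        polar_mean=polar.mean(axis=0), polar_sd=polar.std(axis=0, ddof=ddof),
        nonpolar_mean=nonpolar.mean(axis=0),
        nonpolar_sd=nonpolar.std(axis=0, ddof=ddof),
        n_frames=n_frames)


def pair_contact_matrix(ensemble: Structure, pairs,
                        cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Boolean (n_frames, n_pairs): min heavy-atom distance <= cutoff."""
    resolved = []
    for (ca, ra), (cb, rb) in pairs:
        a = ensemble.get_residue(ca, ra)
        b = ensemble.get_residue(cb, rb)
        resolved.append((
            np.array([x.index for x in a.atoms if x.element != "H"], int),
            np.array([x.index for x in b.atoms if x.element != "H"], int)))
    out = np.zeros((ensemble.n_models, len(resolved)), dtype=bool)
    for f in range(ensemble.n_models):
        fr = ensemble.frame(f)
        for k, (ia, ib) in enumerate(resolved):
            out[f, k] = _residue_min_distance(fr, ia, ib) <= cutoff
    return out


def interface_persistence(ensemble: Structure, pair_set,
                          cutoff: float = CONTACT_CUTOFF) -> float:
    """Fraction of frames in which at least one member pair is in contact."""
    m = pair_contact_matrix(ensemble, pair_set, cutoff=cutoff)
    return float(m.any(axis=1).mean())


def define_interfaces(map_: InteractionMap,
                      ensemble: Structure | None = None,
                      seeds: dict[str, list] | None = None,
                      significance: float = 0.05,
                      max_gap: int = 2,
                      maintained: float = MAINTAINED_THRESHOLD,
                      partial: float = PARTIAL_THRESHOLD,
                      cutoff: float = CONTACT_CUTOFF) -> list[BindingInterface]:
    """Binding interfaces from seeded pair sets or by clustering the map.

    With ``seeds`` (label -> list of ((chain, resseq), (chain, resseq))
    pairs), persistence is computed per seed set over the ensemble.  Without
    seeds, significant pairs (|polar| + |nonpolar| mean above
    ``significance``) are single-linkage clustered with a sequence gap of at
    most ``max_gap`` on each side.
    """
    out = []
    if seeds is not None:
        if ensemble is None:
            raise ValueError("seeded persistence needs the ensemble")
        for label in seeds:
            pairs = [((ca, ra), (cb, rb)) for (ca, ra), (cb, rb) in seeds[label]]
            p = interface_persistence(ensemble, pairs, cutoff=cutoff)
            out.append(BindingInterface(
                label=label,
                pair_set=[(tuple(a) + ("",), tuple(b) + ("",))
                          if len(a) == 2 else (a, b) for a, b in seeds[label]],
                persistence=p,
                status=BindingInterface.status_from_persistence(
                    p, maintained, partial)))
        return out

    strength = np.abs(map_.polar_mean) + np.abs(map_.nonpolar_mean)
    sig = [(i, j) for i in range(strength.shape[0])
           for j in range(strength.shape[1]) if strength[i, j] > significance]
    # single-linkage clustering with sequence-gap linkage
    clusters: list[set] = []
    for cell in sig:
        merged = None
        for cl in clusters:
            if any(abs(cell[0] - c[0]) <= max_gap and abs(cell[1] - c[1]) <= max_gap
                   for c in cl):
                if merged is None:
                    cl.add(cell)
                    merged = cl
                else:
                    merged |= cl
                    cl.clear()
        if merged is None:
            clusters.append({cell})
    clusters = [c for c in clusters if c]
    clusters.sort(key=lambda c: min(c))

    for k, cl in enumerate(clusters):
        pair_keys = [(map_.rows[i], map_.cols[j]) for i, j in sorted(cl)]
        if ensemble is not None:
            pairs = [((a[0], a[1]), (b[0], b[1])) for a, b in pair_keys]
            p = interface_persistence(ensemble, pairs, cutoff=cutoff)
        else:
            p = float("nan")
        status = BindingInterface.status_from_persistence(p, maintained, partial) \
            if np.isfinite(p) else "unknown"
        out.append(BindingInterface(label=f"BI{k + 1}", pair_set=pair_keys,
                                    persistence=p, status=status))
    return out


def classify_runs(ensembles: list[Structure], seeds: dict[str, list],
                  run_ids: list[str] | None = None,
                  cutoff: float = CONTACT_CUTOFF,
                  maintained: float = MAINTAINED_THRESHOLD,
                  partial: float = PARTIAL_THRESHOLD) -> dict:
    """Per-run interface status table plus summary counts.

    For each run and labelled interface: persistence, status, and a
    "remained throughout" flag (persistence 1.0 within one frame).
    Summary counts runs by status per interface.
    """
    if not ensembles:
        raise ValueError("need at least one run")
    if run_ids is None:
        run_ids = [f"run{i}" for i in range(len(ensembles))]
    table: dict[str, dict[str, dict]] = {}
    for rid, ens in zip(run_ids, ensembles):
        row = {}
        for label, pairs in seeds.items():
            p = interface_persistence(ens, pairs, cutoff=cutoff)
            row[label] = {
                "persistence": p,
                "status": BindingInterface.status_from_persistence(
                    p, maintained, partial),
                "remained_throughout": p >= 1.0 - 1.0 / max(ens.n_models, 1) - 1e-12,
            }
        table[rid] = row
    summary: dict[str, dict[str, int]] = {}
    for label in seeds:
        counts = {"maintained": 0, "partial": 0, "lost": 0}
        for rid in table:
            counts[table[rid][label]["status"]] += 1
        summary[label] = counts
    return {"runs": table, "summary": summary}


# ---------------------------------------------------------------------------
# ions, order, RMSD
# ---------------------------------------------------------------------------

def ion_proximity(ensemble: Structure, cutoff: float = 4.0) -> list[IonProximityRecord]:
    """(ion, charged residue) pairs within ``cutoff`` in any frame, with a
    charge-sign compatibility note (cation↔acidic, anion↔basic)."""
    ions = [r for c in ensemble.ion_chains for r in c.residues]
    if not ions:
        return []
    charged = [r for r in ensemble.residues()
               if r.resname in ACIDIC_GROUP_ATOMS or r.resname in BASIC_GROUP_ATOMS]
    records = []
    for f in range(ensemble.n_models):
        fr = ensemble.frame(f)
        for ion in ions:
            ion_sign = ion.formal_charge_sign
            ion_idx = ion.atom_indices
            for r in charged:
                group = ACIDIC_GROUP_ATOMS.get(r.resname) or \
                    BASIC_GROUP_ATOMS.get(r.resname)
                idx = np.array([r.atom(n).index for n in group
                                if r.has_atom(n)], int)
                if not len(idx):
                    continue
                dmin = _residue_min_distance(fr, ion_idx, idx)
                if dmin <= cutoff:
                    res_sign = "-" if r.resname in ACIDIC_GROUP_ATOMS else "+"
                    records.append(IonProximityRecord(
                        ion=ion.key, ion_element=ion.resname,
                        residue=r.key, min_distance=dmin, frame=f,
                        sign_compatible=(ion_sign != res_sign
                                         and "0" not in (ion_sign, res_sign))))
    return records


def order_metrics(ensemble: Structure, strand_definitions: list) -> OrderMetrics:
    """Nematic (P2) and polar (P1) order of strand vectors, plus the mean
    inter-strand backbone H-bond count per adjacent strand pair.

    Strand vectors are unit first-CA→last-CA vectors per
    ``(chain_id, first_resseq, last_resseq)`` definition.  P2 is the largest
    eigenvalue of the nematic Q-tensor; P1 is the mean projection onto the
    director (oriented along the mean strand vector).
    """
    if len(strand_definitions) < 2:
        raise ValueError("need at least two strands")
    strand_atoms = []
    for cid, lo, hi in strand_definitions:
        a = ensemble.get_residue(cid, lo).atom("CA").index
        b = ensemble.get_residue(cid, hi).atom("CA").index
        strand_atoms.append((a, b))

    n_frames = ensemble.n_models
    p2s = np.empty(n_frames)
    p1s = np.empty(n_frames)
    hbs = np.empty(n_frames)
    ranges = {d[0]: (d[1], d[2]) for d in strand_definitions}
    strand_chains = [d[0] for d in strand_definitions]
    for f in range(n_frames):
        fr = ensemble.frame(f)
        vs = []
        for a, b in strand_atoms:
            v = fr[b] - fr[a]
            norm = np.linalg.norm(v)
            if norm < 1e-9:
                raise ValueError("degenerate (zero-length) strand vector")
            vs.append(v / norm)
        vs = np.stack(vs)
        q = 1.5 * np.einsum("ki,kj->ij", vs, vs) / len(vs) - 0.5 * np.eye(3)
        w, vecs = np.linalg.eigh(q)
        p2s[f] = w[-1]
        director = vecs[:, -1]
        mean_v = vs.mean(axis=0)
        if np.dot(director, mean_v) < 0:
            director = -director
        p1s[f] = float((vs @ director).mean())
        # inter-strand backbone H-bonds between adjacent strand pairs
        bonds = detect_hbonds(ensemble, frame=f)
        count = 0
        for k in range(len(strand_chains) - 1):
            c1, c2 = strand_chains[k], strand_chains[k + 1]
            for hb_ in bonds:
                pair = {hb_.donor[0], hb_.acceptor[0]}
                if pair == {c1, c2} and _in_range(hb_, ranges):
                    count += 1
        hbs[f] = count / (len(strand_chains) - 1)
    return OrderMetrics(p2_nematic=float(p2s.mean()), p1_polar=float(p1s.mean()),
                        interstrand_hbond_count=float(hbs.mean()),
                        p2_series=p2s, p1_series=p1s, hbond_series=hbs)


def _in_range(hb: HBond, ranges: dict) -> bool:
    for key in (hb.donor, hb.acceptor):
        lo, hi = ranges[key[0]]
        if not lo <= key[1] <= hi:
            return False
    return True


def mean_structure(ensemble: Structure, selection: np.ndarray,
                   n_iter: int = 2) -> np.ndarray:
    """Iteratively aligned mean coordinates over the selection (2 iterations)."""
    ref = ensemble.frame(0)[selection]
    for _ in range(n_iter):
        aligned = []
        for f in range(ensemble.n_models):
            x = ensemble.frame(f)[selection]
            rot, trans, _ = kabsch(x, ref)
            aligned.append(apply_rigid(x, rot, trans))
        ref = np.mean(aligned, axis=0)
    return ref


def rmsd_series(ensemble: Structure, selection: np.ndarray,
                reference: str = "initial") -> np.ndarray:
    """Per-frame best-fit RMSD of the selection onto the chosen reference
    ('initial' = frame 0, or 'mean_structure')."""
    selection = np.asarray(selection, int)
    if selection.size == 0:
        raise ValueError("empty selection")
    if reference == "initial":
        ref = ensemble.frame(0)[selection]
    elif reference == "mean_structure":
        ref = mean_structure(ensemble, selection)
    else:
        raise ValueError("reference must be 'initial' or 'mean_structure'")
    out = np.empty(ensemble.n_models)
    for f in range(ensemble.n_models):
        _, _, rmsd = kabsch(ensemble.frame(f)[selection], ref)
        out[f] = rmsd
    return out
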