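"""Structure data model, PDB I/O, residue chemistry classes, and SASA.

The in-memory model is a light chain → residue → atom hierarchy with all
model (frame) coordinates held in a single ``(n_models, n_atoms, 3)`` array,
so ensemble operations are plain numpy.  PDB reading and writing are backed
by gemmi; author residue numbering is preserved verbatim.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from coassembler._geom import sphere_points

BACKBONE_ATOMS = ("N", "CA", "C", "O")

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "TIP3"}
ION_NAMES = {"NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "CU", "BR", "I", "LI"}
ION_CHARGE = {"NA": "+", "K": "+", "MG": "+", "ZN": "+", "CA": "+", "MN": "+",
              "FE": "+", "CU": "+", "LI": "+", "CL": "-", "BR": "-", "I": "-"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# van der Waals radii (Å) by element; fallback 1.7
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
             "P": 1.80, "NA": 2.27, "CL": 1.75, "K": 2.75, "MG": 1.73,
             "ZN": 1.39, "CA": 2.31, "BR": 1.85, "I": 1.98}

# Theoretical Gly-X-Gly maximum accessible surface areas (Å²), Tien et al. 2013.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

_CHARGED = {"ARG", "LYS", "ASP", "GLU"}
_POLAR = {"ASN", "GLN", "SER", "THR", "TYR", "TRP", "HIS", "CYS"}


class PDBParseError(ValueError):
    pass


class EmptyStructureError(ValueError):
    pass


class PDBFormatError(ValueError):
    pass


def classify_residue(resname: str, his_charged: bool = False,
                     met_polar: bool = False) -> str:
    """Polarity class of a standard residue: 'charged', 'polar' or 'apolar'.

    Histidine defaults to polar (matching the convention of contact-class
    affinity predictors); ``his_charged`` moves it to charged.  Methionine
    defaults to apolar; ``met_polar`` moves it to polar.
    """
    rn = resname.upper()
    if rn not in STANDARD_AA:
        raise KeyError(f"unknown residue code {resname!r}")
    if rn == "HIS":
        return "charged" if his_charged else "polar"
    if rn == "MET":
        return "polar" if met_polar else "apolar"
    if rn in _CHARGED:
        return "charged"
    if rn in _POLAR:
        return "polar"
    return "apolar"


def formal_charge_sign(resname: str, his_charged: bool = False) -> str:
    rn = resname.upper()
    if rn in ("ARG", "LYS"):
        return "+"
    if rn in ("ASP", "GLU"):
        return "-"
    if rn == "HIS" and his_charged:
        return "+"
    return ION_CHARGE.get(rn, "0")


def element_from_name(name: str, resname: str = "") -> str:
    rn = resname.upper().strip()
    if rn in ION_NAMES and len(name.strip()) <= 2:
        return rn.capitalize() if len(rn) == 2 else rn
    stripped = name.strip().lstrip("0123456789")
    return stripped[0].upper() if stripped else "C"


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    index: int = -1

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII.get(self.element.upper(), 1.70)

    def validate(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.name!r} has empty element")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r} has non-finite coordinates")


@dataclass
class Residue:
    chain_id: str
    resseq: int
    resname: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    his_charged: bool = False

    @property
    def polarity_class(self) -> str:
        return classify_residue(self.resname, his_charged=self.his_charged)

    @property
    def formal_charge_sign(self) -> str:
        return formal_charge_sign(self.resname, his_charged=self.his_charged)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resseq, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.chain_id}:{self.resseq} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def atom_indices(self) -> np.ndarray:
        return np.array([a.index for a in self.atoms], dtype=int)

    def coords(self, frame: np.ndarray | None = None) -> np.ndarray:
        if frame is not None:
            return frame[self.atom_indices]
        return np.stack([a.coord for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    is_ion_group: bool = False


class Structure:
    """Chain/residue/atom topology plus one or more coordinate frames.

    All models share topology and atom ordering; ``coords`` has shape
    ``(n_models, n_atoms, 3)`` and model 0 is exposed through ``Atom.coord``
    views.
    """

    def __init__(self, chains: list[Chain], coords: np.ndarray | None = None,
                 metadata: dict | None = None):
        self.chains = chains
        self.metadata = dict(metadata or {})
        ids = [c.chain_id for c in chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids: {ids}")
        flat = [a for c in chains for r in c.residues for a in r.atoms]
        if coords is None:
            if not flat:
                coords = np.zeros((1, 0, 3))
            else:
                coords = np.stack([np.asarray(a.coord, float) for a in flat])[None, :, :]
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if coords.shape[1] != len(flat):
            raise ValueError(
                f"coords has {coords.shape[1]} atoms; topology has {len(flat)}")
        self.coords = coords
        self._atoms = flat
        for i, a in enumerate(flat):
            a.index = i
            a.coord = self.coords[0, i]
            a.validate()

    # -- inspection ---------------------------------------------------------
    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def atoms(self) -> list[Atom]:
        return self._atoms

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def residues(self, include_ions: bool = False):
        for c in self.chains:
            if c.is_ion_group and not include_ions:
                continue
            yield from c.residues

    @property
    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if not c.is_ion_group]

    @property
    def ion_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.is_ion_group]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def get_residue(self, chain_id: str, resseq: int, icode: str = "") -> Residue:
        for r in self.chain(chain_id).residues:
            if r.resseq == resseq and r.icode == icode:
                return r
        raise KeyError(f"no residue {chain_id}:{resseq}{icode}")

    def atom_indices(self, chain_ids=None, backbone_only: bool = False,
                     resseq_range: tuple[int, int] | None = None) -> np.ndarray:
        idx = []
        for c in self.chains:
            if chain_ids is not None and c.chain_id not in chain_ids:
                continue
            for r in c.residues:
                if resseq_range is not None and not (
                        resseq_range[0] <= r.resseq <= resseq_range[1]):
                    continue
                for a in r.atoms:
                    if backbone_only and not a.is_backbone:
                        continue
                    idx.append(a.index)
        return np.array(idx, dtype=int)

    def sequence(self, chain_id: str) -> str:
        return "".join(THREE_TO_ONE.get(r.resname, "X")
                       for r in self.chain(chain_id).residues)

    # -- construction helpers ----------------------------------------------
    def copy(self) -> "Structure":
        chains = _copy.deepcopy(self.chains)
        return Structure(chains, coords=self.coords.copy(),
                         metadata=dict(self.metadata))

    def with_coords(self, coords: np.ndarray) -> "Structure":
        chains = _copy.deepcopy(self.chains)
        return Structure(chains, coords=np.asarray(coords, float),
                         metadata=dict(self.metadata))

    def single_model(self, i: int = 0) -> "Structure":
        return self.with_coords(self.coords[i][None, :, :])

    def merge(self, other: "Structure", metadata: dict | None = None) -> "Structure":
        """Concatenate chains of two single-frame structures (ids must be disjoint)."""
        if self.n_models != other.n_models:
            raise ValueError("cannot merge structures with different model counts")
        mine = {c.chain_id for c in self.chains}
        theirs = {c.chain_id for c in other.chains}
        if mine & theirs:
            raise ValueError(f"chain id collision: {sorted(mine & theirs)}")
        chains = _copy.deepcopy(self.chains) + _copy.deepcopy(other.chains)
        coords = np.concatenate([self.coords, other.coords], axis=1)
        return Structure(chains, coords=coords, metadata=metadata or {})


@dataclass
class SasaResult:
    per_residue_sasa: dict[tuple[str, int, str], float]
    per_residue_relative: dict[tuple[str, int, str], float]
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(sum(self.per_residue_sasa.values()))


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _dedupe_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties by first encountered."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for at in res:
        if at.name not in best:
            best[at.name] = at
            order.append(at.name)
        elif at.occ > best[at.name].occ:
            best[at.name] = at
    return [best[n] for n in order]


def read_pdb(path, model_policy: str = "first") -> Structure:
    """Read a PDB file into a Structure.

    ``model_policy='first'`` keeps model 1 only; ``'all'`` loads every MODEL
    as a frame (topologies must match).  Waters are dropped; monatomic ions
    (Na+, Cl-, ...) are kept in dedicated ion chains.
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records")

    gm_models = [st[0]] if model_policy == "first" else list(st)

    chains: list[Chain] = []
    ion_residues: dict[str, Residue] = {}
    kept: list[tuple[int, int, int]] = []  # (chain idx, residue idx, atom idx in dedupe)
    model0 = gm_models[0]
    coords0: list[np.ndarray] = []

    def _new_chain(cid, is_ion=False):
        ch = Chain(chain_id=cid, is_ion_group=is_ion)
        chains.append(ch)
        return ch

    ion_chain: Chain | None = None
    for ci, gch in enumerate(model0):
        our_chain: Chain | None = None
        for ri, gres in enumerate(gch):
            if gres.is_water() or gres.name.strip() in WATER_NAMES:
                continue
            atoms = _dedupe_altlocs(gres)
            is_ion = gres.name.strip() in ION_NAMES and len(atoms) == 1
            if is_ion:
                if ion_chain is None:
                    ion_chain = _new_chain("_ions", is_ion=True)
                target = ion_chain
            else:
                if our_chain is None:
                    our_chain = _new_chain(gch.name)
                target = our_chain
            res = Residue(chain_id=target.chain_id, resseq=gres.seqid.num,
                          resname=gres.name.strip(),
                          icode=(gres.seqid.icode or "").strip())
            for ai, gat in enumerate(atoms):
                el = gat.element.name.upper() if gat.element else ""
                if not el:
                    el = element_from_name(gat.name, gres.name)
                res.atoms.append(Atom(name=gat.name, element=el.capitalize(),
                                      coord=np.array([gat.pos.x, gat.pos.y, gat.pos.z]),
                                      occupancy=gat.occ))
                coords0.append(res.atoms[-1].coord)
                kept.append((ci, ri, ai))
            target.residues.append(res)

    if not coords0:
        raise EmptyStructureError(f"{path}: no non-water atoms")

    if len(gm_models) == 1:
        coords = np.stack(coords0)[None, :, :]
    else:
        frames = [np.stack(coords0)]
        for gm in gm_models[1:]:
            fr = np.empty((len(kept), 3))
            for k, (ci, ri, ai) in enumerate(kept):
                try:
                    gat = _dedupe_altlocs(gm[ci][ri])[ai]
                except IndexError as exc:
                    raise PDBParseError(
                        f"{path}: model {gm.name} does not match model 1 topology"
                    ) from exc
                fr[k] = (gat.pos.x, gat.pos.y, gat.pos.z)
            frames.append(fr)
        coords = np.stack(frames)

    return Structure(chains, coords=coords,
                     metadata={"source": str(path), "model_policy": model_policy})


_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999


def write_pdb(s: Structure, path) -> None:
    """Write a Structure as PDB; multi-frame structures get MODEL/ENDMDL framing."""
    if not s.chains or s.n_atoms == 0:
        raise ValueError("cannot write an empty structure")
    if s.coords.max() > _PDB_COORD_MAX or s.coords.min() < _PDB_COORD_MIN:
        raise PDBFormatError("coordinates overflow fixed-width PDB columns")
    st = gemmi.Structure()
    st.name = "coassembler"
    for m in range(s.n_models):
        gm = gemmi.Model(m + 1)
        frame = s.frame(m)
        for ch in s.chains:
            gch = gemmi.Chain(_pdb_chain_id(ch))
            for res in ch.residues:
                gres = gemmi.Residue()
                gres.name = res.resname
                gres.seqid = gemmi.SeqId(res.resseq, res.icode or " ")
                gres.het_flag = "H" if ch.is_ion_group else "A"
                for a in res.atoms:
                    gat = gemmi.Atom()
                    gat.name = a.name
                    gat.element = gemmi.Element(a.element)
                    gat.occ = a.occupancy
                    x, y, z = frame[a.index]
                    gat.pos = gemmi.Position(x, y, z)
                    gres.add_atom(gat)
                gch.add_residue(gres)
            gm.add_chain(gch)
        st.add_model(gm)
    st.setup_entities()
    doc_opts = gemmi.PdbWriteOptions(minimal=True, numbered_ter=False)
    st.write_pdb(str(path), doc_opts)


_ION_CHAIN_ALIAS = "i"


def _pdb_chain_id(ch: Chain) -> str:
    cid = ch.chain_id
    if len(cid) <= 2:
        return cid
    return _ION_CHAIN_ALIAS if ch.is_ion_group else cid[:2]


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------

def shrake_rupley_sasa(s: Structure, probe: float = 1.4,
                       n_points: int = 960, frame: int | None = None,
                       include_ions: bool = False) -> SasaResult:
    """Per-residue solvent-accessible surface area by the Shrake–Rupley method.

    Requires a single model unless ``frame`` selects one.  Ions are excluded
    from both the occlusion set and the report by default (bulk-solvent ions
    should not shadow the protein surface).
    """
    if frame is None:
        if s.n_models != 1:
            raise ValueError("structure has several models; pass frame=...")
        frame = 0
    coords_all = s.frame(frame)

    residues = list(s.residues(include_ions=include_ions))
    atom_idx = np.concatenate([r.atom_indices for r in residues])
    coords = coords_all[atom_idx]
    radii = np.array([a.vdw_radius for r in residues for a in r.atoms]) + probe

    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    neighbor_lists = tree.query_ball_point(coords, r=radii + max_r)
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        neigh = np.array([j for j in neighbor_lists[i] if j != i], dtype=int)
        if len(neigh) == 0:
            areas[i] = 4.0 * np.pi * radii[i] ** 2
            continue
        pts = coords[i] + radii[i] * unit
        d2 = ((pts[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(axis=2)
        exposed = np.all(d2 > radii[neigh][None, :] ** 2, axis=1)
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()

    per_res: dict[tuple[str, int, str], float] = {}
    per_rel: dict[tuple[str, int, str], float] = {}
    pos = 0
    for r in residues:
        n = len(r.atoms)
        sasa = float(areas[pos:pos + n].sum())
        pos += n
        per_res[r.key] = sasa
        ref = MAX_ASA.get(r.resname.upper())
        per_rel[r.key] = min(sasa / ref, 1.2) if ref else 1.0
    return SasaResult(per_residue_sasa=per_res, per_residue_relative=per_rel,
                      probe=probe, n_points=n_points)
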