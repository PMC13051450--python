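"""Contact-class binding-affinity model and Kd/ΔG thermodynamics.

Predicted binding free energy follows the published contact-based linear
model of Vangone & Bonvin (eLife 2015, the model behind the PRODIGY server):
interfacial residue-residue contacts (any heavy-atom pair within a distance
cutoff) are binned by the polarity classes of the two residues, combined
linearly with the percentage composition of the non-interacting surface
(NIS), and offset by an intercept.  ΔG and Kd interconvert as
ΔG = R·T·ln Kd with R = 1.987204e-3 kcal/(mol·K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from coassembler.structio import Structure, shrake_rupley_sasa

R_KCAL = 1.987204e-3  # kcal mol^-1 K^-1
DEFAULT_TEMPERATURE = 298.15

# published coefficients of the contact-based ΔG model (Vangone & Bonvin,
# eLife 2015;4:e07454): IC counts by class pair and %NIS terms + intercept.
COEFF_IC_CHARGED_CHARGED = -0.09459
COEFF_IC_CHARGED_APOLAR = -0.10007
COEFF_IC_POLAR_POLAR = 0.19577
COEFF_IC_POLAR_APOLAR = -0.22671
COEFF_NIS_APOLAR = 0.18681
COEFF_NIS_CHARGED = 0.13810
INTERCEPT = -15.9433


@dataclass
class ContactSet:
    ic_cc: int = 0        # charged-charged
    ic_ca: int = 0        # charged-apolar
    ic_pp: int = 0        # polar-polar
    ic_pa: int = 0        # polar-apolar
    ic_other: int = 0     # charged-polar + apolar-apolar (no model weight)
    nis_apolar: float = 0.0   # % of NIS residues that are apolar
    nis_charged: float = 0.0  # % of NIS residues that are charged
    cutoff: float = 5.5

    def __post_init__(self):
        counts = (self.ic_cc, self.ic_ca, self.ic_pp, self.ic_pa, self.ic_other)
        if any(c < 0 for c in counts):
            raise ValueError("contact counts must be non-negative")
        for p in (self.nis_apolar, self.nis_charged):
            if not 0.0 <= p <= 100.0:
                raise ValueError("NIS percentages must be within [0, 100]")

    @property
    def total_contacts(self) -> int:
        return self.ic_cc + self.ic_ca + self.ic_pp + self.ic_pa + self.ic_other


@dataclass
class AffinityEstimate:
    dG: float          # kcal/mol
    Kd: float          # M
    temperature: float

    def __post_init__(self):
        expected = R_KCAL * self.temperature * np.log(self.Kd)
        if abs(expected - self.dG) > 1e-9 * max(1.0, abs(self.dG)):
            raise ValueError("dG and Kd are thermodynamically inconsistent")


@dataclass
class SnapshotScore:
    frame_index: int
    dG: float
    run_id: str


def dG_from_Kd(Kd: float, T: float = DEFAULT_TEMPERATURE) -> float:
    """Standard binding free energy (kcal/mol) from a dissociation constant."""
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    return R_KCAL * T * float(np.log(Kd))


def Kd_from_dG(dG: float, T: float = DEFAULT_TEMPERATURE) -> float:
    """Dissociation constant (M) from a binding free energy (kcal/mol)."""
    return float(np.exp(dG / (R_KCAL * T)))


def _partner_residues(s: Structure, chain_ids) -> list:
    out = []
    for cid in chain_ids:
        ch = s.chain(cid)
        if ch.is_ion_group:
            continue
        out.extend(ch.residues)
    return out


def interfacial_contacts(complex_structure: Structure, partner_a, partner_b,
                         cutoff: float = 5.5, frame: int = 0,
                         nis_rel_sasa: float = 0.05,
                         sasa_n_points: int = 240) -> ContactSet:
    """Classify interfacial residue contacts and the non-interacting surface.

    A residue pair (a in A, b in B) is in contact iff any heavy-atom pair is
    within ``cutoff``.  Contacts are binned by the polarity classes of the
    two residues.  NIS percentages are the class composition of surface
    residues (relative SASA >= ``nis_rel_sasa``) that take part in no
    interfacial contact.
    """
    partner_a, partner_b = set(partner_a), set(partner_b)
    if partner_a & partner_b:
        raise ValueError("partner chain sets overlap")
    if not partner_a or not partner_b:
        raise ValueError("partner chain sets must be non-empty")

    res_a = _partner_residues(complex_structure, partner_a)
    res_b = _partner_residues(complex_structure, partner_b)
    fr = complex_structure.frame(frame)

    heavy = {}
    for r in res_a + res_b:
        idx = np.array([a.index for a in r.atoms if a.element != "H"], int)
        heavy[r.key] = idx

    contacts: list[tuple] = []
    in_contact: set = set()
    if cutoff > 0:
        atoms_a = np.concatenate([heavy[r.key] for r in res_a])
        atoms_b = np.concatenate([heavy[r.key] for r in res_b])
        owner_a = np.concatenate([np.full(len(heavy[r.key]), i)
                                  for i, r in enumerate(res_a)])
        owner_b = np.concatenate([np.full(len(heavy[r.key]), i)
                                  for i, r in enumerate(res_b)])
        tree_b = cKDTree(fr[atoms_b])
        pairs_found = set()
        neighbor_lists = tree_b.query_ball_point(fr[atoms_a], r=cutoff)
        for ia, neigh in enumerate(neighbor_lists):
            for ib in neigh:
                pairs_found.add((int(owner_a[ia]), int(owner_b[ib])))
        for i, j in sorted(pairs_found):
            contacts.append((res_a[i], res_b[j]))
            in_contact.add(res_a[i].key)
            in_contact.add(res_b[j].key)

    bins = {"cc": 0, "ca": 0, "pp": 0, "pa": 0, "other": 0}
    for ra, rb in contacts:
        classes = frozenset((ra.polarity_class, rb.polarity_class)) \
            if ra.polarity_class != rb.polarity_class \
            else frozenset((ra.polarity_class,))
        if classes == frozenset(("charged",)):
            bins["cc"] += 1
        elif classes == frozenset(("charged", "apolar")):
            bins["ca"] += 1
        elif classes == frozenset(("polar",)):
            bins["pp"] += 1
        elif classes == frozenset(("polar", "apolar")):
            bins["pa"] += 1
        else:
            bins["other"] += 1

    sasa = shrake_rupley_sasa(complex_structure, n_points=sasa_n_points,
                              frame=frame)
    nis_counts = {"charged": 0, "polar": 0, "apolar": 0}
    for r in res_a + res_b:
        if r.key in in_contact:
            continue
        if sasa.per_residue_relative.get(r.key, 0.0) >= nis_rel_sasa:
            nis_counts[r.polarity_class] += 1
    n_nis = sum(nis_counts.values())
    nis_apolar = 100.0 * nis_counts["apolar"] / n_nis if n_nis else 0.0
    nis_charged = 100.0 * nis_counts["charged"] / n_nis if n_nis else 0.0

    return ContactSet(ic_cc=bins["cc"], ic_ca=bins["ca"], ic_pp=bins["pp"],
                      ic_pa=bins["pa"], ic_other=bins["other"],
                      nis_apolar=nis_apolar, nis_charged=nis_charged,
                      cutoff=cutoff)


def predict_dG(contacts: ContactSet,
               temperature: float = DEFAULT_TEMPERATURE) -> AffinityEstimate:
    """Linear contact-class ΔG model with the published coefficients."""
    dG = (COEFF_IC_CHARGED_CHARGED * contacts.ic_cc
          + COEFF_IC_CHARGED_APOLAR * contacts.ic_ca
          + COEFF_IC_POLAR_POLAR * contacts.ic_pp
          + COEFF_IC_POLAR_APOLAR * contacts.ic_pa
          + COEFF_NIS_APOLAR * contacts.nis_apolar
          + COEFF_NIS_CHARGED * contacts.nis_charged
          + INTERCEPT)
    return AffinityEstimate(dG=dG, Kd=Kd_from_dG(dG, temperature),
                            temperature=temperature)


def score_frames(ensemble: Structure, partner_a, partner_b,
                 cutoff: float = 5.5, sasa_n_points: int = 240,
                 temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Per-frame predicted ΔG (kcal/mol) across an ensemble."""
    return np.array([
        predict_dG(interfacial_contacts(ensemble, partner_a, partner_b,
                                        cutoff=cutoff, frame=f,
                                        sasa_n_points=sasa_n_points),
                   temperature=temperature).dG
        for f in range(ensemble.n_models)
    ])


def mean_sd_string(values: np.ndarray, decimals: int = 2) -> str:
    """Format an ensemble ΔG summary as "mean ± sd" (kcal/mol)."""
    values = np.asarray(values, float)
    return f"{values.mean():.{decimals}f} ± {values.std(ddof=1):.{decimals}f}"


def select_snapshots(ensembles: list[Structure], partner_a, partner_b,
                     k_runs: int = 2, k_frames: int = 1,
                     run_ids: list[str] | None = None,
                     cutoff: float = 5.5,
                     sasa_n_points: int = 240) -> list[SnapshotScore]:
    """Lowest-ΔG frames from the runs with the lowest mean predicted ΔG.

    Runs are ranked ascending by mean per-frame ΔG; within the ``k_runs``
    best runs the ``k_frames`` lowest-ΔG frames are returned.  Ties break by
    run order, then frame index.
    """
    if not ensembles:
        raise ValueError("need at least one ensemble")
    if run_ids is None:
        run_ids = [f"run{i}" for i in range(len(ensembles))]
    per_run = []
    for rid, ens in zip(run_ids, ensembles):
        if ens.n_models < 1:
            raise ValueError(f"ensemble {rid} is empty")
        dg = score_frames(ens, partner_a, partner_b, cutoff=cutoff,
                          sasa_n_points=sasa_n_points)
        per_run.append((rid, dg))
    order = sorted(range(len(per_run)),
                   key=lambda i: (per_run[i][1].mean(), i))
    selected: list[SnapshotScore] = []
    for i in order[:k_runs]:
        rid, dg = per_run[i]
        frame_order = sorted(range(len(dg)), key=lambda f: (dg[f], f))
        for f in frame_order[:k_frames]:
            selected.append(SnapshotScore(frame_index=f, dG=float(dg[f]),
                                          run_id=rid))
    return selected
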