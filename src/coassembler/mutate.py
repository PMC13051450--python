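"""In-silico point substitution and wild-type vs mutant ensemble comparison.

A substitution replaces one residue's side chain with the single-rotamer
template for the new residue type, aligned on the local backbone frame; the
backbone never moves.  Variant comparison joins run-status tables (interface
persistence per run) with ensemble affinity summaries and reports descriptive
deltas only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from coassembler import affinity as _affinity
from coassembler import interfaces as _interfaces
from coassembler._sidechains import build_sidechain
from coassembler.structio import Atom, Structure, element_from_name


@dataclass
class Substitution:
    chain: str
    resseq: int
    from_resname: str
    to_resname: str

    @classmethod
    def parse(cls, text: str) -> "Substitution":
        """Parse 'A:422:ILE:THR'."""
        chain, resseq, frm, to = text.split(":")
        return cls(chain=chain, resseq=int(resseq),
                   from_resname=frm.upper(), to_resname=to.upper())


def apply_substitution(s: Structure, sub: Substitution) -> Structure:
    """Return a copy with one residue's side chain replaced.

    The backbone (N, CA, C, O) is bit-identical to the input; side-chain
    atoms are rebuilt from the template rotamer in the residue's backbone
    frame (a glycine target keeps no side chain; a glycine source gets a CB
    constructed from ideal tetrahedral geometry).
    Raises if the residue's current name differs from ``from_resname``.
    """
    if s.n_models != 1:
        raise ValueError("apply to a single-model structure (mutate, then perturb)")
    site = s.get_residue(sub.chain, sub.resseq)
    if site.resname.upper() != sub.from_resname.upper():
        raise ValueError(
            f"site {sub.chain}:{sub.resseq} is {site.resname}, "
            f"not {sub.from_resname}")

    new = s.copy()
    res = new.get_residue(sub.chain, sub.resseq)
    backbone = {a.name: a for a in res.atoms if a.is_backbone}
    missing = {"N", "CA", "C"} - set(backbone)
    if missing:
        raise ValueError(f"site lacks backbone atoms {sorted(missing)}")

    fr0 = new.frame(0)
    n = fr0[backbone["N"].index].copy()
    ca = fr0[backbone["CA"].index].copy()
    c = fr0[backbone["C"].index].copy()
    new_side = build_sidechain(sub.to_resname, n, ca, c)

    res.atoms = [a for a in res.atoms if a.is_backbone]
    res.resname = sub.to_resname.upper()
    fresh = set()
    for name, coord in new_side:
        atom = Atom(name=name,
                    element=element_from_name(name, sub.to_resname),
                    coord=np.asarray(coord, float))
        res.atoms.append(atom)
        fresh.add(id(atom))

    # rebuild the coordinate table in topology order; template side-chain
    # coordinates are identical across frames (the edit is frame-independent)
    columns = []
    for ch in new.chains:
        for r in ch.residues:
            for a in r.atoms:
                if id(a) in fresh:
                    columns.append(np.repeat(a.coord[None, :], new.n_models,
                                             axis=0))
                else:
                    columns.append(new.coords[:, a.index, :])
    coords = np.stack(columns, axis=1)

    return Structure(new.chains, coords=coords,
                     metadata={**new.metadata,
                               "substitution": f"{sub.chain}:{sub.resseq}:"
                               f"{sub.from_resname}>{sub.to_resname}"})


@dataclass
class ComparisonReport:
    wt_runs: dict
    mut_runs: dict
    wt_dG_mean: float
    wt_dG_sd: float
    mut_dG_mean: float
    mut_dG_sd: float
    delta_maintained: dict[str, int]  # WT - mutant, per interface
    delta_dG: float                   # WT - mutant mean dG

    def summary(self) -> dict:
        return {
            "wt": {"dG": f"{self.wt_dG_mean:.2f} ± {self.wt_dG_sd:.2f}",
                   "interfaces": self.wt_runs["summary"]},
            "mut": {"dG": f"{self.mut_dG_mean:.2f} ± {self.mut_dG_sd:.2f}",
                    "interfaces": self.mut_runs["summary"]},
            "delta_maintained_wt_minus_mut": self.delta_maintained,
            "delta_dG_wt_minus_mut": self.delta_dG,
        }


def compare_variants(wt_ensembles: list[Structure],
                     mut_ensembles: list[Structure],
                     seeds: dict[str, list],
                     partner_a, partner_b,
                     cutoff: float = _interfaces.CONTACT_CUTOFF,
                     contact_cutoff: float = 5.5,
                     sasa_n_points: int = 240) -> ComparisonReport:
    """Joint WT vs mutant report: run statuses per interface and mean ± SD of
    per-frame predicted ΔG pooled over runs.  Descriptive deltas only."""
    if not wt_ensembles or not mut_ensembles:
        raise ValueError("both variant ensemble lists must be non-empty")
    if len(wt_ensembles) != len(mut_ensembles):
        raise ValueError("variants must have equal run counts for comparison")

    wt_runs = _interfaces.classify_runs(wt_ensembles, seeds, cutoff=cutoff)
    mut_runs = _interfaces.classify_runs(mut_ensembles, seeds, cutoff=cutoff)

    def pooled_dg(ensembles):
        vals = np.concatenate([
            _affinity.score_frames(e, partner_a, partner_b,
                                   cutoff=contact_cutoff,
                                   sasa_n_points=sasa_n_points)
            for e in ensembles])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return float(vals.mean()), sd

    wt_mean, wt_sd = pooled_dg(wt_ensembles)
    mut_mean, mut_sd = pooled_dg(mut_ensembles)

    delta = {label: wt_runs["summary"][label]["maintained"]
             - mut_runs["summary"][label]["maintained"]
             for label in seeds}
    return ComparisonReport(wt_runs=wt_runs, mut_runs=mut_runs,
                            wt_dG_mean=wt_mean, wt_dG_sd=wt_sd,
                            mut_dG_mean=mut_mean, mut_dG_sd=mut_sd,
                            delta_maintained=delta,
                            delta_dG=wt_mean - mut_mean)
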