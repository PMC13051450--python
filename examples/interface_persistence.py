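"""Interface persistence across engineered ensembles: wild type vs I422T.

Generates sampling-run ensembles whose contact schedules mirror the study's
run-maintenance pattern — the wild-type binder keeps the co-assembly
interface (BI1) in 5 of 8 runs and the β-bridge interface (BI3) in 3 of 8,
while the threonine mutant keeps BI1 in a single run and never forms BI3 —
then recovers those counts with the run classifier.
"""

from coassembler.coassemble import assemble_complex, scan_similarity
from coassembler.fixtures import (
    DEFAULT_BINDER_START,
    BinderSpec,
    ContactDirective,
    EnsembleSpec,
    FibrilSpec,
    build_binder,
    build_fibril,
    perturb_ensemble,
)
from coassembler.interfaces import classify_runs
from coassembler.mutate import Substitution, apply_substitution

fibril = build_fibril(FibrilSpec())
binder = build_binder(BinderSpec())
match = scan_similarity(binder.sequence("X"), fibril.sequence("A")[:20],
                        window=8, min_identity=0.5,
                        binder_start=DEFAULT_BINDER_START)[0]
wt = assemble_complex(binder, fibril, match).structure
mut = apply_substitution(wt, Substitution("X", 422, "ILE", "THR"))

SEEDS = {"BI1": [(("X", 429), ("E", 4))],
         "BI3": [(("X", 422), ("D", 23))]}


def make_runs(structure, bi1_pattern, bi3_pattern, seed0):
    runs = []
    for i, (b1, b3) in enumerate(zip(bi1_pattern, bi3_pattern)):
        schedule = [
            ContactDirective("BI1", mobile=("X", 429), anchor=("E", 4),
                             profile=("always",) if b1 else ("never",)),
            ContactDirective("BI3", mobile=("X", 422), anchor=("D", 23),
                             profile=("always",) if b3 else ("never",)),
        ]
        runs.append(perturb_ensemble(structure, EnsembleSpec(
            n_frames=5, backbone_noise_sd=0.1, contact_schedule=schedule,
            seed=seed0 + i)))
    return runs


wt_runs = make_runs(wt, [True] * 5 + [False] * 3,
                    [True] * 3 + [False] * 5, seed0=0)
mut_runs = make_runs(mut, [True] + [False] * 7, [False] * 8, seed0=100)

for label, runs in (("wild type", wt_runs), ("I422T", mut_runs)):
    summary = classify_runs(runs, SEEDS)["summary"]
    print(f"{label}: BI1 maintained in {summary['BI1']['maintained']}/8 runs,"
          f" BI3 maintained in {summary['BI3']['maintained']}/8 runs")
# Expected output: 5/8 and 3/8 for the wild type, 1/8 and 0/8 for the
# mutant — the persistence classifier reads the engineered schedules back
# exactly (maintained = at least one member pair in contact in >=75% of
# frames).
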