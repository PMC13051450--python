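# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the limits of what the test suite demonstrates.

## Structure model and chemistry classes

Structures are chain → residue → atom hierarchies with all frame coordinates
in one `(n_models, n_atoms, 3)` array; author residue numbering is preserved
verbatim so positions such as 422 (the *nur17* site) or amyloid-β D23 keep
their literature numbering. PDB reading/writing is delegated to gemmi;
waters are dropped, monatomic ions (Na⁺, Cl⁻, …) are kept in a dedicated ion
group for proximity analysis, and alternate locations resolve to the highest
occupancy (first wins on ties).

Residue polarity classes are a fixed table: charged = {ARG, LYS, ASP, GLU},
polar = {ASN, GLN, SER, THR, TYR, TRP, HIS, CYS}, apolar = the remainder.
Histidine is polar by default (`his_charged=True` moves it to charged;
protonation is a convention, not an observation, and is echoed into output
metadata); methionine is apolar by default (`met_polar=True` available).
This table governs both similarity scanning and contact classification. The
affinity model's published coefficients are used unchanged with this table;
the original predictor's own class table differs for Cys/Trp, so absolute
ΔG values on real complexes may shift slightly relative to the original
server — a deliberate single-source-of-truth choice.

SASA uses an own Shrake–Rupley implementation (golden-spiral sphere points,
default 960/atom, probe 1.4 Å) with Tien et al. (2013) theoretical
Gly-X-Gly maxima for relative SASA. At 960 points the per-residue
discretisation error is ≲1 Å² (≈1% for exposed residues); ions are excluded
from occlusion and reporting, since bulk-solvent ions should not shadow the
protein surface.

## Synthetic generators

The generators produce inputs with the *geometric and statistical structure*
of the study's real inputs, so every analysis stage runs and is testable
offline. They make no claim of thermodynamic or conformational realism —
frames exist to exercise analysis contracts.

**Fibril.** An idealized β strand (φ = −119°, ψ = +113°, trans ω, standard
bond geometry) is stacked at a 4.8 Å rise along a stacking axis chosen by a
deterministic local optimisation that minimises deviations of the
inter-strand O(i)···N(i+1) ladder from 2.9 Å. Parallel in-register stacking
is pure translation; the antiparallel arrangement flips alternate strands
180° about the sheet normal. The resulting sheets carry genuine
Kabsch–Sander H-bond ladders and bridges — detectors are validated against
the construction, not against hand-placed labels. The edge monomer's first
`disordered_nterm_len` residues (default 8) are hinged out of the sheet by a
35° lever rotation about the sheet normal through the junction nitrogen,
leaving an extended, unpaired strand — the stand-in for the flexible
N-terminal strand of an edge monomer. Side chains are single
all-anti template rotamers with idealized internal coordinates; ring
geometry is approximate. Templates provide correctly named heavy atoms for
contact chemistry (e.g. Lys NZ, Glu OE1/OE2), not packing accuracy. Default
sequence: the 42-residue amyloid-β peptide.

**Binder.** A single chain with a chosen segment in β geometry and flanks in
polyproline-II coil (or α helix), default sequence
`SGSGVGAPVIGEIDGEYRHDS` numbered from 413 so that the `DGEYRHDS` strand
occupies author positions 426–433 and the isoleucine of interest position
422. Ending the chain at the strand keeps the docked model clash-free by
construction; the strand is solvent-exposed (mean relative SASA > 0.3).

**Ensembles.** Frames = base coordinates + isotropic Gaussian noise of a
stated SD, plus a per-pair contact schedule (`always`, `never`,
`fraction f`, `dissociate_after k`). Enforcement iteratively translates the
pair's *mobile residue* along the closest-atom-pair axis until the minimum
heavy-atom distance is < 4.5 Å (in contact) or > 8 Å (apart). A whole-body
rigid translation of one partner was rejected because independent per-pair
schedules (one interface maintained while another dissociates in the same
frame) are mutually unsatisfiable under a single rigid motion; the local
enforcement trades physical plausibility of the frame for exact, independent
control of each labelled contact. `fraction f` places exactly
`round(f·n_frames)` contact frames at seeded-random positions, so measured
persistence equals f up to 1/n_frames. Defaults: 100 frames, 0.15 Å noise.

**ITC isotherms.** Forward heats from the model below plus Gaussian noise
of 2% of the largest |injection heat|. The default titration mirrors the
reported experiment's scale: 25 × 10 μL injections into a 1.4 mL cell of
10 μM macromolecule with ~2 mM titrant (final molar ratio ≈ 39), site
classes n = 2.5 / K_d = 121 nM and n = 18 / K_d = 1.92 μM. Enthalpies are
not reported and are generator choices, made once: ΔH₁ = −8 kcal/mol (an
enthalpy-driven, H-bond-rich co-assembly interface, |ΔH₁| ≈ |ΔG₁|) and
ΔH₂ = +2 kcal/mol (entropy-driven nonspecific surface adsorption, TΔS ≈
9.8 kcal/mol — the classic hydrophobic signature). Opposite signs are also
what makes the two site classes spectrally distinguishable in a single
titration curve.

## Complex construction

Similarity scanning scores all gapless windows by identity and by
polarity-class similarity, sorted descending with deterministic tie-breaks.
Superposition is Kabsch least squares (SVD with reflection correction) over
backbone {N, CA, C, O} by default, CA-only as an option; correctness is
cross-checked against Horn's closed-form quaternion solution. Note that
RMSDs over *different* atom selections are not nested quantities: reducing
the selection is guaranteed not to increase the RMSD only when both
transforms are evaluated on the same (reduced) selection, which is the
monotone property the tests assert.

Assembly superposes the binder segment onto the (displaced) edge-monomer
segment; only the binder moves, the assembly's coordinates stay
bit-identical. The clash census counts inter-partner heavy-atom pairs below
2.5 Å, excluding pairs where both residues lie within the matched segments
padded by one residue — the matched region is a near-duplicate by
construction, and the padding covers the bonded junctions; models with more
than 5 clashes are flagged, never silently dropped.

## Interface analysis

Hydrogen bonds use the Kabsch–Sander electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with the DSSP
−0.5 kcal/mol cutoff and geometric amide-H placement (H on N along the
preceding C=O direction, 1.01 Å; standard practice for H-less structures).
β-bridges apply the Kabsch–Sander parallel/antiparallel patterns. Salt
bridges pair opposite-charge side-chain group atoms within 4.0 Å.

**Interaction maps are a surrogate.** The per-pair, per-frame polar score is
−(1.0·H-bonds + 1.5·salt bridges) and the non-polar score is −0.2·(apolar
carbon–carbon pairs within 4.5 Å, saturated at 10); means and SDs are taken
over frames. The weights are documented, configurable constants chosen to
put typical single-contact scores on a kcal/mol-like scale; they are *not*
force-field energies, and absolute map values are not comparable to
decomposition-based maps — only the structure of the output (sign, time
averages, SD localisation to intermittent contacts) is contractual.

Binding interfaces are seeded residue-pair sets (or single-linkage clusters
of significant map cells with sequence gap ≤ 2); persistence is the fraction
of frames with ≥ 1 member pair within 4.5 Å; status thresholds are
maintained ≥ 0.75, partial ≥ 0.25, lost otherwise (configurable —
"fully/partially maintained" have no standard quantitative definition).
"Remained throughout" means persistence 1.0 within one frame. Run
classification simply applies this per run and counts statuses.

Order metrics treat each strand's first→last CA unit vector: P2 is the
largest eigenvalue of the nematic Q-tensor (1.0 for both parallel and
antiparallel order), P1 the mean projection onto the director (≈1 parallel,
≈0 antiparallel). RMSD series use per-frame Kabsch fits against either the
first frame or a mean structure computed by two alignment iterations.

Monomer indexing convention: the first/second "most proximal" assembly
monomers are ranked by centroid distance to the binder. Frame indices are
0-based; residues are always author-numbered.

## ITC model, fitting, and design identifiability

The forward model is the standard independent-sites perfusion-cell
formulation (displacement dilution: each species scaled by (1 − dV/V₀) per
injection; free titrant by vectorised bisection to relative 1e-15; the
injection heat includes the (dV/V₀)·(Q_i + Q_{i−1})/2 displaced-volume
term). The one-site closed form (Wiseman isotherm) serves as an independent
oracle in tests, never as the implementation. Fitting is multi-start
trust-region least squares in (n, log₁₀K_d, ΔH) per site class, residuals
normalised by the heat scale, bounds n ∈ (0, 100], K_d ∈ [10⁻¹², 1] M; site
classes are reported sorted by ascending K_d with delta-method standard
errors. Model selection is an F-test on the RSS reduction (α = 0.01) or
AICc; exact ties go to the simpler model.

A design note: with 25 equal injections spanning molar ratio 0–40, the
high-affinity transition (c = n·M/K_d ≈ 200, centred near ratio 2.5) is
crossed by only ~2 points. A Cramér–Rao analysis of this design at 2% heat
noise puts the relative SD of the fitted high-affinity K_d at ≈ 19–39%
depending on the enthalpy pair (≈ 34% at the defaults), while the
stoichiometries are tight (n₁ ≈ 7%, n₂ ≈ 1.5%). Recovered K_d values
therefore scatter seed-to-seed well beyond the stoichiometries' scatter;
this is a property of the titration design, not of the optimiser — the fits
reach noise-level residuals, and noise-free data are recovered to machine
precision. At 0.5% noise the K_d estimator's *bias* is ~1% (20-seed Monte
Carlo in the tests).

## Pipeline

`run_pipeline` chains the stages deterministically (a global seed fans out
to per-stage offsets): fixtures → complex → 8 wild-type and 8 I422T sampling
ensembles whose schedules engineer the 5/8 (BI1) and 3/8 (BI3) wild-type
versus 1/8 / 0/8 mutant maintenance pattern → snapshot selection →
interaction maps, run classification, order and RMSD summaries → variant
comparison → ITC simulate/fit/select, ending with the concordance
|ΔG_ITC − mean ΔG_structural|. Pipeline defaults (8 runs × 10 frames,
144 SASA points) keep a full run at a few minutes on one CPU; tests use
smaller problem sizes (2–8 runs × 3–6 frames, 60-point SASA) chosen as the
smallest sets that still exercise every contract.

## What passing tests do and do not show

Generators are validated against their own constructions (bridge ladders,
rise, persistence schedules), detectors against exhaustive brute-force
enumerations, superposition against a quaternion oracle, the ITC solver
against a closed form, and the engineered run patterns against their
schedules. None of this demonstrates accuracy on *real* structures or
calorimetry: template rotamers are not packed side chains, surrogate maps
are not interaction free energies, scheduled ensembles are not molecular
dynamics, and the synthetic isotherm's enthalpies are assumptions. What the
suite does establish is that every algorithmic step is exact on inputs whose
ground truth is known, and that the full workflow is deterministic and
reproducible from a single seed.

## Known limitations

- mmCIF is not read (PDB only); hydrogens are never required or written.
- Single-rotamer side-chain templates can interpenetrate in dense packings;
  the clash census and contact analyses treat them as labelled points.
- The interaction-map surrogate saturates non-polar scores at 10 atom pairs
  and ignores solvation entirely.
- Interface clustering is single-linkage on the map grid; it does not merge
  interfaces across different partner monomers.
- The two-site ITC fit assumes independent classes; cooperative or
  competitive schemes are out of scope.
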