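# Methods

## Screen model and assumptions

The mining stage operationalises a conserved regulatory architecture:
a transcriptional regulator (TR) transcribed divergently from the operon
it controls, the two sharing one intergenic region that carries both
promoters, with the TR switched by the entry metabolite of the
operon-encoded catabolic pathway. The screen therefore assigns a TR a
role purely from genomic proximity and orientation; it makes no use of
binding-site motifs, homology or expression data, and it can only find
systems that follow this arrangement (notably LysR-type regulators; TRs
acting in *trans* on distant regulons are invisible to it).

Working definitions:

* **TR gene** — CDS whose product text matches a keyword lexicon
  (generic "transcriptional regulator/activator/repressor" plus family
  tokens LysR, MarR, AsnC, MocR, IclR, TetR, AraC, GntR, LacI, XRE,
  sigma-54 dependent). The first family token found names the family,
  else "unknown". The lexicon is a parameter; annotation vocabularies
  vary between genomes.
* **Operon** — maximal run of co-directional genes with successive
  intergenic gaps ≤ `max_gap` (default **150 bp**, a common prokaryotic
  operon-calling heuristic; configurable). TR genes are excluded from
  membership and additionally *break* runs: a regulator gene marks a
  transcription-unit boundary, and bridging a gap across an excluded TR
  could merge unrelated runs. Single-gene runs are kept and removed later
  by the catalytic filter.
* **Catalytic gene** — carries ≥ 1 EC number, or an enzyme-like product
  name (-ase suffix lexicon). TR genes never count, even with an EC
  number, so a regulator cannot satisfy its own operon filter.
* **Divergent pair** — a TR whose 5′ end faces the 5′ end of an operon's
  first gene across an intergenic region of length ≤ `max_intergenic`
  (default **500 bp**; divergent promoter regions are compact — the
  benzoate exemplar is 146 bp). Convergent and co-directional
  arrangements are excluded by construction. A promoter interval that
  overlaps any other CDS, or a negative interval (overlapping genes),
  rejects the pair. Because strand geometry fixes the promoter side of a
  TR, at most one side of a TR can host a divergent operon; when several
  operons on that side qualify, the nearest is taken.

## Ligand inference

Each operon gene's EC numbers are looked up in the reaction
knowledgebase (TSV: `ec, substrates, products, reversible`), and the
union of reactions defines a directed substrate→product compound graph.
Compounds on a cofactor blacklist (water, protons, ATP/ADP/AMP,
NAD(P)(H), CoA, phosphate, CO₂, O₂, ammonia; overridable) are removed
first — they connect everything to everything and are never plausible
effectors. The proposed ligand is the pathway's **primary substrate**:
a graph source, consumed by ≥ 1 reaction and produced by none.
Candidates are ranked by (produced_by ascending, consumed_by
descending, compound id), so sources rank first and ties break
deterministically. Reversible reactions contribute edges both ways,
which can eliminate all sources; that case is reported as an ambiguity
(`produced_by > 0` at rank 1, reason `ambiguous_cycle`) rather than
guessed. The full ranked list is always emitted so a curator can
override rank 1 — pathway intermediates are occasionally the true
effector, and no automatic rule can distinguish that case.

The "≥ 2 catalytic genes" filter (`min_catalytic`, default 2) removes
single-enzyme arrangements; an optional weak-connectivity requirement on
the compound graph (default on) approximates "one distinct metabolic
pathway" — it is an interpretation, not an established rule, and can be
switched off.

## Dose–response characterisation

Raw plate-reader channels are corrected by the mean of medium-only blank
wells per time point, then fluorescence is divided by corrected OD600:
`(FL − FL_blank)/(OD − OD_blank)` (absolute normalised fluorescence,
AFU/OD). Points with corrected OD ≤ 0.01 are masked — the ratio is
unstable at negligible biomass; the floor is configurable.

The dose–response point of a well is its normalised fluorescence at the
**minimal induction interval**, default 80 min after inducer addition:
late enough for reporter synthesis and maturation, early enough that
inducer catabolism has not yet depleted the signal. The nearest recorded
sample (not an interpolation) is used, and must lie within half the
sampling interval of the requested time.

The Hill model `RFP(I) = b_max·Iʰ/(K_mʰ + Iʰ) + b_min` is fit by
trust-region-reflective non-linear least squares
(`scipy.optimize.curve_fit`). Initialisation is generic: `b_min` at the
uninduced mean, `b_max` at max(RFP) − b_min, `h = 1`, and `K_m` at the
best node of a 25-point log-spaced grid over the observed
concentrations. Bounds: h ∈ [0.1, 10], K_m ∈ [min I>0 × 10⁻²,
max I × 10²], b_max > 0, b_min ≥ 0. `b_min` is a free parameter
initialised, not pinned, at the uninduced mean. Fitting requires ≥ 4
distinct non-zero concentrations; optimiser failure sets
`converged=False` instead of raising, and a flat response is flagged
`degenerate`. Parameter standard deviations come from the fit
covariance.

Derived quantities: dynamic range µ = b_max/b_min with σ_µ propagated in
quadrature from σ_bmax (fit covariance) and σ_bmin (replicate spread of
the uninduced wells — the basal level is directly observed, so its
uncertainty is taken from data rather than from the covariance);
µ is undefined (reported "ND") when b_min ≤ 0. Relative response
rescales points to 100·(RFP − RFP_uninduced)/b_max; without a converged
fit the observation at the highest tested concentration defines 100 %.
Fold induction is the plain induced/uninduced ratio. Intracellular
concentration applies the dilution factor
(V_pellet + V_solvent)/V_pellet to the extract concentration, with
V_pellet = wet pellet mass / 1.105 g mL⁻¹ (wet cell density; assumes no
storage-polymer accumulation). V_solvent = 0 degenerates to
C_intracellular = C_extract.

Concentrations are molar internally; fluorescence units cancel in µ,
relative response and relative induction, so all derived quantities are
scale-invariant (property-tested).

## Cross-reactivity

Relative induction of compound *c* on system *s* is
`100·(FL_c − FL_uninduced)/(FL_primary − FL_uninduced)`; it is invariant
under any common affine rescaling of the three inputs and is reported
unclamped (negative values indicate repression). A non-cognate pair is a
**hit** when rel ≥ 5 % *and* absolute fold induction ≥ 5 (both
thresholds configurable); a system is **orthogonal** when every measured
non-cognate entry is strictly < 5 %. The strict/non-strict boundary
conventions are deliberate and mirrored in the tests. Missing
(system, compound) combinations stay absent (NaN), never zero.

## Synthetic data

`fixtures.generate_toy_genome` plants divergent TR–operon cassettes
(TR with a family-labelled product; 2–4 EC-annotated genes whose
reactions form a linear pathway in the companion KB, with cofactors
mixed in to exercise blacklist removal) alongside decoys a correct
screen must reject: convergent pairs, co-directional pairs, and
single-catalytic-gene divergent pairs. Cassettes are separated by
1.5 kb — beyond `max_intergenic` — so no spurious pairings arise, and a
JSON manifest records the ground truth (TR id, promoter interval, operon
genes, entry compound). Output is byte-identical for a given spec and
seed.

`fixtures.simulate_plate_timecourse` emulates a kinetic plate run:
logistic growth (OD₀ = 0.05, OD_max = 1.5, r = 0.02 min⁻¹ — mid-log at
the 80-min window), constant medium autofluorescence/absorbance, and a
reporter whose OD-normalised truth follows the Hill law at each well's
concentration. Default truth is the β-alanine-sensor regime (b_min = 100
AFU/OD, µ = 8, K_m = 201 µM, h = 0.75) at 12 log-spaced concentrations
spanning 0.01–100 × K_m plus uninduced wells, 3 replicates, sampled
every 5 min for 6 h. Noise is multiplicative log-normal with unit mean
(plate-reader error scales with signal), applied to the signal
component; `noise_cv = 0` makes analyse∘simulate the exact identity on
the Hill parameters, which anchors the recovery tests.

What the simulator deliberately omits — and hence what passing tests do
*not* demonstrate about real data: inducer depletion and catabolism
(time-invariant truth), effector-dependent growth effects, maturation
kinetics of the reporter, plate position effects, and annotation noise
in real genomes (the toy genomes have clean, lexicon-matching product
strings). Recovery results on synthetic data bound the estimator's
behaviour under the stated noise model only.

## Numerical and design choices

* Grid initialisation of K_m avoids the flat-likelihood trap when h and
  K_m are jointly far off; the subsequent local fit is then reliably in
  the right basin (verified against an independent coarse-grid SSE
  oracle with closed-form non-negative linear parameters at every node).
* Nearest-sample window extraction, not interpolation: the value should
  be a recorded measurement.
* Ties in ligand ranking break lexicographically to keep output
  deterministic under input reordering; the screen's outputs are sorted
  by (replicon, promoter start).
* Compound identity is by normalised name string only; no structure
  resolution. The knowledgebase supplies chemistry, the package supplies
  set/graph logic.
* Exit codes in the CLI: 0 success, 2 usage error (the CLI toolkit's
  convention), 1 data error.

## Problem sizes

The test suite works at desk scale by choice: toy genomes of ~10–40 kb
with 1–5 planted systems and up to 6 decoys (100 random layouts in the
recall test), 500 random reaction sets for the ligand oracle, 20 noisy
datasets against the grid oracle, and 200 simulated experiments for the
noise-robustness check (5 % CV, 3 replicates, median K_m error ≤ 10 %).
These sizes exercise every code path while keeping the whole suite in a
few seconds.
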