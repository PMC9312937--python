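# Methods

## Scope and data model

`loopbench` evaluates predicted protein structures at the level of
individual loops. Its unit of analysis is the *loop pair*: a contiguous
fragment of an experimental structure whose residues are all classed as
none/turn/bend, matched to the fragment at the same author residue numbers
in a predicted model of identical sequence. Structures are parsed from PDB
(or mmCIF) via gemmi into a backbone-centric model — chains of residues of
atoms with coordinates and a B-factor — and tagged `experimental` or
`predicted`; the tag gates confidence-specific operations, because the
B-factor column means "crystallographic temperature factor" in one case
and "predicted confidence (pLDDT, 0–100)" in the other. Only polymer ATOM
records of the first model are read; waters and HETATM records are
dropped, alternate conformers resolve to the highest-occupancy altloc
(ties to the alphabetically first), and nonstandard residues map to `X`
and are kept only with an intact N/CA/C backbone.

## Secondary-structure assignment

The assignment is a from-scratch implementation of the classic
hydrogen-bond-pattern algorithm:

* **Hydrogens.** Backbone amide H is placed 1.0 Å from N along the O→C
  direction of the preceding carbonyl; prolines and segment-start residues
  get none.
* **Hydrogen bonds.** For donor–acceptor residue pairs (Cα within 9 Å,
  at least 2 apart in chain order) the electrostatic energy
  `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol is clamped
  at −9.9 and a bond accepted below −0.5 kcal/mol; at most the two best
  bonds per donor are kept.
* **Patterns.** An n-turn at i is a bond from N–H(i+n) to C=O(i) for
  n = 3, 4, 5; two consecutive n-turns start a minimal helix (G/H/I).
  Bridges follow the parallel/antiparallel double-bond patterns between
  non-overlapping triplets; consecutive bridges chain into ladders (E),
  isolated ones stay B, and each E/B residue records its ladder sense so
  composition tables can split parallel from antiparallel sheet. Remaining
  turn-pattern residues become T; residues whose Cα-trace bends by more
  than 70° (angle between CA(i)−CA(i−2) and CA(i+2)−CA(i)) become S.
  Overlaps resolve with priority H > E > B > G > I > T > S > C.
* **Chain breaks.** Consecutive Cα further than 4.5 Å apart, or residues
  missing backbone atoms, split a chain into segments; turn and helix
  patterns never span a break, bridges may (sheets cross chains).

A residue is *loop* iff its class is C, T or S. On ideal helices, two
sheet senses, coils, extended chains and full synthetic proteins the
collapsed loop mask — and in fact the full 8-class string — agrees exactly
with the independent DSSP implementation shipped in mdtraj; the test suite
asserts ≥95% mask agreement to leave room for class-boundary differences
between DSSP builds on less idealised inputs.

## Loop extraction and pairing

Loops are maximal mask runs per chain, ≥ `min_len` (default 3, overridable
down to 1), never crossing a segment break or an incomplete residue. Spans
are defined **only** on the experimental assignment: this is what makes
the experimental side of the composition table exactly 0% regular
secondary structure, and it mirrors how a benchmark dataset built from
experimental loop definitions behaves. Pairing is by author residue
number under a strict 100%-identity contract — no alignment machinery;
mismatching spans are rejected and logged, a missing chain is fatal.

## Metrics

* **RMSD** uses an in-package SVD Kabsch superposition (reflections
  excluded by sign-correcting the smallest singular vector; rank-deficient
  inputs flagged degenerate). The default frame is *local* — the two loop
  fragments are superposed onto each other — which is the natural reading
  for extracted fragments and explains sub-0.2 Å values for short loops; a
  *global* frame (whole-structure superposition applied to the loop) is
  available. Default atom set N, CA, C, O; CA-only and all-heavy variants
  exist, and missing atoms trigger a logged CA fallback.
* **TM-score** is computed on Cα with normalisation length L equal to the
  loop's own length and `d0 = max(0.5, 1.24(L−15)^⅓ − 1.8)`; the 0.5 Å
  floor matters because the raw formula is ≤ 0 for L ≤ 21, i.e. almost the
  whole dataset. The maximisation runs the standard iterative scheme —
  superpositions seeded from all contiguous fragments of lengths L, L/2,
  L/4 (≥4), each refined by re-superposing on the residue subset within a
  distance cutoff until stable — followed by a direct Nelder–Mead
  maximisation of the score over rotation and translation from the best
  candidates. The polish step exists because subset-Kabsch fits are
  RMSD-optimal rather than TM-optimal; with it, the returned value matches
  an exhaustive random-start + refinement search to ~1e-11 on test
  fragments, and is provably never below the naive full-length Kabsch
  score.
* **ΔSSE** is `100·(n_regular^pred − n_regular^exp)/L` over the span, with
  regular = {H, G, I, E, B} and classes taken from the *full-structure*
  assignments restricted to the span (hydrogen-bond partners outside the
  span influence classes, so assigning isolated fragments would be wrong).
* **Mean pLDDT** averages the B-factor over all non-hydrogen atoms of the
  predicted fragment — atom-weighted, not residue-weighted (inferred amide
  hydrogens carry no confidence and are excluded).

## Aggregate statistics

Length stratification reports mean, standard error (sample sd with n−1
denominator over √n; 0 for singletons), min, max and n per distinct
length. Regressions are ordinary least squares with R² = 1 − SSres/SStot
(constant response defined as R² = 0), available per-loop and on
per-length bin means; the split fits (≤20 vs >20 residues) use bin means,
because per-loop scatter caps the achievable R² far below what smooth
binned averages show. Representative loops are chosen per length as the
pair whose RMSD is closest to that length's mean (ties to the smaller
pair id). Ensemble variability takes ≥2 experimental structures and one
prediction, defines spans on the first experimental structure, and
reports all replicate-vs-replicate loop RMSDs against all
prediction-vs-replicate RMSDs. Correlations are Pearson; the
confidence-vs-TM presentation bins TM-score at width 0.05 (configurable)
with per-bin mean/min/max/count. The hydropathy index is the mean
Kyte–Doolittle value of the loop sequence, nonstandard residues excluded.

## Synthetic benchmark generator

The generator emulates the statistics of a real loop benchmark so that
every pipeline stage, and every qualitative trend, is testable offline:

* **Architecture.** Proteins of 120–260 residues alternate idealised
  α-helices (φ = −57°, ψ = −47°, ±2° jitter) with coil loops whose
  torsions are drawn from broad PPII/extended basins chosen to avoid the
  helical and tight-strand regions, so experimental loops stay free of
  regular classes. Backbones are built by natural-extension (NeRF) with
  standard bond lengths/angles and trans peptides; Cα–Cα comes out at
  3.80 Å.
* **Loop lengths** follow a geometric law beyond the 3-residue minimum
  with decay 0.778, putting ≈83% of drawn loops below 10 residues and
  ≈98.6% below 20 — the regime a real loop set occupies. Extracted loops
  run 1–2 residues longer than drawn spans where helix-cap residues
  classify as bend/none; tests that recover generator parameters therefore
  join extracted to simulated loops by span overlap.
* **Loop fraction** per protein targets a draw around 0.40 (sd 0.07,
  clipped to [0.15, 0.8]) by sizing the following helix relative to each
  loop; realised values centre near 0.37 because of helix caps and the
  terminal helix.
* **Prediction errors.** Each loop's atoms receive iid Gaussian noise with
  per-coordinate amplitude σ(L) = min(0.025·L·(1+L/40), 1.5) Å —
  non-decreasing in loop length, giving ≈0.15 Å RMSD for 4-residue loops
  and ≈2 Å beyond 20 residues; helices and injected spans get 0.05 Å.
  With probability min(0.9, 0.012·(L−5)) (zero below 6 residues) a ≥6
  residue sub-span of a loop is rebuilt with helical torsions: long enough
  for the double-turn pattern to register as real helix, so the injection
  is recoverable as ΔSSE > 0. Overall ≈3–5% of loops are affected, rising
  with length.
* **Confidence.** Per-residue pLDDT = clamp(95 − 25·d_local + N(0, 2), 0,
  100), where d_local is the residue's mean atomic deviation from the
  experimental backbone after superposing each architecture segment
  locally. The local frame is deliberate: a rebuilt helix registers its
  full conformational change, while the lever-arm displacement it causes
  downstream does not leak into unrelated residues. This yields a strong
  anticorrelation between per-loop confidence and RMSD (r ≈ −0.96 on the
  default set) and a positive confidence–TM relation.
* **Determinism.** All randomness flows from one integer seed through
  `numpy.random.SeedSequence.spawn`; the same spec reproduces byte-identical
  PDB files and truth tables.

What the generator does **not** emulate: side chains (backbone-only
residues), missing residues and crystallographic disorder, β-sheet loops
interacting with distant strands, sequence-dependent conformational
preferences (random sequences are available but do not bend the backbone),
and correlated, physically relaxed error modes — predicted copies are
noised and re-torsioned, not energy-minimised. Passing tests therefore
demonstrate the correctness of the measurement machinery and the
recoverability of known trends, not predictor accuracy on real proteins.

## Numerical choices and degenerate inputs

Kabsch requires ≥3 finite points and equal shapes; collinear sets return a
flagged minimiser. TM-score requires L ≥ 3. Hydrogen-bond energies clamp
at −9.9 kcal/mol when any of the four distances drops below 0.5 Å.
Zero-variance inputs make Pearson correlation NaN with a warning; constant
responses give R² = 0; all-identical predictors are an error. Chains
shorter than 3 residues assign to all-C. The two-strand sheet fixture is
placed by a deterministic grid search (orientation flip × 3D offsets,
clash-filtered) maximising inter-strand hydrogen bonds.

## Problem sizes

The default acceptance run simulates 60 proteins (~650 loops, ~4,400 loop
residues); the test suite uses the same size for its statistical fixtures
and 200 proteins for the Monte-Carlo check of the loop-length law. These
sizes give stable length-stratified means over the populated bins (3–20
residues) while keeping a full run in the low minutes on one core.

## Known limitations

Exact per-class agreement with any particular DSSP build is not promised
on arbitrary real structures (π-helix precedence and bend boundaries vary
across versions); the collapsed loop mask is the contract. TM-score values
can exceed those of reference binaries by a hair because of the final
continuous polish. The PDB writer emits minimal ATOM/TER/END records —
no SEQRES, occupancy alternates, or anisotropic records. Pairing requires
consistent author numbering between experimental and predicted files, as
is the case for models predicted from the same sequence.
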