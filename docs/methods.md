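# Methods

This note records the models, parameter choices and numerical decisions
behind rinmap, and what the synthetic fixtures do and do not establish.

## Residue interaction networks

Nodes are polymer residues identified by `chain:seq_num:ins_code:aa3` (blank
insertion codes rendered `_`, author numbering preserved).  Two edge types
are detected by explicit geometric criteria:

* **contact** — at least one heavy-atom pair within `contact_cutoff`
  (default 5.0 Å, a standard distance-RIN threshold);
* **hbond** — at least one N/O–N/O pair within `hbond_cutoff` (default
  3.5 Å).  No donor–hydrogen–acceptor angle is applied because hydrogens are
  generally absent from X-ray structures; this over-calls hydrogen bonds
  slightly relative to angle-aware methods.

Residues within `exclude_neighbors` (default 1) sequence positions on the
same chain are skipped — peptide-bond neighbours are trivially in contact
and carry no information.  The backbone atom set is {N, CA, C, O, OXT};
everything else is sidechain; an edge's subtype is `mc_mc` / `sc_sc` when
all qualifying pairs are backbone–backbone / sidechain–sidechain, otherwise
`mc_sc`.  `natom_pairs` counts the qualifying pairs and doubles as an edge
weight.  Candidate pairs come from a k-d tree; by construction the result
is identical to the exhaustive scan, and the test suite asserts this
equality on every fixture.

Dot-surface (probe-based) contact scoring, π-stacking/salt-bridge/disulfide
typing and water-mediated interactions are out of scope; externally
produced RIN files in the same SIF dialect are read as-is, so richer
generators can feed the downstream machinery.

Alternate locations are resolved at parse time: the conformer with the
highest occupancy wins, ties break to the lexicographically smallest altloc
identifier — deterministic and standard.  HETATM records and waters are
excluded by default (RIN nodes are polymer residues); a flag re-admits
modified residues.  The representative point of a residue is its CA atom,
falling back to the heavy-atom centroid — conventional, and robust to
missing sidechains.  Model selection defaults to the first model.

## Secondary structure

Segments come from HELIX/SHEET header records when present; uncovered
residues form maximal loop runs, so segments always partition each chain.
Without header records a dihedral fallback applies window rules on
(φ, ψ): helix for runs ≥ 4 residues with φ ∈ (−100°, −30°), ψ ∈ (−80°, −5°);
strand for runs ≥ 3 with φ ∈ (−180°, −40°), ψ ∈ (90°, 180°) ∪ (−180°, −170°);
otherwise loop.  These are deliberately simple published windows; DSSP-class
assignment (hydrogen-bond patterns, kinks, bridges) is a non-goal, and the
windows misclassify distorted termini — acceptable for colouring, distance
weighting and aggregation, the only uses here.

## Anchored stress layout

The energy is `E(X) = (1−λ)·S/S₀ + λ·A/A₀` with weighted stress
`S = Σ w_uv (‖x_u−x_v‖ − d_uv)²` over the chosen pair set and anchor term
`A = Σ ‖x_u − a_u‖²`.  Choices that were genuinely open:

* **Weights** `w_uv = d_uv^(−2)`: the standard local-emphasis exponent —
  short distances must be drawn accurately, long ones may flex.
* **Secondary-structure weighting**: pairs within the same segment get
  `w ×= ss_weight_factor` (default 4), keeping helices/strands rigid in the
  drawing.  Factor 1 reduces exactly to the unweighted variant.
* **Normalisers** `S₀ = Σ w d²` and `A₀ = n·(mean pairwise anchor distance)²`
  make the two terms dimensionless so a λ of 0.5 really balances them;
  degenerate inputs (single node, coincident anchors) fall back to 1.
* **Schedule**: λ ramps linearly from `anchor_start` (0.1) to `anchor_end`
  (0.9) over the sweeps — the simplest monotone schedule that starts
  structure-driven and ends orientation-preserving.  Both endpoints are
  configurable; pinning them equal gives a fixed-λ optimisation.
* **Minimiser**: SMACOF-style majorization.  The stress term is replaced by
  its Cauchy–Schwarz quadratic upper bound at the current configuration
  (Guttman transform); the anchor term is already quadratic and enters the
  linear system exactly, so each sweep solves
  `((1−λ)/S₀·L_w + λ/A₀·I) X⁺ = (1−λ)/S₀·B(X)X + λ/A₀·A` and the energy is
  provably non-increasing at fixed λ.  At λ = 0 the weighted Laplacian is
  singular (translation invariance); the least-squares solution is
  re-centred on the previous iterate's mean, which preserves translation
  covariance of the whole procedure.
* **Determinism**: the initial configuration is the projection of the 3D
  coordinates under the view transform (rotation ∘ scale, then drop z); no
  randomness exists anywhere in the layout.
* **Degenerate distances**: coincident representative atoms would give
  `d = 0` and an infinite weight; `d` is clamped to 1e−6 with a warning.
* **Pair scope**: all-pairs stress is O(n²) per sweep and comfortable for
  single-domain proteins (hundreds of residues); `graph_k` (default k = 3)
  restricts pairs to graph distance ≤ k for larger systems.
* Stopping: relative energy decrease below `tol` (1e−6) once λ has reached
  its final value, or `iterations` (200) sweeps.
* Coordinate convention: y grows upward; writers targeting screen-space
  formats must negate y themselves.

An optional per-pair weight-multiplier hook exists in the config surface
(through `ss_weight_factor` and the weight exponent); arbitrary external
edge-weight files are not given default semantics.

## Sequence comparison and mutation scoring

Global alignment is Needleman–Wunsch with affine gaps (open −10, extend −1,
the usual BLOSUM62 pairing) computed by Biopython's `PairwiseAligner`; of
the co-optimal tracebacks the aligner's first is returned, which is
deterministic.  The test suite independently verifies optimality with a
quadratic-space Gotoh DP.  The BLOSUM62 table itself comes from
`Bio.Align.substitution_matrices` — never retyped.

Column classification: equal non-gap letters are matches; unequal non-gap
letters are substitutions (scored with BLOSUM62); a gap in the parent row is
an insertion in the mutant; a gap in the mutant row a deletion from the
parent.  A column gapped in both rows is an invalid alignment and an error.

The comparison network collapses interaction types: edge identity is the
unordered residue pair, because the conserved/lost/gained statuses describe
the presence of *an* interaction, not its type.  Orientation is fixed:
network A is the parent, B the mutant, so *lost* means present only in A.
The unchanged fraction divides conserved incident edges by **all** incident
comparison edges (conserved + lost + gained); an isolated node scores 1.0 —
no change was observed because there was nothing to change.  Multi-chain
inputs are handled by aligning chains separately and binding the column
maps per chain; cross-chain edges then compare like any other pair.

## Aggregation, annotation, filters

Aggregation groups nodes by any attribute (default `ss_segment`); the
inter-group edge weight counts RIN edges spanning the groups, intra-group
edges are dropped by default but tallied, so
`Σ inter-group weights + intra-group count = |edges|` always holds.  Group
ids follow first occurrence in (chain, position) order, making output stable
under node reordering.

Annotation tables are TSVs keyed by node_id; column types come from a
sidecar JSON or are inferred (ints → numeric, true/false → boolean, else
categorical).  Unknown node_ids warn rather than fail — external resources
frequently use shifted numbering.  Conservation grades follow the 9-grade
convention (1 variable … 9 conserved) with ≥ 7 as the usual "high
conservation" threshold in the examples.

Filters are parsed with Python's `ast` module into a whitelisted grammar
(comparisons, and/or/not, parentheses, constants, attribute names).  A node
missing a referenced attribute fails the predicate silently; a name unknown
to the entire network is an error with the offending position.  Anything
outside the grammar (calls, subscripts, attribute access) is rejected, so
expressions cannot execute code.

## Synthetic fixtures: what they emulate and what they do not

Helix and strand fixtures are grown by internal-coordinate chaining (NeRF)
at ideal torsions — helix (φ, ψ) = (−57°, −47°), strand (−120°, +120°),
ω = 180° — with textbook bond lengths and angles.  This yields genuine
α-helical geometry (CA radius ≈ 2.25 Å, rise ≈ 1.55 Å, ≈ 100°/residue,
CA–CA 3.80 Å) so the dihedral SS windows, the contact ladder and the
hydrogen-bond ladder are all exercised on real numbers.  Fixtures are
backbone-only by default (a flag adds CB so sidechain subtypes get
exercised); they have no physical sidechain packing.

The dimer fixture places rigid residue clusters so that exactly the
requested cross-chain pairs come within 3.7 Å while every other cross-chain
pair stays beyond 6 Å; a built-in brute-force check refuses unrealizable
requests (two partners for one residue, clashes < 2.5 Å).  The random coil
is a seeded self-avoiding CA walk with 3.8 Å steps.  Mutant pairs are
generated at the sequence level with a ground-truth alignment; the
companion `mutant_structure` helper applies substitutions/deletions to the
geometry (insertions have no coordinates and are skipped).

Passing tests on these fixtures establish algorithmic correctness —
builder = exhaustive scan, layout = generic minimiser, planted mutations
recovered exactly — but not biological fidelity on real structures:
fixtures have no sidechain rotamers, no crystallographic noise, no
alternate conformations beyond the parser tests, and mutant geometries are
not re-modelled.  Applying the pipeline to a real parent structure and a
modelled mutant requires externally produced coordinates for the mutant.

## Problem sizes and reproducibility

Tests and the acceptance script use helices of 12–30 residues, dimers of
5 + 5, coils of 8–30 residues and random networks of up to 50 nodes, with
20-seed sweeps for the stochastic properties — sizes at which the exhaustive
oracles are exact and instantaneous while every code path is covered.  All
generators are deterministic given their seed; PDB/SIF/TSV/GraphML writers
emit no timestamps, so identical inputs reproduce byte-identical outputs.
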