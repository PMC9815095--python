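# Methods

## The score

For a model residue *i* of amino-acid type *a*, the package evaluates

    DAQ(AA)_i = ln( p_i(a) / mean_j p_j(a) )

with `p_i(a)` the probability of type *a* interpolated from the 20-channel
probability volume at the residue's Cα. The denominator averages the same
channel over all scoring positions *j* of the model. Two normalisation
sets are available: the default averages over the Cα of every scored
residue (`positions="ca"`); `positions="all"` averages over every atom
position in the model. The per-residue probability produced by a
sliding-box classifier describes the residue as a whole, so a single
representative position per residue is the default; the all-atom mode
exists for fidelity experiments and the two coincide on Cα-only models.

The logarithm is natural. Any base rescales all scores by a constant and
preserves signs and rankings, but the −0.5 flagging threshold is
base-dependent, so the base is fixed and documented here.

Numerical choices:

* **Interpolation** — trilinear by default; nearest-voxel optional. On a
  1 Å grid either is defensible, but trilinear avoids voxel-boundary
  artifacts in the scores of adjacent residues.
* **Probability floor** — lookups outside the grid, and interpolated
  values below 1e-6, return 1e-6. This keeps the logarithm finite and
  makes residues that sit off the density strongly negative, which is the
  score's intent. Degenerate lookups are tallied in diagnostics, never
  fatal; however, if more than half of the Cα lookups fall off-grid the
  model and volume almost certainly disagree on the coordinate frame, and
  scoring aborts with a geometry error instead of silently returning
  floored values.
* **Windowing** — windowed scores average raw scores over a centred
  19-residue window. The window shrinks at chain termini (no padding is
  invented beyond the chain) and never crosses a gap in author numbering,
  so chain breaks truncate it. Window 1 is the identity.
* **Flagging** — applied to the *windowed* score. The windowed track is
  what localises register shifts, and a threshold on it is stable against
  single-residue noise in the raw track.
* **Totals** — the per-model total used for ranking is the sum of windowed
  scores; a raw-sum variant and a mean-per-residue mode (for models of
  unequal length) are exposed. Tied totals are broken by input order and
  the tie groups are recorded.

## Input preparation

Template trimming removes residues with windowed DAQ(AA) ≤ 0 (a strict
`< 0` rule is selectable). Trimming changes membership only — coordinates,
numbering and atom records of kept residues are untouched. An empty result
is returned with an explicit `empty_template` status, never silently.

MSA masking gaps the match columns of all *non-query* rows at query
positions with windowed score ≥ 0. Masking means writing the gap
character, not deleting columns, so row lengths and the A3M insertion
bookkeeping stay valid; lowercase insertion states adjacent to masked
columns are preserved, and the query row is never altered — the predictor
must always see the full target sequence. Masking is idempotent.

The two rules are deliberate complements: the predictor keeps structural
information (template) exactly where it loses evolutionary information
(MSA), and vice versa. Positions scoring exactly 0 are removed from the
template *and* masked, i.e. invisible to both channels; this boundary case
follows both rules literally and is exercised in the tests.

Candidate models are superposed on the trimmed template by the Kabsch
solution over Cα pairs shared by residue key; the transform is applied to
all atoms, so internal geometry is preserved exactly. Correspondence is by
key (chain, author number, insertion code) — candidates are models of the
same chain; homologous chains require an explicit residue map, the package
never aligns sequences silently.

## Quality metrics

* **Kabsch** — least-squares optimal proper rotation + translation via
  `scipy.spatial.transform.Rotation.align_vectors`; the r.m.s.d. is
  re-evaluated from the fitted transform because the solver's residual
  norm loses precision near zero. Collinear or coincident point sets are
  rejected as degenerate.
* **Cα r.m.s.d.** — Kabsch-minimised by default; a frame-fixed mode is
  available for comparing models already placed in the map frame.
* **GDT-HA** — mean over thresholds 0.5/1/2/4 Å of the maximal fraction of
  Cα pairs within the threshold over searched superpositions. The search
  is a deterministic seed-and-extend heuristic: seeds from every
  contiguous window of lengths 3, 5 and 7 plus the global fit, each
  refined by refitting on its inlier set per threshold until stable (≤20
  rounds); every candidate transform (raw and refined) is then evaluated
  at every threshold. This guarantees the per-threshold fractions are
  monotone in the threshold and never below the global-fit fraction.
  Chains of ≤24 residues use an exhaustive seed pool (every window
  length), so at that scale the search provably equals full seed
  enumeration; exact LGA replication is a non-goal. All metrics are
  computed over the pairable residue set, and coverage (pairs / reference
  length) is always reported, because short models can combine a low
  r.m.s.d. with a low GDT-HA through low coverage.
* **Misaligned segments** — after global superposition, a residue is
  inconsistent when its Cα is >2 Å from its corresponding reference Cα
  *and* its nearest reference Cα belongs to a different residue. The
  nearest-neighbour test uses a 5 Å capture radius (configurable): a
  residue displaced into empty space is a conformational error, not a
  register error. Maximal runs of ≥4 contiguous inconsistent residues are
  reported.

## The synthetic generator

The generator emulates the classifier's output directly rather than
simulating density and a network: direct imprinting gives controllable
ground truth for the scoring arithmetic, which is the thing under test.

Backbones are ideal Cα traces (helix: 1.5 Å rise, 100° twist, 2.3 Å
radius; extended: 3.8 Å spacing). Each residue imprints a probability
distribution around its Cα with Gaussian weight exp(−d²/2σ²):
its own type gets `peak_prob` (default 0.6), each of the two
sequence-neighbour types `neighbor_prob` (default 0.19), and the small
remainder is spread over the other types. The neighbour mass reflects the
dominant confusion mode of a sliding-box classifier, whose 11 Å receptive
field overlaps adjacent residues; it also keeps the probability of an
*unrelated* type at an occupied position near 1e-3, which is what makes an
assignment error sharply visible in the log-ratio. Imprints are blended
with a weak uniform background (`background_weight` 0.01) and normalised
exactly per voxel; far from the model the field is uniform. With
`peak_prob = 1/20` the imprint degenerates to uniform and all scores are
identically zero, making selection ties explicit.

`blur_sigma` defaults to 1.3 Å. This value matters: on a helix, residues
three apart are ≈5 Å contacts, and a wider imprint leaks each residue's
type into its i±3 neighbours' positions — precisely the channel a +3
register shift reads — washing out the contrast between planted errors and
intact residues. A much narrower imprint would instead let the background
dominate the trilinear lookups between voxel centres. 1.3 Å separates a
+3 shift cleanly at the −0.5 threshold under the default peak/neighbour
masses.

Error injectors:

* `inject_register_shift` — types within a region are reassigned from
  positions offset by *k*; coordinates bit-identical. A pure
  sequence-assignment error, used to probe the score.
* `inject_trace_shift` — the geometric face of the same error: residues
  take the *coordinates* of positions offset by *k* while keeping their
  identities, which is what two depositions differing by a local register
  shift look like. Used to probe the misalignment detector.
* `inject_conformational_error` — a rigid displacement (plus optional
  seeded jitter) with types unchanged. The default direction is the helix
  axis: an axial displacement leaves no compromise superposition that can
  partially recapture the displaced residues, so the planted inlier count
  is exactly what any correct superposition search must report (a radial
  displacement of a 10 Å tail admits a transform catching 9/10 pairs at
  4 Å, making the planted count ill-posed).

The core experiment (`core_fixture`) is a 100-residue helix carrying a
+3 register shift on residues 46–55, scored against its own noiseless
volume. Its sequence cycles deterministically through the 20 amino acids,
guaranteeing that every shifted position actually changes identity — with
a random sequence ~1/20 of shifted positions silently keep their type,
confounding the recovery measurement and making it seed-dependent. Under
these conditions every shifted residue scores below −0.5 (windowed), ≈96%
of unshifted residues stay positive (the shortfall is the windowed
shoulder on either side of the planted region), the trimmed template
excludes the entire region, and the clean model outranks the shifted one.

What passing these tests does *not* show: the generator has no
resolution-dependent noise, no partial occupancy, no conformational
heterogeneity, and its confusion structure (neighbour types) is idealised.
Results on synthetic fixtures validate the arithmetic and the protocol
logic, not the performance of the upstream classifier on real maps.

## Problem sizes and determinism

Fixtures are desk-scale by design: 100-residue chains, ≈20×20×160 voxel
volumes, ensembles of ≤4 candidates. Every generator is a pure function of
its seed, and the I/O layer writes bit-stable output (shortest-round-trip
float formatting in TSV, fixed key order in JSON, float32 MRC), so
identical seeds and configurations reproduce byte-identical files — which
the acceptance script verifies on every run.

## Known limitations

* Exact-zero windowed scores are invisible to both the template and the
  MSA (see above); in practice scores are never exactly zero except on
  degenerate volumes.
* The GDT-HA search is heuristic for chains longer than 24 residues;
  fractions are lower bounds on the combinatorial optimum (never below
  the global-fit fraction).
* The probability-volume manifest (20 MRC channels + JSON) is this
  package's own convention; no standard on-disk format exists for
  per-type probability grids. A per-residue TSV table is accepted as a
  lighter carrier.
* Nucleic acids and map sharpening are out of scope; only the 20
  canonical amino acids (plus a configurable modified-residue mapping on
  parse) are supported.
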