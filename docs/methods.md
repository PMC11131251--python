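# Methods

## The 3D lineage-tree construction

A dataset addresses time by *saved file index*: snapshots exist at multiples
of a save stride, and the genealogy records raw iteration numbers in the
same units. Trees are drawn over the sampled indices
`tmin, tmin+fileStep, …` with `tmax` always included (appended when the
stepping misses it, so the final state is drawn regardless of
divisibility); `fileStep` must be a multiple of the save stride, since
intermediate indices do not exist on disk.

**Branches.** For each consecutive sampled pair (k, k′) and each clone
member listed in the snapshot at k′, one straight segment runs from the
cell's position at k to its position at k′. If the cell was not yet
recorded at k, its nearest ancestor's position there is used instead; this
anchors a daughter's first branch at its mother, and for a mutated clone's
root it anchors the entry segment at the parent-clone mother — that
boundary segment is owned by the daughter clone, so single-clone plots are
self-contained. Cells born and dead strictly inside one sampling window
leave no branch; coarser sampling therefore straightens branches by
construction, and the branch multiset of the all-clone forest is exactly
the concatenation of the per-clone trees.

**Snapshot timing.** A snapshot at index k records the state *entering*
iteration k: a cell dividing or dying at k is still listed at k (its
`end_iter` equals k), and its daughters first appear at the next saved
index. This convention makes the minimal worked example exact — a founder
dividing at the middle of three snapshots contributes one mother branch and
two daughter branches, three in total — and keeps every listed cell inside
`birth_iter ≤ k ≤ end_iter-or-alive`.

**Time scaling.** The vertical axis is the linear map
`y(k) = (k − tmin)/(tmax − tmin) · (xmax − xmin)`, i.e. a per-`fileStep`
spacing of `timeStep = (xmax − xmin)·fileStep/(tmax − tmin)`. This
guarantees `y(tmin) = 0` and `y(tmax) = xmax − xmin` exactly — the time
axis spans the tissue's x-extent, giving the three axes comparable scale —
including when `tmax` was appended off-grid, where any formula quantized to
whole `fileStep` multiples could not satisfy both anchors.

**Survivor pruning.** The pruned ("alive") tree keeps cells with at least
one descendant (or themselves) alive at `tmax`, computed by walking mother
links upward from the final snapshot — O(cells) rather than enumerating
descendant sets. For single-clone scope the walk is seeded only by the
clone's *own* surviving cells and the result restricted to its members:
survival does not flow back across a mutation boundary, so a clone whose
cells all died renders empty even if clones it spawned persist. Because a
descendant path between two same-clone cells can never leave the clone
(clone identity changes only at a mutation birth and never reverts), this
is equivalent to "has an alive same-clone descendant", which is what the
brute-force oracle in the tests checks. Clone roots are the earliest-born
member whose mother is absent (founder sentinel `mother_id = 0`) or belongs
to another clone; ties break to the smallest cell id.

## Microenvironment backdrop

The factor field is split into four equal-width bands on [min, max]:
`band(v) = ⌊4(v − min)/(max − min)⌋` clipped to 3, so boundary values fall
upward and the maximum lands in the top band; a constant field degenerates
to the single lowest band. Equal-width (not quartile) binning keeps the
split deterministic on spiky fields. Colors are fixed highest→lowest as
red–yellow–cyan–blue. The plane is placed at the `tmin` face (scene time 0)
so the tree grows away from its environment map; either face is defensible
and the choice is isolated in `BackgroundPlane.y_time`.

## Rendering

Branches are grouped into one `Line3DCollection` per clone — fast for
forests with thousands of segments, and introspectable (`segment_count`
recovers the exact number of segments in a figure). The clone palette is a
pure function of the clone id: clone 0 is fixed to pink, other clones take
golden-ratio-spaced hues with alternating saturation/value, which stay
pairwise distinct for hundreds of clones and are identical across runs and
figures. Rendering works under the Agg backend; `export_jpeg` saves the
figure (Pillow provides the JPEG encoder), and interactive rotation is
available whenever a GUI backend is active. An empty branch set renders
empty axes — a dead clone is a result, not an error.

## The tumor simulator

The synthetic-data engine is an off-lattice agent-based model on a tissue
rectangle (default [−100, 100]², matching the tree examples) with
`n_vessels` point vessels at fixed non-uniform random positions. Per
iteration, in order: snapshot (at save indices), drug transport and dose
accumulation, drug/random deaths, random motility, divisions, overlap
relaxation, out-of-domain removal.

* **Drug.** Explicit 5-point finite-difference diffusion on a regular grid
  with no-flux walls, uniform first-order decay, per-cell fractional uptake
  at the cell's node, and vessel nodes clamped to a constant concentration
  after `drug_start`. The stability bound D·Δt/h² ≤ 0.25 is enforced at
  parameter construction, and a non-finite field aborts with an error
  naming the bound. With no sources or sinks the update conserves total
  mass to rounding error (the discrete Laplacian with edge padding sums to
  zero), which the tests verify at 1e−9 relative.
* **Dose and death.** Cells accumulate the concentration at their node each
  iteration; a *sensitive* cell dies when the accumulated dose exceeds
  `death_threshold`. Mutated clones are absolutely resistant and never die
  of drug. All cells are also subject to a small per-iteration random death
  probability, and cells wandering outside the domain are removed — both
  recorded exactly like deaths (an `end_iter` with no daughters), since the
  text format cannot distinguish the three.
* **Division and crowding.** A cell divides once its age exceeds a jittered
  maturity (uniform 0.7–1.3 × `division_age`) *and* it has no neighbor
  closer than `crowding_radius`. Division replaces the mother by two new
  records (daughters' `birth_iter` equals the mother's `end_iter`; neither
  daughter inherits the mother's id) placed symmetrically beside her. Each
  daughter independently mutates with probability `p_mut`, taking the next
  unused clone id. Overlaps are then relaxed by symmetric pairwise
  repulsion (k-d-tree neighbor queries) for a fixed small number of passes;
  dense interiors therefore stay compressed and effectively quiescent, so
  colonies expand from the rim — the emergent growth control. When the drug
  clears space, the survivors' neighborhoods open up and proliferation
  resumes.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| `domain` | (−100, 100)² | tissue units | rectangle, matches the tree examples |
| `n_vessels` | 5 | — | point drug sources, non-uniform layout |
| `p_mut` | 0.005 | per daughter | mutation probability; 0.005 and 0.05 are the two standard regimes |
| `n_iters` | 5000 | iterations | run length |
| `drug_start` | 2500 | iteration | injection start; ≥ `n_iters` disables the drug |
| `save_stride` | 50 | iterations | snapshot frequency (must divide `n_iters`) |
| `grid_h` | 4 | tissue units | drug-grid spacing (51×51 nodes) |
| `diffusion_coeff` | 2 | units²/iter | CFL number 0.125, comfortably stable |
| `decay_rate` | 5e−4 | /iter | decay length √(D/λ) ≈ 63 units: drug reaches the whole patch |
| `uptake_rate` | 2e−3 | /cell/iter | mild sink; strong uptake creates shielded sanctuaries |
| `vessel_conc` | 1 | conc. | clamped source value (sets the concentration scale) |
| `death_threshold` | 3 | conc.·iter | lethal accumulated dose for sensitive cells |
| `division_age` | 150 | iterations | mean division interval |
| `crowding_radius` | 6 | tissue units | contact-inhibition distance (caps the patch at ~1200 cells) |
| `random_death_prob` | 2e−4 | /cell/iter | baseline attrition, produces dead branches pre-drug |
| `motility_step` | 0.05 | units/iter | random-walk displacement scale |

The default configuration was chosen to reproduce, at desk scale, the
qualitative regimes the tree routines exist to visualize: the colony grows
from one founder to roughly a thousand cells; the drug then drives the
sensitive initial clone extinct across seeds while resistant clones
repopulate the tissue; and the two standard mutation probabilities separate
cleanly (mean clone counts ~85 vs ~900 over seeds, an order-of-magnitude
split with non-overlapping ranges). A run takes ~10–15 s on one CPU. The
`small_colony_params` preset shrinks everything (80×80 patch, 120
iterations, ≤ ~150 cells, ~20 ms) for generating large numbers of random
genealogies in property tests.

### What the generator does and does not emulate

It emulates the features the tree routines consume: binary genealogy with
exact birth/end bookkeeping, spatially coherent clone growth, mutation-born
resistant clones, drug-gradient-driven extinction, random death and domain
exit, and snapshots in the exact text format. It does **not** attempt
pharmacokinetic realism (the kinetic constants are phenomenological), cell
mechanics beyond pairwise repulsion, phenotypes beyond the binary
sensitive/resistant switch, or time-varying vasculature. Passing tests
therefore demonstrate the correctness of the bookkeeping, pruning, and
rendering pipeline on data with realistic *structure* — not that any
particular biological rate is right.

## Numerical and edge-case choices

* Coordinates are written with 6 significant digits; integer fields
  round-trip bit-for-bit. Blank lines are ignored on read.
* An empty snapshot file pair is a *valid* empty snapshot (all cells dead).
* Division vs death is disambiguated by daughter count: an ended record
  with two daughters is a division, with none a death/exit; one daughter is
  a validation error (the genealogy is strictly binary).
* Out-of-bounds coordinates in an otherwise consistent dataset are an
  advisory warning, not a hard failure — cells that left the domain are
  legitimately absent, and a present cell slightly outside the stated
  rectangle usually means the rectangle, not the data, is wrong.
* Crowding relaxation uses strict inequality for the division block and a
  half-overlap symmetric push; two coincident cells separate along a random
  direction to the full contact distance in one pass, while a deeply
  overlapping ring needs on the order of a hundred passes to fully open
  (the simulator deliberately uses 4 — compression is the growth control).
* The fine-grid steady-state oracle for the drug profile is an independent
  sparse direct solve of the diffusion–decay balance; profiles are compared
  in *shape* (normalized one node away from the source), because clamping a
  single node imposes a resolution-dependent effective source radius.

## Problem sizes used by the tests and the acceptance script

Property tests and the pruning-oracle sweep use 200 miniature simulations
(≤ ~150 cells each); the regime check runs the full default configuration
for 5 seeds at each mutation probability; the drug-physics checks use a
21×21 grid with a few hundred to a few thousand explicit steps. These sizes
were chosen so the whole suite completes in a few minutes on one CPU while
every check still exercises the full code path.

## Known limitations

* Cell positions are never interpolated between saved snapshots; lineage
  is taken from the history file, never inferred from coordinates.
* The history format cannot distinguish death from domain exit; both prune
  identically.
* The clone palette cycles in hue for extremely large clone counts
  (thousands); colors remain deterministic but perceptual distinctness
  degrades.
* The backdrop shows a single (final-time) field; time-varying gradient
  playback is out of scope.
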