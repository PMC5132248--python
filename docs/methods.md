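# Methods

This note documents the models, conventions and numerical choices behind
`porestate`, and what the synthetic tests do and do not establish about
real MD data.

## Pore axis and projection

The pore axis of a frame is defined by two atom sets: the origin is the
unweighted centroid of the *from* set, the direction the unit vector
toward the centroid of the *to* set.  With the *from* set at the
intracellular end of the selectivity filter and the *to* set at the
extracellular end, the extracellular side has positive *z*.  For an ion at
position **p**, z = (**p** − **o**)·**d** and r = |(**p** − **o**) −
z **d**|; by construction |**p** − **o**|² = z² + r², and both coordinates
are invariant under any rigid-body motion applied to the whole frame.

The axis is recomputed every frame rather than taken from an averaged
structure, so slow drift or rotation of the protein does not contaminate
the ion coordinates.  Centroids are not mass-weighted (the basis sets are
normally chemically identical atoms, where weighting is a no-op).  If the
two centroids fall within 1e-6 Å of each other the axis is undefined and
an error is raised.  Periodic-boundary unwrapping is *not* performed: the
pore region is assumed whole within each frame, which holds for standard
membrane-protein post-processing where the protein is re-centered.

## Sites and binding states

A site model is a strictly descending axial boundary list b₀ > … > bₙ
defining n sites; site i spans bᵢ ≥ z > bᵢ₊₁.  Intervals are
upper-inclusive so that every z maps to exactly one site or to none — the
choice of where a tie lands is arbitrary but must be deterministic and
partition-preserving.  An optional radial cutoff (`site-max-radius`)
excludes ions far from the axis; it defaults to unbounded because in an
intact channel the pore walls impose the radial bound sterically.

The boundary-suggestion helper histogramms the axial ion density (default
bin width 0.25 Å) and reports the density minimum between each pair of
adjacent peaks, in descending order.  It is advisory: peak separation can
be genuinely ambiguous, and the final boundary list is the user's call,
informed by structure (e.g. the octahedral oxygen cages of a K⁺ filter).

The binding state of a frame is the *set* of occupied sites plus the
species label, `K:0:2:4`.  Set semantics lose multiplicity; a
multiply-occupied site is legal but triggers a warning, since for
single-file channels it usually signals boundaries that are too wide.

## State graph

Adjacent duplicate states collapse into runs.  Node probability is the
fraction of frames spent in a state; edge probability is the transition
count divided by the total number of distinct-state transitions (a global
normalization — a per-source conditional normalization would also be
defensible; the global one makes edge widths comparable across the whole
graph).  Self-edges are excluded: dwell time lives in node counts.  A
transition whose occupancy sets differ by more than one ion move is kept
as an ordinary edge but flagged `multi_jump` and logged, because it means
the snapshot interval skipped at least one intermediate state.  The GML
writer emits nodes sorted by descending probability (then label) and
edges sorted by endpoints, so output is byte-stable for a given graph.

The most stable state is the node-probability argmax, with lexicographic
tie-breaking (logged).

## Cycles, conduction events and permeation

The collapsed state path is split at every visit of the most stable state
(the *anchor*).  Interior segments give anchored cycles; the segment
before the first anchor visit is retained as a flagged *leading partial*
path (it contains the trajectory's first frames and can still hold a
conduction event) and the segment after the last visit as a *trailing
partial*.  Trailing partials are excluded from event classification by
default, since an unfinished cycle's pattern is censored.  Concatenating
leading partial, cycles and trailing partial (merging shared anchors)
reproduces the collapsed path exactly; a path that visits the anchor only
once decomposes into nothing.

A path is a conduction event iff its ion-count sequence contains at least
one increase and at least one decrease.  For anchored cycles any count
change implies both (the cycle returns to the anchor's count); the
two-sided test also covers partial paths.  A cycle containing two
complete conduction events is kept as one path, not sub-split.

Permeation is counted per ion, independently of states.  Each ion's
per-frame site assignment collapses into an itinerary of tokens: site
indices, `intra`/`extra` for reservoir dwell beyond the terminal
boundaries, or `off` for radially excluded in-span positions.  An outward
permeation is a witnessed crossing — reservoir entry on the intracellular
side, at least one site visit, exit to the extracellular reservoir; inward
is symmetric.  Ions already inside the pore at the first frame have no
witnessed entry side, so their first exit counts nothing.  Optional
grazing smoothing removes reservoir excursions shorter than
`min_offsite_frames` *between two site visits* (default 1 = off), so a
single-frame noise dip across a terminal boundary neither splits nor
double-counts a crossing; terminal reservoir visits are never smoothed
away.

## Character encoding, alignment, clustering

Characters are assigned per state, classed by ion count relative to the
anchor: the anchor is `*`; its count class gets `A B C…`; one more ion
`a b c…`; two more `# % & …`; all other counts draw from a digit and
punctuation pool.  Within a class, characters follow descending node
probability (ties lexicographic), so the map is deterministic for a given
graph.  When a class is spent it spills into the shared pool, then into
any unused printable ASCII; a graph with more states than printable
characters raises an error suggesting a coarser site model.  Encoding can
be restricted to the states actually appearing in events.  Anchored
cycles are stored explicitly as `*…*`; the compact rendering drops the
leading `*`.

Alignment is global dynamic programming with linear gap scoring,
S[i][j] = max(S[i−1][j−1] + s(aᵢ,bⱼ), S[i−1][j] + g, S[i][j−1] + g), with
gap-filled borders and traceback ties broken diagonal > up > left.  The
substitution score s is the three-point rule (1.0 / 0.5 / 0.0).  The gap
score defaults to 0: no gap treatment is canonical for this problem, and
with non-negative substitution scores a zero gap turns the optimum into a
maximum-weight monotone matching, which is scale-free.  It is exposed as
an option.  Event similarity is the raw score divided by the longer
sequence's length (optional), keeping entries in [0, 1] with an exact
unit diagonal and penalizing length mismatch; clustering runs on
distance = 1 − similarity with scipy's agglomerative linkage, UPGMA
(average) by default and single/complete/ward selectable.  The two-cluster
"midpoint cut" is taken at the midpoint between the two highest merge
heights — the point inside the gap that separates the final merge from
everything below it (half the final height would cut inside within-cluster
structure whenever clusters are internally heterogeneous).

## Synthetic generator

`synthetic_data.HoppingModel` is a combinatorial surrogate for single-file
permeation, not physics: no electrostatics, water, or force field.  Ions
occupy discrete sites on a straight axis, hop to adjacent sites, enter
from the intracellular reservoir and exit extracellularly (reverse rates
optional), with hard-core exclusion and an optional minimum site
separation.  The stock 7-site models use `min_separation = 2` (no
adjacent occupancy), the water-separated-ion configuration of K⁺
filters; this confines the reachable occupancy space to ~34 states and
produces short knock-on-like cycles rather than diffusive wandering.

Dynamics are a discrete-time Markov chain at the frame interval: per
frame at most one move fires, chosen categorically with probability
rate × dt.  This choice (rather than independent simultaneous firing with
conflict resolution) makes the embedded occupancy chain's one-frame
transition matrix exactly computable by enumerating the reachable
occupancies, which the stationary-distribution oracles in the tests use;
a total move probability above 0.5 per frame raises a time-step error.
Reservoir bookkeeping assumes entry is always possible; the simulation
records whether the intracellular reservoir ever ran dry so tests can
verify the assumption.

Coordinates: two static 4-atom rings at z = 0 and z = 5 Å define the
axis; pore ions sit at their site center plus isotropic Gaussian noise
(σ); reservoir ions occupy slabs 5 Å beyond the terminal boundaries with
deterministic lateral offsets.  Defaults for the stock 7-site model:
4 Å site spacing, σ = 0.5 Å, frame interval 10 ps, outward-biased rates
(hop up 0.004 /ps, hop down 0.0005 /ps, entry 0.004 /ps, exit
0.006 /ps), 20 reservoir ions with id recycling.  The 4 Å spacing puts
boundaries 4σ from site centers, so discretization of noisy coordinates
is essentially error-free (~6·10⁻⁵ misassignment per ion per frame); the
Kv1.2-style preset instead uses the historical boundary list 12.93, 9.32,
6.25, 3.00, 0.44, −2.21, −6.08, −20 Å with site centers at interval
midpoints and σ = 0.4 Å.

The two-mechanism event generator draws short state sequences from a
knock-on-like template (association first, concerted march, dissociation)
and an association/dissociation-like template (dissociation first, late
rebinding), perturbed by same-ion-count substitutions (p = 0.25 per
interior position) and occasional deletions (p = 0.15).  These values
were chosen so that within-template similarity (~0.85) clearly exceeds
cross-template similarity (~0.6) while events are far from identical.

**What passing synthetic tests show — and what they do not.**  They show
the machinery is correct: projection is exact geometry, discretization
recovers known labels, graph statistics match an exactly solvable chain,
permeation counts match an event log, and clustering separates known
mechanism templates.  They do not show that real MD data yields
well-separated density peaks, that a straight axis is adequate for a
given channel, or that real conduction events fall into clean clusters —
those are properties of the system under study, to be judged from the
histogram and dendrogram outputs.

## Problem sizes used in the test suite

Deterministic oracles run exhaustively at small n (alignments up to
length 6 against brute-force enumeration; all label sequences of length
≤ 6 on a 3-site model for conduction flags).  Stochastic checks use a
10⁵-frame run of the 7-site model for ground-truth recovery (≥ 99.9 %
frame labels, exact permeation counts, node probabilities within three
batch-means standard errors of the exact stationary distribution — batch
means because frames are autocorrelated) and 100 seeded 12-event runs for
mechanism separation.  The whole suite runs in about a minute on one CPU.

## Known limitations

- Straight pore axes only; curved or branching pores are out of scope.
- One ion species per run; the state label's species prefix comes from
  the configuration.
- Edge probabilities are globally normalized; kinetics (rates, MFPTs,
  committors) are not estimated.
- TRR is the only binary trajectory format read; convert others first.
- The boundary-ties convention (upper-inclusive) and the zero default gap
  score are conventions, not physical claims; both are configurable where
  it matters.
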