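# porestate

Ion-binding state analysis of molecular-dynamics trajectories of ion
channels.

Long MD simulations of K⁺ channels contain many ion conduction events, but
the raw output — Cartesian coordinates of every atom in every snapshot —
hides them.  `porestate` reduces such a trajectory to a discrete-state
description of permeation and then classifies the individual conduction
events:

1. **Pore-axis projection.**  The pore axis of each frame is the line from
   the centroid of one user-chosen atom set to the centroid of another
   (e.g. the backbone oxygens at the bottom and top of the selectivity
   filter).  Each ion's position becomes an axial coordinate *z* and a
   radial distance *r*.
2. **Site discretization.**  The axial ion density is histogrammed; minima
   between density peaks suggest boundaries for a series of binding sites
   S0…S(n−1), numbered from the extracellular side.  The *ion-binding
   state* of a frame is the set of occupied sites, written `K:0:2:4`
   (species prefix, ascending site indices; `K:` is the empty pore).
3. **State graph.**  The per-frame state sequence collapses into runs;
   states become nodes (weighted by occupancy probability) and observed
   state-to-state transitions become directed edges.  The graph is written
   as GML for Cytoscape and friends.
4. **Cycle decomposition.**  Anchored at the most stable state, the state
   path splits into cyclic paths.  A cycle containing both an ion-count
   increase (association) and a decrease (dissociation) is a conduction
   event.  Per-ion itineraries through the sites give permeation counts.
5. **Event classification.**  Each state gets a character (`*` for the
   anchor, upper/lower case by ion count relative to the anchor, `#` for
   two extra ions…), so events become strings.  Pairwise global alignment
   under the three-point rule — 1.0 identical state, 0.5 same ion count,
   0.0 otherwise — yields a similarity matrix, and UPGMA clustering a
   dendrogram that groups events by mechanism (e.g. knock-on vs.
   association/dissociation).

A seeded synthetic generator (`porestate.synthetic_data`) simulates
single-file hopping through a linear pore with ground-truth labels, so the
entire pipeline is testable without MD data.

## Input formats

GROMACS `.trr` trajectories are read through MDAnalysis (other formats
should be converted with VMD/MDAnalysis first).  A plain-text dialect
(`#frames N atoms M` header, then per frame a `t <time_ps>` line and M
`x y z` rows in Å) is supported for fixtures and synthetic data.  Atom
selections are resolved against a topology — a structure file readable by
MDAnalysis or a TSV with `name`/`resid`/`resname` columns — with a small
expression language (`resid 374 and name O`, `name K`, `not …`,
parentheses).

## Worked example

Generate a driven (voltage-biased) synthetic trajectory and run the whole
pipeline:

```sh
porestate simulate -o fixtures --preset knockon_bias --seed 5
porestate all -c fixtures/knockon_bias.config -o results
```

`results/` then contains the axial trace and density histogram (TSV +
PNG), the occupancy table, `state_graph.gml`, the cycle list, per-ion
itineraries, permeation counts, the event sequences with their similarity
matrix, and a dendrogram (Newick + PNG).  For the run above:

```
$ cat results/most_stable_state.txt
K:3:5
$ cat results/permeations.tsv
outward inward
365     0
$ head -4 results/sequences.txt
j#abefh*
BDGKcdh*
BDI01AC*
BEGJeAC*
```

The most stable state `K:3:5` holds two ions at sites S3 and S5; 365 ions
crossed outward (none inward — the preset has no inward driving force);
each sequence line is one conduction event rendered in characters, ending
at the anchor `*`.  The manifest records 134 cyclic paths of which 133
are conduction events, matching the strongly driven kinetics of this
preset.

Every stage can also be run separately (`project`, `histogram`,
`occupancy`, `graph`, `cycles`, `classify`), reading the previous stage's
artifacts from the output directory.  Config files use flat
`key = value` lines (keys like `fn-trr`, `pore-axis-basis-from`,
`site-boundary`, `site-max-radius`) or YAML; CLI flags override.

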