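# Methods

## Graph inference from stay records

A stay record is the 5-tuple (patient, case, unit, acquisition date,
outgoing date).  Records are grouped by the (patient, case) pair and
ordered within a case by acquisition date, with ties broken by outgoing
date and then by original file position.  Stays are expected not to
overlap; when the next acquisition precedes the previous outgoing date
the pair is reported in the run log but kept in acquisition order.

The case graph has one vertex per distinct unit code (the vertex
labelling is injective: a revisited unit maps back to the same vertex,
which is what makes directed cycles possible).  Every consecutive
record pair with differing units contributes the directed edge
(unit(r_i), unit(r_{i+1})).  Consecutive records in the same unit are
treated as a continued stay and add nothing — edges are relocations
between units, so the graphs carry no self-loops.  The edge weight is

    w = |duration(target stay) − duration(start stay)| + 1   (days)

where a stay's duration is outgoing − acquisition in whole days; the
+1 makes every weight a positive integer.  A directed relocation that
repeats within a case keeps the weight of its first occurrence and
increments an integer multiplicity instead (the graphs stay simple;
the per-occurrence information feeds the frequency tables).

The joined per-patient graph is the union of the patient's case graphs:
vertices merge by unit code, directed edges unite, multiplicities sum.
No merging rule for conflicting weights follows from the union itself;
we keep the weight contributed by the earliest case, where "earliest"
is positional — the pipeline passes cases in chronological order of
their first stay, which is the order the grouping stage emits.

## Classification

Categories are assigned in a fixed precedence: `empty` (no edges),
`cyclic` (the graph contains a directed cycle), `linear_2` /
`linear_long` (a directed path: a unique source with out-degree 1 and
in-degree 0, a unique sink with the degrees reversed, every other
vertex with exactly one incoming and one outgoing edge; together with
acyclicity these conditions force a single spanning path), and `other`
for the remaining acyclic shapes (branching vertices, disconnected
unions).  Connectivity means weak connectivity — one component of the
underlying undirected graph, hence no isolated vertices; strong
connectivity would declare every linear graph disconnected and is not
used.  Connectivity and categories are tabulated only for graphs with
more than one vertex, matching how such cohorts are conventionally
reported.

One corner case needs a convention: a joined graph can have several
vertices and no edges (a union of single-stay cases in different
units).  Per graph it is reported as `empty` (the category is defined
by the absence of edges); in the cohort summary it is counted in the
`other` column so that the four category columns exactly partition the
"more than one vertex" row.  Individual case graphs cannot hit this
corner: a multi-unit case always forms a single weakly connected chain,
so the per-case "disconnected" count is structurally zero.

## Indices

Distances are hop counts; the day weights are labels and never enter
an index.  The Wiener index is computed on the underlying undirected
graph — on a directed path the reverse distances do not exist, and the
undirected reading is the one under which linear graphs have finite
scores that grow with their order.  On a disconnected graph only
mutually reachable pairs contribute and the per-graph table flags the
graph as disconnected.

The Randić sum ranges over the edge set with the endpoint-degree
product under an inverse square root.  For directed graphs the sum is
evaluated twice over the directed edges — once with in-degrees, once
with out-degrees — and averaged (R_fin).  An endpoint of a directed
path has in-degree or out-degree 0; an edge whose degree product is 0
contributes 0, otherwise R_fin would be undefined on every linear
graph.  This contribute-zero convention is a package choice.  Under it
R_fin of a directed cycle on n vertices is exactly n, and R_fin of the
directed path on n vertices is n − 2 (each half loses its endpoint
edge and scores 1 on every interior edge) — small worked values are
frozen in the tests.

Extremal search ranks the graphs of a collection under one index after
discarding edgeless graphs (their score is trivially 0 and they carry
no flow information); all ties are reported in input order.

## Synthetic cohorts

The generator emulates the statistical shape of a single-diagnosis
paediatric cohort: 298 patients by default, a truncated-geometric
number of cases per patient with mean 4 (capped at 15), and a
records-per-case distribution of

| records | 1 | 2 | 3 | 4 | 5 |
|---------|---|---|---|---|---|
| prob    | 0.874 | 0.105 | 0.012 | 0.005 | 0.004 |

so that about 12.6 % of case graphs have more than one vertex and
two-vertex linear graphs dominate the non-empty ones.  Unit sequences
draw without replacement from a 13-code alphabet of ward/ICU/clinic
codes; from the third record of a case onwards, with probability
`revisit_prob` (default 0.03) the next stay returns to an earlier unit
of the same case, which always plants a directed cycle (the revisited
unit already reaches the current one along the chain).  An optional
transition-bias map reweights the choice of the next unit per
(current, candidate) pair, e.g. to concentrate transfers out of
intensive care onto wards.  Stay durations are 0–14 days (same-day
discharge probability 0.02, otherwise uniform on 1–14); consecutive
stays never overlap (the next acquisition is the previous outgoing date
plus a 0–2 day gap), which also removes any ordering ambiguity.  Start
dates fall in a 2005–2013 window.  All randomness flows from one
`numpy` generator seeded by the spec, and identical specs produce
byte-identical CSV output.

Ground truth (intended category, record count, planted transition list
per case) is emitted separately from the data file, which stays
format-faithful to the five-column spreadsheet schema.

What the generator does **not** model: per-patient ward affinity (each
case draws its first unit independently, so joined per-patient graphs
accumulate distinct units faster than in a real service where most
patients frequent a single ward — joined-graph connectivity proportions
are therefore not calibrated, only their accounting invariants);
seasonality, clinical severity, readmission timing, or any dependence
of stay length on unit.  Passing tests therefore demonstrate correct
graph inference, exact recovery of planted structure, and calibrated
per-case class proportions — not distributional realism of the joined
population.

## Numerical and design notes

* Dates are parsed strictly against a configurable format
  (day-first dotted by default); normalized output is ISO-8601.
* Unit codes are case-sensitive exact tokens, trimmed of surrounding
  whitespace only.
* Duplicate identical rows are kept (they may encode re-admission) and
  logged as warnings.
* Frequency rankings break count ties lexicographically so reports are
  deterministic; transition counts are per occurrence (record level),
  unit counts are per graph.
* The test oracles (cycle detection, path recognition, all-pairs BFS)
  are hand-rolled on adjacency dicts, independent of the networkx code
  paths they check; classifier agreement is exhaustive for all
  self-loop-free digraphs on up to 3 labelled vertices and sampled for
  4–6 vertices.
* Problem sizes in the test and acceptance runs (cohorts of 298
  patients, ten seeds; 1,000 random digraphs for the index identity)
  were chosen to exercise the cohort scale the pipeline targets while
  keeping the default suite fast.
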