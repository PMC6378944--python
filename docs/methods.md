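# Methods

## Model and assumptions

`wfcompose` synthesises *linear* pipelines: a single data item flows
through a chain of tools, each with exactly one input and one output
port.  This is a deliberate simplification — many real tools take
multiple inputs (e.g. a search engine also needs a sequence database) —
but it makes exhaustive enumeration tractable and matches how
tool-interoperability questions are usually asked ("what can I feed this
file into next?").  Multi-port annotations are rejected with an explicit
error rather than truncated.

Subsumption is plain is-a reachability over the taxonomy DAG, reflexive
and transitive, with multiple parents allowed.  No other ontology
relations (has-topic, has-input) participate in matching.  Applicability
is directional: tools may declare *classes* for their ports, data states
are always *concrete*, and a state satisfies a declared concept when the
state's concept is a descendant-or-equal of it.  Consequently
`format:1915` (the format root) in a goal means "any format".

### Constraint semantics

The five constraint templates are interpreted over the finite trace of
tool names only (states play no role):

* `use A` — some position matches A;
* `do not use A` — no position matches;
* `use A only after B` — no position matching A may precede the first
  position matching B.  This is the *weak* (anywhere-before) reading: B
  is not required when A never occurs, and B need not be immediately
  before A.  The strict "immediately before" alternative would reject
  published pipelines in which unrelated steps sit between the
  dependency pair, so the weak reading is the only one consistent with
  the bundled use cases.  If A and B first match at the same position,
  the constraint is violated ("strictly preceded").
* `do not use A more than once` — at most one match;
* `do not use A directly after A` — no two consecutive matches.

The empty trace satisfies everything except `use A`.  Operation atoms
match a tool through its *annotated* operations under subsumption; a
tool never matches an operation merely because some other relation
places it nearby.

Each template compiles to a deterministic total monitor with 2 states
(`use`, `do not use`) or 3 states (the rest, including a reject sink).
Monitor/declarative equivalence is enforced by seeded randomised tests
rather than assumed.

### Search

Synthesis is breadth-first over the product of the concrete data state
and the joint monitor-state vector, layered by pipeline length:

1. layer 0 holds the initial product state; layer *l+1* is obtained by
   applying every applicable (tool, declared output format) pair and
   stepping all monitors, discarding any successor whose monitor vector
   contains a reject sink, and deduplicating product states;
2. a product state at layer *l* is a *goal node* when its data state
   satisfies the goal under subsumption and all monitors accept;
3. solutions of length *l* are recovered by walking the layered edge
   relation from the root to the goal nodes; counting uses dynamic
   programming over the same layers.

Deduplication bounds the number of expanded nodes by
`|data states| x prod(monitor sizes) x bound` (checked by an explicit
counter), while path recovery still yields every individual solution.
The search is sound and complete within the bound; cycles such as
repeated format conversions are allowed up to the bound unless excluded
by constraints, which is exactly why the bundled domain model carries
global "do not use msconvert/idconvert directly after itself" rules.

Determinism: successor expansion is ordered by tool name then output
format id, solutions sort by (length, tool names, formats), and DOT/TSV
writers emit sorted, byte-stable output.

Zero-length solutions are admitted when the initial state already
satisfies the goal and the empty trace satisfies all constraints; the
bundled use cases never exercise this, but the identity case keeps the
semantics total.

### Counting modes

Solutions are state-annotated paths: one tool chain routed through two
different intermediate formats counts twice.  This matches counting
paths through a merged solution graph whose nodes are concrete data
items, and it is the mode in which the bundled fixture was calibrated.
`SolutionSet.tool_sequences()` (CLI: `--count-mode tool-sequences`)
collapses to distinct tool chains instead.

### Solution graphs

Merging is per step index: two solutions share a node only when they
reach the same (data, format) pair at the same depth.  Global merging
(ignoring depth) could create input-to-output paths that correspond to
no solution; per-step merging guarantees the path-count identity
`DP path count == number of solutions`, which the test suite checks on
all four use cases.

## The bundled fixture and its calibration

The fixture emulates a published proteomics composition study: an EDAM
1.18 excerpt (36 concepts over the operation/data/format branches) and
22 tools.  The study's comprehensive annotation table is not
redistributable, so the annotations were reconstructed from the named
tools, the listed workflows and the solution-graph structure, then
calibrated against the published solution counts.  The calibrated
surface — reproduced exactly — comprises the minimal pipeline lengths
(4, 6, 4, 4 for use cases 1–4) and the solution counts at those lengths
(31, 20, 13, 16, state-path counting), which decompose as:

* uc1: 4 (msconvert formats into Comet -> PeptideProphet -> rt4)
  + 3 x 3 x 3 (SearchGUI route x report formats x TSV-family
  retention-time predictors) = 31;
* uc2: 4 x (2 + 1 + 2) (accession-list formats accepted by GeneTrail2 /
  EnrichNet / gProfileR) = 20;
* uc3: 4 + 3 x 3 = 13;  uc4: 4 + 3 x 4 = 16.

Calibration-sensitive choices are flagged with `note` fields inside
`src/wfcompose/data/domain_model.json`.  The largest one: three
TSV-family retention-time predictors (SSRCalc plus ELUDE and GPTime, two
real tools beyond those the study's listings name) are required — the
named tools alone cannot produce 31 length-4 solutions for use case 1.

**Known, intentional divergence:** the published counts at larger
bounds (388 solutions up to length 5 and 3127 up to length 6 for use
case 1) depend on the many additional annotated tools of the original
study and are *not* reproduced: this reconstruction computes 96 and 323.
`wfcompose.fixtures.count_report()` recomputes all quantities and flags
these two as outside the calibrated surface.  Passing tests therefore
demonstrate correctness of the synthesis semantics and calibration of
the minimal-length surface, not recovery of the full original tool
library.

The EDAM excerpt follows the study's printed concept ids verbatim;
un-printed ids are a plausible reconstruction and nothing depends on
their numeric values.  One consequence adopted deliberately: the
identification-results data concept is `data:0945` ("Protein
identification", as printed) for the whole identification chain, so the
PTM use-case goal is reachable exactly as listed.

## Random domain models

The property-test generator (`fixtures.random_domain`) emulates the
*shape* of real domain models — rooted taxonomy trees per branch, tools
with branch-correct single ports, 1–3 formats per port — at sizes (≤7
tools, ≤5 concepts per branch) where brute-force enumeration is feasible
as an oracle.  It does not emulate realistic format sparsity, label
text, or multi-parent concepts (random DAG taxonomies are exercised
separately in the subsumption tests); conclusions from these tests are
about the search/monitor machinery, not about any real tool library.
Generation is a pure function of `RandomDomainConfig` (seed included),
so failures reproduce exactly.

## Numerical/engineering choices

* Problem sizes in tests and the acceptance script: 200 random models at
  bound ≤ 4 with ≤ 6 tools for oracle equivalence, 1000 random traces
  for monitor equivalence, bounds ≤ 6 on the fixture.  These sizes keep
  the whole suite under a few seconds while exercising every code path;
  the fixture synthesis itself is milliseconds.
* Curies are case-sensitive and must match
  `^(operation|data|format|topic):[0-9]+$`.
* Taxonomy loading validates: resolvable same-branch parents, exactly
  one root per branch, acyclicity (one offending cycle is printed).
* Domain-model files carry an `edam_version` string; it is provenance
  only (the flattened taxonomy dialect carries no version to compare
  against).
* Tie-breaks everywhere are lexicographic; there is no randomness in
  the library itself, only in test/verification harnesses, always
  seeded.

## Limitations

* No multi-input/multi-output tools, no parallelism, loops or
  conditional branching; pipelines are sequences.
* Only the five constraint templates — no nested temporal operators.
* Solutions are abstract: the skeleton exporter emits placeholder
  command lines, not runnable invocations (tool parameters are outside
  the annotation model).
* Only is-a subsumption; no OWL reasoning, no handling of deprecated
  concepts.
* The OBO reader accepts the id/name/is_a subset only.
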