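# wfcompose

Automated composition of linear bioinformatics tool pipelines from
semantic annotations.

## The problem

Mass-spectrometry-based proteomics (and bioinformatics generally) offers
dozens of interchangeable command-line tools for each analysis step —
format conversion, peptide database search, validation of
peptide-spectrum matches (PSMs), protein inference, retention-time
prediction, quantitation, enrichment analysis.  Working out *which chains
of tools are even type-compatible*, including the format converters
nobody remembers to mention, is tedious and error-prone.  When every tool
is annotated with EDAM ontology concepts — an operation, plus one input
and one output port, each a Data concept with one or more Format
concepts — pipeline discovery becomes a search problem that can be solved
exhaustively.

`wfcompose` is a toolkit for that search.  It is aimed at bioinformatics
methods developers who want to enumerate, compare and benchmark all
workflows satisfying a declarative specification, rather than hand-pick
one.

## The model

A **taxonomy** is the EDAM is-a DAG over `operation`, `data`, `format`
(and `topic`) branches; a concrete concept *c* satisfies a class-level
requirement *C* iff *c* ⊑ *C* (reachability over is-a edges, reflexive).
A **domain model** adds a library of tools, each
`t = (ops(t), in(t), out(t))` with single input/output ports, and global
constraints.  A **data state** is a concrete pair (data concept, format).
Tool *t* is applicable in state *(d, f)* iff `d ⊑ data(in(t))` and
`f ⊑ φ` for some declared input format φ; it branches to one successor
state per declared output format.

A **workflow specification** gives an initial state, a goal class
(data concept, format class — the format root `format:1915` means "any
format"), a length bound, and temporal constraints over the finite trace
of tools, written in five natural-language templates:

```
use <A>                          F a           (something matching A occurs)
do not use <A>                   G ¬a
use <A> only after <B>           ¬a W b        (no A before the first B)
do not use <A> more than once    at most one position matches A
do not use <A> directly after <A>   no two consecutive A's
```

where `<A>` is a tool name or an operation class (matched against a
tool's annotated operations under subsumption).  Each constraint compiles
to a 2–3-state deterministic monitor; synthesis is a breadth-first search
over the product of the data state and the joint monitor state, layered
by length, with reject-sink pruning.  The search is complete within the
bound: it returns *every* state-annotated pipeline (the same tool chain
routed through different intermediate formats counts separately, matching
path counts over solution graphs whose nodes are concrete data items).
Fixed-length solution sets merge into an automata-like **solution graph**
in which every input-to-output path is a valid workflow.

## Bundled fixture: four proteomics use cases

The package ships an EDAM 1.18 excerpt and a library of 22 annotated
proteomics tools (msconvert, Comet, X! Tandem, the Trans-Proteomic
Pipeline Prophet tools, SearchGUI/PeptideShaker, retention-time
predictors, enrichment tools, iTRAQ quantitation), with four workflow
specifications, all starting from mass-spectrometry spectra in Thermo RAW
format:

1. peptide retention-time prediction (goal: amino acid index);
2. protein identification + gene-set enrichment (goal: pathway/network);
3. PTM identification and localization (goal: identification results);
4. iTRAQ protein quantitation (goal: expression profile).

## Worked example

Enumerate the shortest pipelines for use case 3 (PTM localization):

```sh
$ wfcompose compose --spec src/wfcompose/data/spec_uc3.json
length  tools   formats
4  msconvert -> Comet -> PeptideProphet -> PTMProphet  format:3712 -> format:3244 -> format:3655 -> format:3655 -> format:3655
...
4  msconvert -> SearchGUI -> PeptideShaker_VPSM -> PeptideShaker_PTMI  format:3712 -> format:3654 -> format:3713 -> format:3752 -> format:3475
{
  "count_mode": "state-paths",
  "counts_by_length": {"4": 13},
  ...
}
```

13 solutions of length 4: every pipeline opens with a conversion step
(no search engine reads vendor RAW), runs a peptide database search, one
PSM-validation step (the spec forbids more than one), then a PTM tool.
The 13 state-paths collapse to 2 distinct tool chains
(`--count-mode tool-sequences`), differing in intermediate formats.

```sh
$ wfcompose min-length --spec src/wfcompose/data/spec_uc2.json
6
```

Six steps are needed for identification + enrichment: conversion,
search, PeptideProphet, ProteinProphet, accession extraction, enrichment.

```sh
$ wfcompose validate --spec src/wfcompose/data/spec_uc1.json \
    "msconvert -> Comet -> PeptideProphet -> rt4"
PASS
  step 1: msconvert [format:3712 -> format:3244]
  step 2: Comet [format:3244 -> format:3655]
  step 3: PeptideProphet [format:3655 -> format:3655]
  step 4: rt4 [format:3655 -> format:3475]
```

`wfcompose graph --spec ... --out g.dot` emits the merged solution graph
as DOT; `wfcompose fixtures --out DIR` writes the bundled taxonomy,
domain model and specification files for inspection or editing.

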