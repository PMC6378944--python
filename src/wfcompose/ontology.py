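"""EDAM-style taxonomies: concepts, branches and is-a subsumption.

The EDAM ontology organises bioinformatics vocabulary into four branches
(``operation``, ``data``, ``format``, ``topic``), each a rooted DAG under the
is-a relation.  Workflow composition only needs subsumption queries over that
DAG: a concrete concept satisfies a class-level requirement exactly when the
class is an ancestor-or-equal.  Two serialisations are supported:

* a strict subset of OBO (``[Term]`` stanzas with ``id``/``name``/``is_a``),
  read through :mod:`obonet`;
* a flattened tab-delimited table with columns ``id``, ``label``, ``branch``,
  ``parents`` (pipe-separated), which is the dialect the bundled fixture uses
  so that no ontology download is required.

Concept identifiers are curie strings such as ``operation:3631`` and are
treated case-sensitively.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import LookupError_, TaxonomyError

BRANCHES = ("operation", "data", "format", "topic")

CURIE_RE = re.compile(r"^(operation|data|format|topic):[0-9]+$")

#: Root of the EDAM format branch ("any format" in workflow specifications).
FORMAT_ROOT = "format:1915"


def branch_of(curie: str) -> str:
    """Return the branch encoded in a curie's prefix.

    Raises :class:`TaxonomyError` if the curie is malformed.
    """
    m = CURIE_RE.match(curie)
    if not m:
        raise TaxonomyError(f"malformed concept id {curie!r}; "
                            f"expected e.g. 'operation:3631'")
    return m.group(1)


@dataclass(frozen=True)
class Concept:
    """A single ontology concept.

    Attributes
    ----------
    id:
        Curie-style persistent identifier, unique within a taxonomy.
    label:
        Preferred term.
    branch:
        One of ``operation``, ``data``, ``format``, ``topic``.
    parent_ids:
        Direct is-a parents; empty for a branch root.  All parents must lie
        in the same branch.
    """

    id: str
    label: str
    branch: str
    parent_ids: tuple[str, ...] = ()


class Taxonomy:
    """A validated is-a DAG over EDAM-style concepts.

    Construction validates that every parent reference resolves within the
    same branch, that each branch present has exactly one root, and that the
    parent relation is acyclic.  Subsumption queries are answered from a
    cached transitive closure.
    """

    def __init__(self, concepts: Iterable[Concept]):
        self._concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.id in self._concepts:
                raise TaxonomyError(f"duplicate concept id {c.id}")
            if c.branch not in BRANCHES:
                raise TaxonomyError(
                    f"concept {c.id} has unknown branch {c.branch!r}")
            if branch_of(c.id) != c.branch:
                raise TaxonomyError(
                    f"concept {c.id} declares branch {c.branch!r} but its id "
                    f"prefix says {branch_of(c.id)!r}")
            self._concepts[c.id] = c
        self._validate()
        self._ancestors: dict[str, frozenset[str]] = {}
        self._descendants: dict[str, frozenset[str]] | None = None

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        for c in self._concepts.values():
            for p in c.parent_ids:
                parent = self._concepts.get(p)
                if parent is None:
                    raise TaxonomyError(
                        f"concept {c.id} references unknown parent {p}")
                if parent.branch != c.branch:
                    raise TaxonomyError(
                        f"concept {c.id} ({c.branch}) has parent {p} in "
                        f"branch {parent.branch}")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            pretty = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
            raise TaxonomyError(f"is-a relation contains a cycle: {pretty}")
        for branch in self.branches():
            roots = [c.id for c in self._concepts.values()
                     if c.branch == branch and not c.parent_ids]
            if len(roots) != 1:
                raise TaxonomyError(
                    f"branch {branch!r} must have exactly one root, "
                    f"found {sorted(roots)}")

    # -- basic access ----------------------------------------------------

    def __contains__(self, curie: str) -> bool:
        return curie in self._concepts

    def __len__(self) -> int:
        return len(self._concepts)

    def __iter__(self):
        return iter(self._concepts.values())

    @property
    def concepts(self) -> Mapping[str, Concept]:
        return self._concepts

    def get(self, curie: str) -> Concept:
        try:
            return self._concepts[curie]
        except KeyError:
            raise LookupError_(f"unknown concept id {curie}") from None

    def branches(self) -> tuple[str, ...]:
        return tuple(sorted({c.branch for c in self._concepts.values()},
                            key=BRANCHES.index))

    def branch_root(self, branch: str) -> Concept:
        roots = [c for c in self._concepts.values()
                 if c.branch == branch and not c.parent_ids]
        if not roots:
            raise LookupError_(f"taxonomy has no {branch!r} branch")
        return roots[0]

    def branch_concepts(self, branch: str) -> frozenset[str]:
        return frozenset(c.id for c in self._concepts.values()
                         if c.branch == branch)

    def resolve_label(self, label: str, branch: str | None = None) -> str:
        """Map a preferred term back to its curie.

        Raises :class:`LookupError_` when the label is unknown or ambiguous
        within the requested branch.
        """
        hits = [c.id for c in self._concepts.values()
                if c.label == label and (branch is None or c.branch == branch)]
        if not hits:
            raise LookupError_(f"no concept labelled {label!r}")
        if len(hits) > 1:
            raise LookupError_(
                f"label {label!r} is ambiguous: {sorted(hits)}")
        return hits[0]

    def graph(self) -> nx.DiGraph:
        """The is-a relation as a child -> parent :class:`networkx.DiGraph`."""
        g = nx.DiGraph()
        g.add_nodes_from(self._concepts)
        for c in self._concepts.values():
            for p in c.parent_ids:
                g.add_edge(c.id, p)
        return g

    # -- subsumption -----------------------------------------------------

    def ancestors(self, curie: str) -> frozenset[str]:
        """All ancestors-or-self of ``curie`` via zero or more parent steps."""
        cached = self._ancestors.get(curie)
        if cached is not None:
            return cached
        c = self.get(curie)
        acc: set[str] = {curie}
        for p in c.parent_ids:
            acc |= self.ancestors(p)
        result = frozenset(acc)
        self._ancestors[curie] = result
        return result

    def is_subsumed(self, child_id: str, ancestor_id: str) -> bool:
        """True iff ``ancestor_id`` is reachable from ``child_id`` upwards.

        Reflexive: every concept subsumes itself.
        """
        self.get(ancestor_id)  # raise on unknown ancestor
        return ancestor_id in self.ancestors(child_id)

    def descendants(self, curie: str) -> frozenset[str]:
        """All ids ``c`` with ``is_subsumed(c, curie)``, including ``curie``."""
        if self._descendants is None:
            down: dict[str, set[str]] = {i: {i} for i in self._concepts}
            for c in self._concepts.values():
                for anc in self.ancestors(c.id):
                    down[anc].add(c.id)
            self._descendants = {k: frozenset(v) for k, v in down.items()}
        try:
            return self._descendants[curie]
        except KeyError:
            raise LookupError_(f"unknown concept id {curie}") from None


# -- serialisation -------------------------------------------------------

TSV_HEADER = ("id", "label", "branch", "parents")


def _load_tsv(path: Path) -> Taxonomy:
    concepts = []
    with open(path, encoding="utf-8") as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if tuple(fields) != TSV_HEADER:
                    raise TaxonomyError(
                        f"{path}:{lineno}: bad header {fields!r}; expected "
                        f"{list(TSV_HEADER)}")
                header = fields
                continue
            if len(fields) == 3:  # roots may omit the empty parents column
                fields = fields + [""]
            if len(fields) != 4:
                raise TaxonomyError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}")
            cid, label, branch, parents = fields
            parent_ids = tuple(p for p in parents.split("|") if p)
            try:
                concepts.append(
                    Concept(cid, label, branch, parent_ids))
            except TaxonomyError as exc:
                raise TaxonomyError(f"{path}:{lineno}: {exc}") from None
    if header is None:
        raise TaxonomyError(f"{path}: empty taxonomy file")
    return Taxonomy(concepts)


def _load_obo(path: Path) -> Taxonomy:
    import obonet

    try:
        g = obonet.read_obo(str(path), ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted parse errors
        raise TaxonomyError(f"{path}: OBO parse error: {exc}") from None
    concepts = []
    for node, attrs in g.nodes(data=True):
        parents = tuple(sorted(
            v for _, v, key in g.out_edges(node, keys=True) if key == "is_a"))
        concepts.append(Concept(
            id=node,
            label=attrs.get("name", node),
            branch=branch_of(node),
            parent_ids=parents,
        ))
    concepts.sort(key=lambda c: c.id)
    return Taxonomy(concepts)


def load_taxonomy(path: str | Path, dialect: str | None = None) -> Taxonomy:
    """Load a taxonomy from ``path``.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"tsv"`` (flattened table) or ``"obo"``; inferred from the file
        extension when omitted.
    """
    p = Path(path)
    if dialect is None:
        dialect = "obo" if p.suffix.lower() == ".obo" else "tsv"
    if dialect == "tsv":
        return _load_tsv(p)
    if dialect == "obo":
        return _load_obo(p)
    raise TaxonomyError(f"unknown taxonomy dialect {dialect!r}")


def write_taxonomy_tsv(taxonomy: Taxonomy, path: str | Path) -> None:
    """Serialise to the flattened dialect (stable, sorted by id)."""
    lines = ["\t".join(TSV_HEADER)]
    for c in sorted(taxonomy, key=lambda c: c.id):
        lines.append("\t".join(
            (c.id, c.label, c.branch, "|".join(c.parent_ids))))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
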