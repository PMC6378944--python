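"""Annotated tool libraries and tool applicability in a data state.

A *domain model* bundles a taxonomy, a library of semantically annotated
tools and a (possibly empty) set of global temporal constraints.  Each tool
carries exactly one input and one output port; a port names one EDAM Data
concept and one or more EDAM Format concepts.  A concrete *data state* (one
Data concept, one concrete Format) is acceptable to a tool when the state's
concepts are descendants-or-equal of the declared port concepts: tools may
declare classes, states are concrete.

The file format is JSON::

    {
      "edam_version": "1.18",
      "tools": [
        {"name": "msconvert",
         "operations": ["operation:0335"],
         "input":  {"data": "data:0943", "formats": ["format:3712", ...]},
         "output": {"data": "data:0943", "formats": ["format:3244", ...]}},
        ...
      ],
      "constraints": ["do not use msconvert directly after msconvert", ...]
    }

Constraint strings use the natural-language templates of
:mod:`wfcompose.constraints`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

from .errors import LookupError_, ValidationError
from .ontology import Taxonomy

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .constraints import Constraint


@dataclass(frozen=True)
class PortSpec:
    """One I/O port: an EDAM Data concept plus one or more Format concepts."""

    data_id: str
    format_ids: tuple[str, ...]

    def validate(self, taxonomy: Taxonomy, where: str) -> None:
        if not self.format_ids:
            raise ValidationError(f"{where}: port declares no formats")
        if self.data_id not in taxonomy:
            raise ValidationError(
                f"{where}: unknown data concept {self.data_id}")
        if taxonomy.get(self.data_id).branch != "data":
            raise ValidationError(
                f"{where}: {self.data_id} is not in the data branch")
        for f in self.format_ids:
            if f not in taxonomy:
                raise ValidationError(f"{where}: unknown format concept {f}")
            if taxonomy.get(f).branch != "format":
                raise ValidationError(
                    f"{where}: {f} is not in the format branch")


@dataclass(frozen=True)
class ToolAnnotation:
    """A tool with its EDAM operation(s) and single input/output ports."""

    name: str
    operation_ids: tuple[str, ...]
    input: PortSpec
    output: PortSpec

    def validate(self, taxonomy: Taxonomy) -> None:
        if not self.name:
            raise ValidationError("tool with empty name")
        if not self.operation_ids:
            raise ValidationError(
                f"tool {self.name!r}: no operation annotation")
        for op in self.operation_ids:
            if op not in taxonomy:
                raise ValidationError(
                    f"tool {self.name!r}: unknown operation concept {op}")
            if taxonomy.get(op).branch != "operation":
                raise ValidationError(
                    f"tool {self.name!r}: {op} is not in the operation branch")
        self.input.validate(taxonomy, f"tool {self.name!r} input")
        self.output.validate(taxonomy, f"tool {self.name!r} output")


@dataclass(frozen=True, order=True)
class DataState:
    """A concrete data item: one Data concept in one concrete Format."""

    data_id: str
    format_id: str

    def validate(self, taxonomy: Taxonomy) -> None:
        if self.data_id not in taxonomy:
            raise ValidationError(f"unknown data concept {self.data_id}")
        if taxonomy.get(self.data_id).branch != "data":
            raise ValidationError(
                f"{self.data_id} is not in the data branch")
        if self.format_id not in taxonomy:
            raise ValidationError(f"unknown format concept {self.format_id}")
        if taxonomy.get(self.format_id).branch != "format":
            raise ValidationError(
                f"{self.format_id} is not in the format branch")


class DomainModel:
    """Taxonomy + tool library + global constraints.

    Tool names are unique; every concept reference is checked against the
    taxonomy at construction time.
    """

    def __init__(self, taxonomy: Taxonomy,
                 tools: Iterable[ToolAnnotation],
                 global_constraints: "tuple[Constraint, ...]" = (),
                 edam_version: str | None = None):
        self.taxonomy = taxonomy
        self._tools: dict[str, ToolAnnotation] = {}
        for t in tools:
            if t.name in self._tools:
                raise ValidationError(f"duplicate tool name {t.name!r}")
            t.validate(taxonomy)
            self._tools[t.name] = t
        self.global_constraints = tuple(global_constraints)
        self.edam_version = edam_version

    @property
    def tools(self) -> Mapping[str, ToolAnnotation]:
        return self._tools

    def tool(self, name: str) -> ToolAnnotation:
        try:
            return self._tools[name]
        except KeyError:
            raise LookupError_(f"unknown tool {name!r}") from None

    def __len__(self) -> int:
        return len(self._tools)

    def __contains__(self, name: str) -> bool:
        return name in self._tools


def compatible(tool: ToolAnnotation, state: DataState,
               taxonomy: Taxonomy) -> bool:
    """True iff ``tool`` can consume ``state``.

    The state's data concept must be a descendant-or-equal of the tool's
    declared input data concept, and the state's concrete format a
    descendant-or-equal of at least one declared input format.
    """
    if not taxonomy.is_subsumed(state.data_id, tool.input.data_id):
        return False
    return any(taxonomy.is_subsumed(state.format_id, f)
               for f in tool.input.format_ids)


def successors(model: DomainModel,
               state: DataState) -> list[tuple[str, DataState]]:
    """The transition relation used by synthesis.

    One entry per (applicable tool, declared output format): a tool with
    several declared output formats branches into one successor state per
    format.  The list is sorted by tool name, then successor format id, so
    enumeration order is reproducible.
    """
    out: list[tuple[str, DataState]] = []
    for name in sorted(model.tools):
        tool = model.tools[name]
        if compatible(tool, state, model.taxonomy):
            for f in sorted(tool.output.format_ids):
                out.append((name, DataState(tool.output.data_id, f)))
    return out


# -- serialisation -------------------------------------------------------

def _port_from_json(obj, where: str) -> PortSpec:
    if not isinstance(obj, dict) or "data" not in obj or "formats" not in obj:
        raise ValidationError(
            f"{where}: port must be an object with 'data' and 'formats'")
    formats = obj["formats"]
    if not isinstance(formats, list) or not formats:
        raise ValidationError(f"{where}: 'formats' must be a non-empty list")
    return PortSpec(data_id=obj["data"], format_ids=tuple(formats))


def load_domain_model(path: str | Path, taxonomy: Taxonomy) -> DomainModel:
    """Load and validate a domain-model JSON file against ``taxonomy``.

    A mismatch between the file's ``edam_version`` and the taxonomy is not
    detectable here (the flattened taxonomy carries no version), so the
    version string is retained on the model for provenance only.
    """
    from .constraints import parse_constraint

    p = Path(path)
    try:
        doc = json.loads(p.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{p}: invalid JSON: {exc}") from None
    if not isinstance(doc, dict) or "tools" not in doc:
        raise ValidationError(f"{p}: expected an object with a 'tools' list")
    tools = []
    for i, entry in enumerate(doc["tools"]):
        where = f"{p}: tools[{i}]"
        if not isinstance(entry, dict) or "name" not in entry:
            raise ValidationError(f"{where}: missing tool name")
        name = entry["name"]
        for key in ("operations", "input", "output"):
            if key not in entry:
                raise ValidationError(
                    f"{where} ({name!r}): missing field {key!r}")
        extra = [k for k in entry
                 if k not in ("name", "operations", "input", "output",
                              "note")]
        if extra:
            raise ValidationError(
                f"{where} ({name!r}): unsupported fields {extra} "
                f"(tools have exactly one input and one output port)")
        tools.append(ToolAnnotation(
            name=name,
            operation_ids=tuple(entry["operations"]),
            input=_port_from_json(entry["input"], f"{where} ({name!r}) input"),
            output=_port_from_json(entry["output"],
                                   f"{where} ({name!r}) output"),
        ))
    model = DomainModel(taxonomy, tools,
                        edam_version=doc.get("edam_version"))
    constraints = tuple(parse_constraint(text, model)
                        for text in doc.get("constraints", []))
    model.global_constraints = constraints
    return model


def save_domain_model(model: DomainModel, path: str | Path) -> None:
    """Round-tripping writer for the JSON domain-model dialect."""
    from .constraints import constraint_to_text

    doc = {
        "edam_version": model.edam_version,
        "tools": [
            {
                "name": t.name,
                "operations": list(t.operation_ids),
                "input": {"data": t.input.data_id,
                          "formats": list(t.input.format_ids)},
                "output": {"data": t.output.data_id,
                           "formats": list(t.output.format_ids)},
            }
            for t in (model.tools[n] for n in sorted(model.tools))
        ],
        "constraints": [constraint_to_text(c)
                        for c in model.global_constraints],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
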