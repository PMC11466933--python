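"""Op metadata model and YAML descriptor round-tripping.

An *op* is a named algorithm plugin with a declared functional shape
(function / computer / inplace), an ordered parameter list, a priority used
for ranking, and a ``source`` locator (``"module:callable"``) resolving to the
implementation.  Ops are declared in YAML descriptor files; this module owns
the schema, parsing, emission, and the expansion of optional parameters into
reduced signatures.

Descriptor schema (normative for this package)::

    version: "1"
    ops:
      - names: [filter.gauss]
        type: computer            # function | computer | inplace
        priority: 0.0
        source: "pkg.module:callable"
        description: "..."
        parameters:
          - {name: input,  type: image, io: input,  optional: false}
          - {name: sigma,  type: real,  io: input,  optional: false}
          - {name: output, type: image, io: container}
        dependencies: []          # [{slot: gauss, name: filter.gauss, type: computer}]

Dependency entries accept optional ``in:`` (list of type names) and ``out:``
keys so a composite op can pin the parameter types of its helper requests.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace

import yaml

from .errors import DescriptorError, ValidationError

log = logging.getLogger(__name__)

MANDATORY_KEYS = ("names", "type", "source", "parameters")
KNOWN_OP_KEYS = MANDATORY_KEYS + ("priority", "description", "dependencies")
KNOWN_PARAM_KEYS = ("name", "type", "io", "optional", "default", "description")
KNOWN_DEP_KEYS = ("slot", "name", "type", "in", "out")


class Shape(str, enum.Enum):
    """Functional shape of an op."""

    FUNCTION = "function"  # pure: consumes inputs, allocates a new output
    COMPUTER = "computer"  # writes its output into a pre-allocated container
    INPLACE = "inplace"    # overwrites one mutable argument

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class IORole(str, enum.Enum):
    INPUT = "input"
    CONTAINER = "container"
    MUTABLE = "mutable"
    OUTPUT = "output"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class _NoDefault:
    """Sentinel: an optional parameter that declares no default value."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "<no default>"


NO_DEFAULT = _NoDefault()


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    type_name: str
    io_role: IORole = IORole.INPUT
    optional: bool = False
    default: object = NO_DEFAULT
    description: str = ""


@dataclass(frozen=True)
class DependencySpec:
    """A helper op a composite op requires, resolved by the engine at match time."""

    slot: str
    name: str
    shape: Shape
    in_types: tuple[str, ...] | None = None
    out_type: str | None = None


@dataclass(frozen=True)
class OpInfo:
    """The registered description of one op."""

    names: tuple[str, ...]
    shape: Shape
    parameters: tuple[ParameterSpec, ...]
    source: str
    priority: float = 0.0
    description: str = ""
    dependencies: tuple[DependencySpec, ...] = ()
    reduced_from: "OpInfo | None" = None

    @property
    def name(self) -> str:
        """Primary (first) name."""
        return self.names[0]

    def input_params(self) -> tuple[ParameterSpec, ...]:
        """All call-order parameters (everything except the declared OUTPUT)."""
        return tuple(p for p in self.parameters if p.io_role is not IORole.OUTPUT)

    def output_param(self) -> ParameterSpec | None:
        for p in self.parameters:
            if p.io_role is IORole.OUTPUT:
                return p
        return None

    def container_index(self) -> int | None:
        """Index of the CONTAINER among call-order parameters, or None."""
        for i, p in enumerate(self.input_params()):
            if p.io_role is IORole.CONTAINER:
                return i
        return None

    def mutable_index(self) -> int | None:
        for i, p in enumerate(self.input_params()):
            if p.io_role is IORole.MUTABLE:
                return i
        return None


def validate_op_info(info: OpInfo) -> None:
    """Check structural invariants; raise :class:`ValidationError` listing the violation."""
    label = "/".join(info.names) if info.names else "<unnamed>"
    if not info.names:
        raise ValidationError("op has an empty names list")
    if not info.source:
        raise ValidationError(f"op {label}: empty source locator")
    names = [p.name for p in info.parameters]
    if len(set(names)) != len(names):
        raise ValidationError(f"op {label}: duplicate parameter names {names}")
    n_out = sum(p.io_role is IORole.OUTPUT for p in info.parameters)
    n_cont = sum(p.io_role is IORole.CONTAINER for p in info.parameters)
    n_mut = sum(p.io_role is IORole.MUTABLE for p in info.parameters)
    if info.shape is Shape.FUNCTION:
        if n_out != 1 or n_cont or n_mut:
            raise ValidationError(
                f"op {label}: a function op needs exactly one OUTPUT and no "
                f"CONTAINER/MUTABLE (got {n_out} outputs, {n_cont} containers, {n_mut} mutables)"
            )
    elif info.shape is Shape.COMPUTER:
        if n_cont != 1 or n_out or n_mut:
            raise ValidationError(
                f"op {label}: a computer op needs exactly one CONTAINER and no "
                f"OUTPUT/MUTABLE (got {n_cont} containers, {n_out} outputs, {n_mut} mutables)"
            )
    elif info.shape is Shape.INPLACE:
        if n_mut != 1 or n_out or n_cont:
            raise ValidationError(
                f"op {label}: an inplace op needs exactly one MUTABLE and no "
                f"OUTPUT/CONTAINER (got {n_mut} mutables, {n_out} outputs, {n_cont} containers)"
            )
    for p in info.parameters:
        if p.optional and p.io_role is not IORole.INPUT:
            raise ValidationError(
                f"op {label}: parameter {p.name!r} is optional but has io role "
                f"{p.io_role.value}; only INPUT parameters may be optional"
            )


# ---------------------------------------------------------------------------
# YAML parsing / emission
# ---------------------------------------------------------------------------

def _parse_param(raw: dict, label: str) -> ParameterSpec:
    if not isinstance(raw, dict):
        raise DescriptorError(f"entry {label}: parameter entry is not a mapping: {raw!r}")
    for key in ("name", "type"):
        if key not in raw:
            raise DescriptorError(f"entry {label}: parameter missing mandatory key {key!r}")
    for key in raw:
        if key not in KNOWN_PARAM_KEYS:
            log.warning("entry %s: ignoring unknown parameter key %r", label, key)
    try:
        io = IORole(raw.get("io", "input"))
    except ValueError:
        raise DescriptorError(
            f"entry {label}: unknown io role {raw.get('io')!r} for parameter {raw['name']!r}"
        ) from None
    default = raw["default"] if "default" in raw else NO_DEFAULT
    return ParameterSpec(
        name=str(raw["name"]),
        type_name=str(raw["type"]),
        io_role=io,
        optional=bool(raw.get("optional", False)),
        default=default,
        description=str(raw.get("description", "")),
    )


def _parse_dep(raw: dict, label: str) -> DependencySpec:
    for key in ("slot", "name", "type"):
        if key not in raw:
            raise DescriptorError(f"entry {label}: dependency missing mandatory key {key!r}")
    for key in raw:
        if key not in KNOWN_DEP_KEYS:
            log.warning("entry %s: ignoring unknown dependency key %r", label, key)
    try:
        shape = Shape(raw["type"])
    except ValueError:
        raise DescriptorError(
            f"entry {label}: unknown dependency shape {raw['type']!r}"
        ) from None
    in_types = tuple(str(t) for t in raw["in"]) if "in" in raw else None
    out_type = str(raw["out"]) if "out" in raw else None
    return DependencySpec(
        slot=str(raw["slot"]), name=str(raw["name"]), shape=shape,
        in_types=in_types, out_type=out_type,
    )


def parse_descriptor(yaml_text: str) -> list[OpInfo]:
    """Parse a YAML descriptor into a list of validated :class:`OpInfo`.

    Defaults are applied (priority 0.0, optional false); unknown keys are
    ignored with a logged warning.  Malformed YAML raises a
    :class:`DescriptorError` naming the line; a missing mandatory key raises a
    schema error naming the entry.
    """
    try:
        doc = yaml.safe_load(yaml_text)
    except yaml.YAMLError as e:
        mark = getattr(e, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise DescriptorError(f"malformed YAML{line}: {e}") from e
    if doc is None:
        return []
    if not isinstance(doc, dict) or "ops" not in doc:
        raise DescriptorError("descriptor must be a mapping with an 'ops' key")
    entries = doc["ops"] or []
    infos: list[OpInfo] = []
    for i, raw in enumerate(entries):
        if not isinstance(raw, dict):
            raise DescriptorError(f"entry #{i}: op entry is not a mapping")
        label = ",".join(raw.get("names", [])) or f"#{i}"
        for key in MANDATORY_KEYS:
            if key not in raw:
                raise DescriptorError(f"entry {label}: missing mandatory key {key!r}")
        for key in raw:
            if key not in KNOWN_OP_KEYS:
                log.warning("entry %s: ignoring unknown key %r", label, key)
        names = raw["names"]
        if isinstance(names, str):
            names = [names]
        try:
            shape = Shape(raw["type"])
        except ValueError:
            raise DescriptorError(f"entry {label}: unknown op type {raw['type']!r}") from None
        info = OpInfo(
            names=tuple(str(n) for n in names),
            shape=shape,
            parameters=tuple(_parse_param(p, label) for p in raw["parameters"] or []),
            source=str(raw["source"]),
            priority=float(raw.get("priority", 0.0)),
            description=str(raw.get("description", "")),
            dependencies=tuple(_parse_dep(d, label) for d in raw.get("dependencies", []) or []),
        )
        validate_op_info(info)
        infos.append(info)
    return infos


def _emit_param(p: ParameterSpec) -> dict:
    out: dict = {"name": p.name, "type": p.type_name, "io": p.io_role.value}
    if p.io_role is IORole.INPUT:
        out["optional"] = p.optional
    if p.default is not NO_DEFAULT:
        out["default"] = p.default
    if p.description:
        out["description"] = p.description
    return out


def _emit_dep(d: DependencySpec) -> dict:
    out: dict = {"slot": d.slot, "name": d.name, "type": d.shape.value}
    if d.in_types is not None:
        out["in"] = list(d.in_types)
    if d.out_type is not None:
        out["out"] = d.out_type
    return out


def emit_descriptor(infos: list[OpInfo], version: str = "1") -> str:
    """Emit a YAML descriptor with deterministic key ordering.

    The output re-parses (via :func:`parse_descriptor`) to an equal OpInfo
    list.  Reduced signatures are an in-memory artifact and are not emitted;
    pass unreduced infos.
    """
    entries = []
    for info in infos:
        validate_op_info(info)
        entry: dict = {
            "names": list(info.names),
            "type": info.shape.value,
            "priority": info.priority,
            "source": info.source,
            "description": info.description,
            "parameters": [_emit_param(p) for p in info.parameters],
            "dependencies": [_emit_dep(d) for d in info.dependencies],
        }
        entries.append(entry)
    return yaml.safe_dump({"version": version, "ops": entries}, sort_keys=False)


# ---------------------------------------------------------------------------
# Optional-parameter reduction
# ---------------------------------------------------------------------------

def reduce_optional(info: OpInfo) -> list[OpInfo]:
    """Expand an op into itself plus its reduced signatures.

    Optional INPUT parameters forming a contiguous trailing block (ignoring
    the declared OUTPUT) are dropped one by one from right to left; each
    reduction records ``reduced_from`` and inherits the parent's priority.
    An optional parameter followed by a required one is legal to declare but
    never droppable (logged).  A droppable optional parameter must declare a
    default; otherwise a :class:`ValidationError` is raised.
    """
    validate_op_info(info)
    call_params = info.input_params()
    input_idx = [i for i, p in enumerate(call_params) if p.io_role is IORole.INPUT]
    trailing: list[int] = []
    for i in reversed(input_idx):
        if call_params[i].optional:
            trailing.append(i)
        else:
            break
    stranded = [
        call_params[i].name
        for i in input_idx
        if call_params[i].optional and i not in trailing
    ]
    if stranded:
        log.info(
            "op %s: optional parameter(s) %s are not in the trailing block and "
            "will never be dropped", info.name, ", ".join(stranded),
        )
    for i in trailing:
        if call_params[i].default is NO_DEFAULT:
            raise ValidationError(
                f"op {info.name}: optional parameter {call_params[i].name!r} "
                "declares no default and cannot be reduced"
            )
    result = [info]
    dropped: set[str] = set()
    for i in trailing:  # rightmost first
        dropped.add(call_params[i].name)
        params = tuple(
            p for p in info.parameters
            if not (p.io_role is IORole.INPUT and p.name in dropped)
        )
        result.append(replace(info, parameters=params, reduced_from=info))
    return result
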