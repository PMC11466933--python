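"""Zero-code op registration: scan source docstrings for op annotations.

A callable becomes an op when its docstring contains an ``@implNote op`` line;
parameter types and io roles are read from structured doc lines.  Grammar::

    @implNote op names="<n1>[,<n2>...]" type=<function|computer|inplace> [priority=<real>]
    @param <name> (<type>) [optional[=<default>]] <description>
    @container <name> (<type>) <description>
    @mutable <name> (<type>) <description>
    @return (<type>) <description>

Callables without the tag are ignored.  The emitted descriptor's ``source``
field records ``module-path:callable-name``.  Indexing is idempotent: the
same sources always yield identical YAML text.
"""

from __future__ import annotations

import ast
import logging
import re
from collections.abc import Mapping, Sequence

import yaml

from .errors import IndexingError
from .model import (
    NO_DEFAULT, IORole, OpInfo, ParameterSpec, Shape, emit_descriptor,
    validate_op_info,
)

log = logging.getLogger(__name__)

_IMPLNOTE_RE = re.compile(
    r'@implNote\s+op\s+names="(?P<names>[^"]+)"\s+type=(?P<type>\w+)'
    r'(?:\s+priority=(?P<priority>-?\d+(?:\.\d+)?))?'
)
_PARAM_RE = re.compile(
    r'@(?P<role>param|container|mutable)\s+(?P<name>\w+)\s+\((?P<type>[\w.\-]+)\)'
    r'(?:\s+optional(?:=(?P<default>\S+))?)?'
    r'\s*(?P<desc>.*)'
)
_RETURN_RE = re.compile(r'@return\s+\((?P<type>[\w.\-]+)\)\s*(?P<desc>.*)')

_ROLE_MAP = {
    "param": IORole.INPUT,
    "container": IORole.CONTAINER,
    "mutable": IORole.MUTABLE,
}


def _parse_default(text: str):
    return yaml.safe_load(text)


def _info_from_docstring(doc: str, source: str, callable_name: str) -> OpInfo | None:
    m = _IMPLNOTE_RE.search(doc)
    if m is None:
        if "@implNote" in doc:
            raise IndexingError(
                f"{callable_name}: @implNote tag present but unparseable"
            )
        return None
    try:
        shape = Shape(m.group("type"))
    except ValueError:
        raise IndexingError(
            f"{callable_name}: unknown op type {m.group('type')!r} in @implNote"
        ) from None
    names = tuple(n.strip() for n in m.group("names").split(",") if n.strip())
    priority = float(m.group("priority") or 0.0)
    params: list[ParameterSpec] = []
    description_lines: list[str] = []
    for line in doc.splitlines():
        line = line.strip()
        pm = _PARAM_RE.search(line)
        if pm:
            default = NO_DEFAULT
            optional = "optional" in line.split("(", 1)[1]
            # only the explicit grammar token counts, not the description text
            optional = bool(re.search(r'\)\s+optional(=|\s|$)', line))
            if pm.group("default") is not None:
                default = _parse_default(pm.group("default"))
            params.append(ParameterSpec(
                name=pm.group("name"),
                type_name=pm.group("type"),
                io_role=_ROLE_MAP[pm.group("role")],
                optional=optional,
                default=default,
                description=pm.group("desc").strip(),
            ))
            continue
        rm = _RETURN_RE.search(line)
        if rm:
            params.append(ParameterSpec(
                name="out", type_name=rm.group("type"),
                io_role=IORole.OUTPUT, description=rm.group("desc").strip(),
            ))
            continue
        if not line.startswith("@") and line:
            description_lines.append(line)
    info = OpInfo(
        names=names, shape=shape, parameters=tuple(params), source=source,
        priority=priority, description=" ".join(description_lines).strip(),
    )
    try:
        validate_op_info(info)
    except Exception as e:
        raise IndexingError(f"{callable_name}: invalid op annotation: {e}") from e
    return info


def scan_source(module_path: str, text: str) -> list[OpInfo]:
    """Extract annotated ops from one source text."""
    try:
        tree = ast.parse(text)
    except SyntaxError as e:
        raise IndexingError(f"{module_path}: source does not parse: {e}") from e
    infos: list[OpInfo] = []
    for node in ast.walk(tree):
        if not isinstance(node, (ast.FunctionDef, ast.AsyncFunctionDef)):
            continue
        doc = ast.get_docstring(node)
        if not doc:
            continue
        info = _info_from_docstring(doc, f"{module_path}:{node.name}", node.name)
        if info is not None:
            infos.append(info)
    return infos


def index_annotations(sources: Mapping[str, str] | Sequence[str] | str) -> str:
    """Scan annotated source texts and emit a YAML descriptor.

    ``sources`` may be a mapping of module path to source text, a sequence of
    source texts (module paths default to ``source_<i>``), or a single text.
    Duplicate op names across one scan are kept (priority breaks ties at
    match time) with a logged warning.
    """
    if isinstance(sources, str):
        sources = [sources]
    if isinstance(sources, Mapping):
        items = list(sources.items())
    else:
        items = [(f"source_{i}", text) for i, text in enumerate(sources)]
    infos: list[OpInfo] = []
    for module_path, text in items:
        infos.extend(scan_source(module_path, text))
    seen: dict[tuple, str] = {}
    for info in infos:
        key = (info.names, info.shape, tuple(p.type_name for p in info.parameters))
        if key in seen:
            log.warning(
                "duplicate op %s in %s and %s; both kept (priority breaks ties)",
                info.name, seen[key], info.source,
            )
        seen[key] = info.source
    return emit_descriptor(infos)
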