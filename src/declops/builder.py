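"""Fluent request builder, help/introspection, and execution plumbing.

Typical use::

    env = default_environment()
    out  = env.op("filter.gauss").input(img, 2.0).apply()          # function
    env.op("filter.gauss").input(img, 2.0).output(buf).compute()   # computer
    env.op("benchmark.increment").input(buf).mutate()              # inplace
    add  = env.op("math.add").input_types("integer", "integer").function()

``apply()`` allocates and returns a new value, ``compute()`` overwrites the
supplied container, ``mutate()`` transforms the flagged argument in place;
``function()``/``computer()``/``inplace()`` return the matched executable
without running it.  Argument types are resolved from staged values through
the type registry's recognizers; every execution that wrote an output
appends one record to the environment's OpHistory (creations included, so
provenance is total).
"""

from __future__ import annotations

import difflib

from .engine import OpEnvironment, OpRequest, request_key
from .errors import OpExecutionError, OpsError, ParameterError
from .history import OpHistory, HistoryRecord  # noqa: F401  (public surface)
from .model import IORole, Shape


class OpBuilder:
    def __init__(self, env: OpEnvironment, name: str) -> None:
        self._env = env
        self._name = name
        self._values: tuple | None = None
        self._types: tuple[str, ...] | None = None
        self._container = None
        self._out_type: str | None = None

    # -- staging ----------------------------------------------------------
    def input(self, *values) -> "OpBuilder":
        self._values = values
        return self

    def input_types(self, *type_names: str) -> "OpBuilder":
        self._types = tuple(type_names)
        return self

    def output(self, container) -> "OpBuilder":
        self._container = container
        return self

    def out_type(self, type_name: str) -> "OpBuilder":
        self._out_type = type_name
        return self

    # -- request assembly --------------------------------------------------
    def _input_types(self) -> tuple[str, ...]:
        if self._types is not None:
            return self._types
        if self._values is None:
            raise ParameterError(
                f"request for {self._name!r}: no arguments or argument types staged"
            )
        reg = self._env.registry
        return tuple(reg.resolve_value(v) for v in self._values)

    def _request(self, shape: Shape, mutable_index: int | None = None) -> OpRequest:
        container_type = None
        if shape is Shape.COMPUTER:
            if self._container is None:
                raise ParameterError(
                    f"computer request for {self._name!r} needs .output(container)"
                )
            container_type = self._env.registry.resolve_value(self._container)
        return OpRequest(
            name=self._name, shape=shape, in_types=self._input_types(),
            out_type=self._out_type, container_type=container_type,
            mutable_index=mutable_index,
        )

    def _executable(self, request: OpRequest):
        tree = self._env.match_cached(request)
        return tree, self._env.instantiate(tree)

    def _invoke(self, fn, args, tree):
        try:
            return fn(*args)
        except OpsError:
            raise
        except Exception as e:
            raise OpExecutionError(
                f"op implementation failed (tree digest {tree.digest()}): {e}",
                digest=tree.digest(),
            ) from e

    # -- executing terminals -----------------------------------------------
    def apply(self):
        """Match a function op, run it, and return the fresh output."""
        if self._values is None:
            raise ParameterError("apply() needs staged argument values")
        request = self._request(Shape.FUNCTION)
        tree, fn = self._executable(request)
        out = self._invoke(fn, self._values, tree)
        self._env.history.record(request_key(request), tree.digest(), id(out))
        return out

    def compute(self):
        """Match a computer op, overwrite the supplied container, return it."""
        if self._values is None:
            raise ParameterError("compute() needs staged argument values")
        request = self._request(Shape.COMPUTER)
        tree, fn = self._executable(request)
        self._invoke(fn, (*self._values, self._container), tree)
        self._env.history.record(request_key(request), tree.digest(),
                                 id(self._container))
        return self._container

    def mutate(self, index: int = 0) -> None:
        """Match an inplace op and overwrite the argument at ``index``."""
        if self._values is None:
            raise ParameterError("mutate() needs staged argument values")
        request = self._request(Shape.INPLACE, mutable_index=index)
        tree, fn = self._executable(request)
        self._invoke(fn, self._values, tree)
        self._env.history.record(request_key(request), tree.digest(),
                                 id(self._values[index]))

    # -- matching terminals (no execution) -----------------------------------
    def function(self):
        return self._executable(self._request(Shape.FUNCTION))[1]

    def computer(self, container_type: str | None = None):
        if container_type is not None:
            request = OpRequest(self._name, Shape.COMPUTER, self._input_types(),
                                container_type=container_type)
        else:
            request = self._request(Shape.COMPUTER)
        return self._executable(request)[1]

    def inplace(self, index: int = 0):
        return self._executable(self._request(Shape.INPLACE, mutable_index=index))[1]


# ---------------------------------------------------------------------------
# Introspection
# ---------------------------------------------------------------------------

def describe_type(env: OpEnvironment, type_name: str) -> str:
    """Simple name for a type via the highest-priority engine.describe op;
    falls back to the raw type name (total — never raises)."""
    best = None
    for op in env.ops:
        if not any(n == "engine.describe" or n.startswith("engine.describe.")
                   for n in op.names):
            continue
        if op.shape is not Shape.FUNCTION:
            continue
        ins = [p for p in op.input_params() if p.io_role is IORole.INPUT]
        if len(ins) != 1 or ins[0].type_name != type_name:
            continue
        if best is None or (-op.priority, op.source) < (-best.priority, best.source):
            best = op
    if best is None:
        return type_name
    try:
        return str(env._resolve(best.source)(type_name))
    except Exception:
        return type_name


def _signature_line(env: OpEnvironment, op) -> str:
    params = ", ".join(
        f"{p.name}: {describe_type(env, p.type_name)}" for p in op.input_params()
    )
    if op.shape is Shape.FUNCTION:
        result = op.output_param().type_name
    elif op.shape is Shape.COMPUTER:
        result = op.input_params()[op.container_index()].type_name
    else:
        result = op.input_params()[op.mutable_index()].type_name
    return f"{op.name}({params}) -> {describe_type(env, result)}"


def help_text(env: OpEnvironment, query: str, verbose: bool = False) -> str:
    """Describe registered ops matching a query.

    A category prefix (e.g. ``math``) lists all op names under it, sorted; a
    full op name lists each implementation's signature (one per line, rank
    order then lexicographic); ``verbose`` adds per-parameter descriptions.
    """
    exact = [op for op in env.ops if query in op.names]
    if exact:
        exact.sort(key=lambda o: (-o.priority, o.source,
                                  -len(o.input_params()),
                                  _signature_line(env, o)))
        lines = []
        for op in exact:
            lines.append(_signature_line(env, op))
            if verbose:
                if op.description:
                    lines.append(f"    {op.description}")
                for p in op.input_params():
                    opt = " (optional)" if p.optional else ""
                    desc = f" — {p.description}" if p.description else ""
                    lines.append(
                        f"    {p.name}: {describe_type(env, p.type_name)}{opt}{desc}"
                    )
        return "\n".join(lines)
    all_names = sorted({n for op in env.ops for n in op.names})
    under = [n for n in all_names if n.startswith(query + ".")]
    if under:
        return "\n".join(under)
    near = difflib.get_close_matches(query, all_names, n=3)
    suffix = f"; nearest: {', '.join(near)}" if near else ""
    return f"no ops found for {query!r}{suffix}"
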