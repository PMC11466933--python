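"""The op environment and its deterministic matching engine.

A request names an op, its argument types and a functional shape; the engine
resolves it through four routines attempted in a fixed order:

1. **direct** — an op with a matching name, shape, and assignable types;
2. **adaptation** — a single ``engine.adapt`` op bridges a shape (or
   element-wise lifts a scalar op to images);
3. **conversion** — single-hop ``engine.convert`` ops bridge mismatched
   parameter types, with copy-back (via ``engine.copy``) for converted
   containers and mutables;
4. **adaptation + conversion** combined.

The first routine producing at least one candidate wins; within a routine,
candidates are ranked by priority (higher first), then fewer wrapper ops,
then lexicographically by canonical source locator — so matching is a pure
function of the request, independent of registration order.  Dependencies of
the winner are resolved recursively (depth cap 100; the resolution stack may
not revisit the same (op, shape) pair).  The result is an :class:`InfoTree`
recording the root op, wrappers, and dependency subtrees — the full
provenance of the match.
"""

from __future__ import annotations

import difflib
import functools
import hashlib
import importlib
import itertools
import logging
from dataclasses import dataclass, field

from .errors import (
    DependencyCycleError, OpMatchError, ResolutionDepthError, TypeLookupError,
)
from .model import (
    IORole, OpInfo, Shape, parse_descriptor, reduce_optional,
)
from .typesys import TypeRegistry

log = logging.getLogger(__name__)

DEPTH_LIMIT = 100
ROUTINES = ("direct", "adaptation", "conversion", "adaptation+conversion")


@dataclass(frozen=True)
class OpRequest:
    """A declarative query: name, argument/output type names, functional shape.

    ``in_types`` lists the user's argument types in call order; for a computer
    request the container is carried separately in ``container_type`` (the
    builder appends it last).  ``in_types=None`` is a wildcard used for
    dependency requests that pin only name and shape.  ``out_type=None``
    matches any candidate output.
    """

    name: str
    shape: Shape
    in_types: tuple[str, ...] | None = None
    out_type: str | None = None
    container_type: str | None = None
    mutable_index: int | None = None


def request_key(request: OpRequest) -> str:
    """Canonical cache key: ``name|shape|in=t1,t2,...|out=t``.

    For computer requests the container type is appended last to ``in=`` and
    repeated as ``out=``; for inplace requests the mutable type carries a
    ``~`` prefix.  ``*`` marks wildcards.
    """
    if request.in_types is None:
        ins = "*"
        out = request.out_type or "*"
    else:
        marked = list(request.in_types)
        if request.mutable_index is not None:
            marked[request.mutable_index] = "~" + marked[request.mutable_index]
        if request.container_type is not None:
            marked.append(request.container_type)
            out = request.container_type
        elif request.mutable_index is not None:
            out = request.in_types[request.mutable_index]
        else:
            out = request.out_type or "*"
        ins = ",".join(marked)
    return f"{request.name}|{request.shape.value}|in={ins}|out={out}"


@dataclass(frozen=True)
class Sig:
    """User-facing signature of a (possibly adapted) op."""

    in_types: tuple[str, ...]
    container_type: str | None
    mutable_index: int | None
    out_type: str


def op_sig(op: OpInfo) -> Sig:
    call = op.input_params()
    if op.shape is Shape.FUNCTION:
        return Sig(tuple(p.type_name for p in call), None, None,
                   op.output_param().type_name)
    if op.shape is Shape.COMPUTER:
        ins = tuple(p.type_name for p in call if p.io_role is not IORole.CONTAINER)
        ct = call[op.container_index()].type_name
        return Sig(ins, ct, None, ct)
    ins = tuple(p.type_name for p in call)
    m = op.mutable_index()
    return Sig(ins, None, m, ins[m])


@dataclass
class AdaptationEntry:
    adapter: OpInfo
    helpers: dict  # slot -> InfoTree
    meta: dict


@dataclass
class _ConvNeed:
    forward: OpInfo
    back: OpInfo | None = None
    copy_tree: "InfoTree | None" = None


@dataclass
class Candidate:
    root: OpInfo
    routine: str
    sig: Sig
    adaptation: AdaptationEntry | None = None
    conversions: dict = field(default_factory=dict)  # pos|'container'|'mutable'|'out' -> _ConvNeed

    def wrapper_count(self) -> int:
        return (1 if self.adaptation else 0) + len(self.conversions)


def _candidate_sort_key(c: Candidate):
    conv_sources = tuple(
        (str(k), c.conversions[k].forward.source,
         c.conversions[k].back.source if c.conversions[k].back else "")
        for k in sorted(c.conversions, key=str)
    )
    return (
        -c.root.priority,
        c.wrapper_count(),
        c.root.source,
        tuple(p.type_name for p in c.root.parameters),
        c.adaptation.adapter.source if c.adaptation else "",
        conv_sources,
    )


def rank_candidates(candidates: list[Candidate]) -> list[Candidate]:
    """Total deterministic order: higher priority, fewer wrappers, then
    lexicographic canonical source locators.  Registration-order independent."""
    return sorted(candidates, key=_candidate_sort_key)


class InfoTree:
    """The resolved match: root op plus adaptation/conversion wrappers and
    recursively resolved dependency subtrees.  Serializable to a canonical
    text form; two trees are equal iff their canonical forms are equal."""

    def __init__(self, root: OpInfo, shape: Shape,
                 adaptation: AdaptationEntry | None = None,
                 conversions: dict | None = None,
                 dependencies: dict | None = None,
                 meta: dict | None = None) -> None:
        self.root = root
        self.shape = shape
        self.adaptation = adaptation
        self.conversions = conversions or {}
        self.dependencies = dependencies or {}
        self.meta = meta or {}

    def canonical(self) -> str:
        parts = [
            f"root={self.root.source}"
            f"[{self.root.name}/{self.root.shape.value}"
            f"({','.join(p.type_name for p in self.root.parameters)})]"
        ]
        if self.adaptation is not None:
            helpers = ",".join(
                f"{k}={t.canonical()}" for k, t in sorted(self.adaptation.helpers.items())
            )
            parts.append(f"adapt={self.adaptation.adapter.source}{{{helpers}}}")
        for key in sorted(self.conversions, key=str):
            e = self.conversions[key]
            bits = [e["forward"].canonical()]
            if e.get("back") is not None:
                bits.append("back=" + e["back"].canonical())
            if e.get("copy") is not None:
                bits.append("copy=" + e["copy"].canonical())
            parts.append(f"conv[{key}]={'/'.join(bits)}")
        for slot in sorted(self.dependencies):
            parts.append(f"dep[{slot}]={self.dependencies[slot].canonical()}")
        return "{" + " ".join(parts) + "}"

    def digest(self) -> str:
        return hashlib.sha1(self.canonical().encode()).hexdigest()[:16]

    def count_nodes(self, op_name: str) -> int:
        """Number of nodes in the tree (root + dependencies) named ``op_name``."""
        n = 1 if op_name in self.root.names else 0
        return n + sum(t.count_nodes(op_name) for t in self.dependencies.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, InfoTree) and self.canonical() == other.canonical()

    def __repr__(self) -> str:
        return f"InfoTree({self.canonical()})"


# ---------------------------------------------------------------------------
# Adapter rules: which shapes an engine.adapt op bridges and the adapted
# signature it presents.  The runtime wrapping callable is the adapter op's
# ``source``; an adapter participates only while its op is registered.
# ---------------------------------------------------------------------------

def _rule_computer_to_function(env, adapter, op, request):
    if op.shape is not Shape.COMPUTER or request.shape is not Shape.FUNCTION:
        return None
    s = op_sig(op)
    ref = next((i for i, t in enumerate(s.in_types) if t == s.container_type), None)
    if ref is None:
        return None
    create = env._direct_tree(OpRequest(
        "engine.create", Shape.FUNCTION, (s.container_type,), s.container_type))
    if create is None:
        return None
    entry = AdaptationEntry(adapter, {"create": create}, {"ref_index": ref})
    return entry, Sig(s.in_types, None, None, s.container_type)


def _rule_function_to_computer(env, adapter, op, request):
    if op.shape is not Shape.FUNCTION or request.shape is not Shape.COMPUTER:
        return None
    s = op_sig(op)
    copy = env._copy_tree(s.out_type)
    if copy is None:
        return None
    entry = AdaptationEntry(adapter, {"copy": copy}, {})
    return entry, Sig(s.in_types, s.out_type, None, s.out_type)


def _rule_inplace_to_computer(env, adapter, op, request):
    if op.shape is not Shape.INPLACE or request.shape is not Shape.COMPUTER:
        return None
    s = op_sig(op)
    t = s.in_types[s.mutable_index]
    copy = env._copy_tree(t)
    if copy is None:
        return None
    entry = AdaptationEntry(adapter, {"copy": copy}, {"mutable_index": s.mutable_index})
    return entry, Sig(s.in_types, t, None, t)


def _rule_computer_to_inplace(env, adapter, op, request):
    if op.shape is not Shape.COMPUTER or request.shape is not Shape.INPLACE:
        return None
    s = op_sig(op)
    j = next((i for i, t in enumerate(s.in_types) if t == s.container_type), None)
    if j is None:
        return None
    create = env._direct_tree(OpRequest(
        "engine.create", Shape.FUNCTION, (s.container_type,), s.container_type))
    copy = env._copy_tree(s.container_type)
    if create is None or copy is None:
        return None
    entry = AdaptationEntry(adapter, {"create": create, "copy": copy},
                            {"mutable_index": j})
    return entry, Sig(s.in_types, None, j, s.container_type)


def _rule_inplace_to_function(env, adapter, op, request):
    if op.shape is not Shape.INPLACE or request.shape is not Shape.FUNCTION:
        return None
    s = op_sig(op)
    t = s.in_types[s.mutable_index]
    create = env._direct_tree(OpRequest(
        "engine.create", Shape.FUNCTION, (t,), t))
    copy = env._copy_tree(t)
    if create is None or copy is None:
        return None
    entry = AdaptationEntry(adapter, {"create": create, "copy": copy},
                            {"mutable_index": s.mutable_index})
    return entry, Sig(s.in_types, None, None, t)


def _rule_lift_elementwise(env, adapter, op, request):
    if op.shape is not Shape.FUNCTION or request.shape is not Shape.FUNCTION:
        return None
    if request.in_types is None:
        return None
    s = op_sig(op)
    arity = len(s.in_types)
    if arity not in (1, 2) or arity != len(request.in_types):
        return None
    reg = env.registry
    if "number" not in reg or "dense-image" not in reg:
        return None
    try:
        scalar = all(reg.assignable(t, "number") for t in s.in_types) and \
            reg.assignable(s.out_type, "number")
    except TypeLookupError:
        return None
    if not scalar:
        return None
    entry = AdaptationEntry(adapter, {}, {"arity": arity})
    return entry, Sig(("dense-image",) * arity, None, None, "dense-image")


ADAPTER_RULES = {
    "engine.adapt.computer_to_function": _rule_computer_to_function,
    "engine.adapt.function_to_computer": _rule_function_to_computer,
    "engine.adapt.inplace_to_computer": _rule_inplace_to_computer,
    "engine.adapt.computer_to_inplace": _rule_computer_to_inplace,
    "engine.adapt.inplace_to_function": _rule_inplace_to_function,
    "engine.adapt.lift_elementwise": _rule_lift_elementwise,
}


def assignable(registry: TypeRegistry, from_type: str, to_type: str) -> bool:
    """True iff ``from_type`` equals or is a (transitive) subtype of ``to_type``."""
    return registry.assignable(from_type, to_type)


class OpEnvironment:
    """The collection of registered ops plus the engine operating over them."""

    def __init__(self, registry: TypeRegistry | None = None,
                 cache_enabled: bool = True) -> None:
        self.registry = registry if registry is not None else TypeRegistry()
        self.cache_enabled = cache_enabled
        self.generation = 0
        self._ops: list[OpInfo] = []
        self._impls: dict[str, object] = {}
        self._cache: dict[str, InfoTree] = {}
        from .history import OpHistory  # local import avoids a module cycle
        self.history = OpHistory()

    # -- registration -----------------------------------------------------
    def register(self, *infos: OpInfo, implementations: dict | None = None) -> None:
        """Register ops (reduced signatures are materialized eagerly).

        ``implementations`` optionally maps source locators to callables,
        overriding import-based resolution — handy for ad-hoc ops.
        """
        expanded: list[OpInfo] = []
        for info in infos:
            expanded.extend(reduce_optional(info))
        self._ops.extend(expanded)
        if implementations:
            self._impls.update(implementations)
        self._bump()

    def register_yaml(self, yaml_text: str) -> None:
        self.register(*parse_descriptor(yaml_text))

    def unregister(self, info: OpInfo) -> None:
        self._ops = [o for o in self._ops if o != info and o.reduced_from != info]
        self._bump()

    def _bump(self) -> None:
        self.generation += 1
        self._cache.clear()

    @property
    def ops(self) -> tuple[OpInfo, ...]:
        return tuple(self._ops)

    # -- matching ---------------------------------------------------------
    def match(self, request: OpRequest, _stack: tuple = (), _depth: int = 0) -> InfoTree:
        if _depth > DEPTH_LIMIT:
            raise ResolutionDepthError(
                f"dependency resolution exceeded depth {DEPTH_LIMIT} "
                f"while resolving {request_key(request)}"
            )
        self._check_request_types(request)
        named = [op for op in self._ops if request.name in op.names]
        base = [(op, None, op_sig(op)) for op in named if op.shape is request.shape]
        adapted = []
        for adapter in self._adapter_ops():
            rule = ADAPTER_RULES[adapter.name]
            for op in named:
                res = rule(self, adapter, op, request)
                if res is not None:
                    entry, sig = res
                    adapted.append((op, entry, sig))

        routine_candidates = (
            ("direct", lambda: self._exact_candidates(base, request, "direct")),
            ("adaptation", lambda: self._exact_candidates(adapted, request, "adaptation")),
            ("conversion", lambda: self._converted_candidates(base, request, "conversion")),
            ("adaptation+conversion",
             lambda: self._converted_candidates(adapted, request, "adaptation+conversion")),
        )
        for routine, produce in routine_candidates:
            cands = produce()
            if cands:
                best = rank_candidates(cands)[0]
                log.debug("request %s matched via %s routine -> %s",
                          request_key(request), routine, best.root.source)
                return self._build_tree(best, request, _stack, _depth)
        raise OpMatchError(self._near_miss_report(request, named, base, adapted))

    def match_cached(self, request: OpRequest) -> InfoTree:
        """As :meth:`match`, served from the cache on repeated identical
        requests; any environment mutation invalidates all entries."""
        if not self.cache_enabled:
            return self.match(request)
        key = request_key(request)
        tree = self._cache.get(key)
        if tree is None:
            tree = self.match(request)
            self._cache[key] = tree
        return tree

    # -- candidate production ---------------------------------------------
    def _adapter_ops(self) -> list[OpInfo]:
        return [op for op in self._ops if op.name in ADAPTER_RULES]

    def _check_request_types(self, request: OpRequest) -> None:
        names = list(request.in_types or ())
        names += [t for t in (request.out_type, request.container_type) if t]
        for t in names:
            if t not in self.registry:
                raise TypeLookupError(f"request uses unregistered type {t!r}")

    def _sig_fits_exactly(self, sig: Sig, request: OpRequest) -> bool:
        if request.in_types is None:
            return True
        reg = self.registry
        try:
            if len(sig.in_types) != len(request.in_types):
                return False
            if request.shape is Shape.COMPUTER:
                if sig.container_type is None or not reg.assignable(
                        request.container_type, sig.container_type):
                    return False
            if request.shape is Shape.INPLACE:
                if request.mutable_index is not None and \
                        sig.mutable_index != request.mutable_index:
                    return False
            for ut, pt in zip(request.in_types, sig.in_types):
                if not reg.assignable(ut, pt):
                    return False
            if request.shape is Shape.FUNCTION and request.out_type is not None:
                if not reg.assignable(sig.out_type, request.out_type):
                    return False
        except TypeLookupError:
            return False
        return True

    def _exact_candidates(self, variants, request, routine) -> list[Candidate]:
        out = []
        for op, entry, sig in variants:
            if self._sig_fits_exactly(sig, request):
                out.append(Candidate(root=op, routine=routine, sig=sig,
                                     adaptation=entry))
        return out

    def _converter_options(self, from_type: str, to_type: str) -> list[OpInfo]:
        reg = self.registry
        opts = []
        for op in self._ops:
            if op.shape is not Shape.FUNCTION:
                continue
            if not any(n.startswith("engine.convert") for n in op.names):
                continue
            s = op_sig(op)
            if len(s.in_types) != 1:
                continue
            try:
                if reg.assignable(from_type, s.in_types[0]) and \
                        reg.assignable(s.out_type, to_type):
                    opts.append(op)
            except TypeLookupError:
                continue
        return sorted(opts, key=lambda o: (-o.priority, o.source))

    def _copy_tree(self, type_name: str) -> InfoTree | None:
        return self._direct_tree(OpRequest(
            "engine.copy", Shape.COMPUTER, (type_name,), container_type=type_name))

    def _converted_candidates(self, variants, request, routine) -> list[Candidate]:
        if request.in_types is None:
            return []
        reg = self.registry
        out: list[Candidate] = []
        for op, entry, sig in variants:
            if len(sig.in_types) != len(request.in_types):
                continue
            if request.shape is Shape.INPLACE and request.mutable_index is not None \
                    and sig.mutable_index != request.mutable_index:
                continue
            needs: dict = {}
            feasible = True
            try:
                for i, (ut, pt) in enumerate(zip(request.in_types, sig.in_types)):
                    if sig.mutable_index is not None and i == sig.mutable_index:
                        continue
                    if reg.assignable(ut, pt):
                        continue
                    opts = self._converter_options(ut, pt)
                    if not opts:
                        feasible = False
                        break
                    needs[i] = [_ConvNeed(forward=o) for o in opts]
                if feasible and sig.mutable_index is not None:
                    m = sig.mutable_index
                    ut, pt = request.in_types[m], sig.in_types[m]
                    if not reg.assignable(ut, pt):
                        needs["mutable"] = self._copyback_options(ut, pt)
                        feasible = bool(needs["mutable"])
                if feasible and request.shape is Shape.COMPUTER:
                    ut, pt = request.container_type, sig.container_type
                    if not reg.assignable(ut, pt):
                        needs["container"] = self._copyback_options(ut, pt)
                        feasible = bool(needs["container"])
                if feasible and request.shape is Shape.FUNCTION \
                        and request.out_type is not None \
                        and not reg.assignable(sig.out_type, request.out_type):
                    opts = self._converter_options(sig.out_type, request.out_type)
                    if not opts:
                        feasible = False
                    else:
                        needs["out"] = [_ConvNeed(forward=o) for o in opts]
            except TypeLookupError:
                feasible = False
            if not feasible or not needs:
                continue
            keys = sorted(needs, key=str)
            for combo in itertools.product(*(needs[k] for k in keys)):
                out.append(Candidate(
                    root=op, routine=routine, sig=sig, adaptation=entry,
                    conversions=dict(zip(keys, combo)),
                ))
        return out

    def _copyback_options(self, user_type: str, op_type: str) -> list[_ConvNeed]:
        """Conversion entries for a written-to argument: forward converter,
        best-ranked back converter, and an engine.copy op for the user's type."""
        forwards = self._converter_options(user_type, op_type)
        backs = self._converter_options(op_type, user_type)
        copy = self._copy_tree(user_type)
        if not forwards or not backs or copy is None:
            return []
        return [_ConvNeed(forward=f, back=backs[0], copy_tree=copy) for f in forwards]

    def _direct_tree(self, request: OpRequest) -> InfoTree | None:
        named = [op for op in self._ops
                 if request.name in op.names and op.shape is request.shape]
        cands = self._exact_candidates(
            [(op, None, op_sig(op)) for op in named], request, "direct")
        if not cands:
            return None
        return self._build_tree(rank_candidates(cands)[0], request, (), 0)

    # -- tree construction -------------------------------------------------
    def _dep_request(self, dep) -> OpRequest:
        if dep.shape is Shape.COMPUTER:
            return OpRequest(dep.name, dep.shape, dep.in_types,
                             container_type=dep.out_type)
        if dep.shape is Shape.INPLACE:
            mi = 0 if dep.in_types is not None else None
            return OpRequest(dep.name, dep.shape, dep.in_types, mutable_index=mi)
        return OpRequest(dep.name, dep.shape, dep.in_types, out_type=dep.out_type)

    def _plain_tree(self, op: OpInfo, shape: Shape, stack, depth) -> InfoTree:
        cand = Candidate(root=op, routine="direct", sig=op_sig(op))
        return self._build_tree(cand, OpRequest(op.name, shape), stack, depth)

    def _build_tree(self, cand: Candidate, request: OpRequest,
                    stack: tuple, depth: int) -> InfoTree:
        key = (cand.root.source, cand.root.shape.value, cand.root.names)
        if key in stack:
            chain = " -> ".join(f"{k[2][0]}({k[0]})" for k in stack + (key,))
            raise DependencyCycleError(f"dependency cycle: {chain}")
        stack = stack + (key,)
        deps = {}
        for dep in cand.root.dependencies:
            deps[dep.slot] = self.match(self._dep_request(dep), stack, depth + 1)
        conversions = {}
        for k, need in cand.conversions.items():
            entry = {"forward": self._plain_tree(need.forward, Shape.FUNCTION,
                                                 stack, depth + 1)}
            if need.back is not None:
                entry["back"] = self._plain_tree(need.back, Shape.FUNCTION,
                                                 stack, depth + 1)
            if need.copy_tree is not None:
                entry["copy"] = need.copy_tree
            conversions[k] = entry
        meta = {"mutable_index": cand.sig.mutable_index}
        return InfoTree(cand.root, request.shape, cand.adaptation,
                        conversions, deps, meta)

    # -- diagnostics -------------------------------------------------------
    def _near_miss_report(self, request, named, base, adapted) -> str:
        lines = [f"no op matched request {request_key(request)}"]
        if not named:
            all_names = sorted({n for op in self._ops for n in op.names})
            near = difflib.get_close_matches(request.name, all_names, n=3)
            lines.append(f"  no registered op is named {request.name!r}"
                         + (f"; nearest: {', '.join(near)}" if near else ""))
            return "\n".join(lines)
        shapes = sorted({op.shape.value for op in named})
        lines.append(f"  direct: {len(base)} op(s) named {request.name!r} with "
                     f"shape {request.shape.value} but incompatible types "
                     f"(registered shapes: {', '.join(shapes)})")
        for op, _, sig in base:
            lines.append(f"    - {op.source} expects in={','.join(sig.in_types)}")
        lines.append(f"  adaptation: {len(adapted)} adapted variant(s), none type-compatible")
        lines.append("  conversion: no single-hop converter chain bridges the mismatch")
        lines.append("  adaptation+conversion: no combination found")
        return "\n".join(lines)

    # -- instantiation -----------------------------------------------------
    def _resolve(self, source: str):
        if source in self._impls:
            return self._impls[source]
        module, _, attr = source.partition(":")
        obj = importlib.import_module(module)
        for part in attr.split("."):
            obj = getattr(obj, part)
        return obj

    def instantiate(self, tree: InfoTree):
        """Turn an :class:`InfoTree` into an executable callable.

        Conventions: function executables take inputs in declared order and
        return the output; computer executables take ``(*inputs, container)``
        with the container last; inplace executables take all arguments in
        declared order with the mutable at its declared index.
        """
        fn = self._resolve(tree.root.source)
        deps = {slot: self.instantiate(sub) for slot, sub in tree.dependencies.items()}
        if deps:
            fn = functools.partial(fn, **deps)
        if tree.root.reduced_from is not None:
            fn = _inject_defaults(fn, tree.root)
        if tree.root.shape is Shape.COMPUTER:
            ci = tree.root.container_index()
            n = len(tree.root.input_params())
            if ci != n - 1:
                fn = _container_last(fn, ci)
        if tree.adaptation is not None:
            adapter_impl = self._resolve(tree.adaptation.adapter.source)
            helpers = {k: self.instantiate(t)
                       for k, t in tree.adaptation.helpers.items()}
            fn = adapter_impl(fn, helpers, dict(tree.adaptation.meta))
        if tree.conversions:
            fn = self._wrap_conversions(fn, tree)
        return fn

    def _wrap_conversions(self, fn, tree: InfoTree):
        convs = {
            k: {kk: self.instantiate(t) for kk, t in entry.items()}
            for k, entry in tree.conversions.items()
        }

        def convert_inputs(ins):
            return [convs[i]["forward"](x) if i in convs else x
                    for i, x in enumerate(ins)]

        if tree.shape is Shape.FUNCTION:
            def wrapped(*ins):
                r = fn(*convert_inputs(ins))
                if "out" in convs:
                    r = convs["out"]["forward"](r)
                return r
        elif tree.shape is Shape.COMPUTER:
            def wrapped(*args):
                *ins, cont = args
                ins = convert_inputs(ins)
                if "container" in convs:
                    e = convs["container"]
                    c2 = e["forward"](cont)
                    fn(*ins, c2)
                    e["copy"](e["back"](c2), cont)
                else:
                    fn(*ins, cont)
        else:
            m = tree.meta.get("mutable_index")

            def wrapped(*args):
                args = list(args)
                for i in range(len(args)):
                    if i != m and i in convs:
                        args[i] = convs[i]["forward"](args[i])
                if "mutable" in convs:
                    e = convs["mutable"]
                    orig = args[m]
                    args[m] = e["forward"](orig)
                    fn(*args)
                    e["copy"](e["back"](args[m]), orig)
                else:
                    fn(*args)
        return wrapped

    # -- convenience -------------------------------------------------------
    def op(self, name: str):
        from .builder import OpBuilder
        return OpBuilder(self, name)

    def help(self, query: str, verbose: bool = False) -> str:
        from .builder import help_text
        return help_text(self, query, verbose=verbose)

    def describe(self, type_name: str) -> str:
        from .builder import describe_type
        return describe_type(self, type_name)


def _inject_defaults(fn, info: OpInfo):
    """Wrap a reduced op so the declared defaults fill the dropped parameters."""
    parent = info.reduced_from
    reduced_names = [p.name for p in info.input_params()]
    parent_params = parent.input_params()

    def wrapper(*args):
        by_name = dict(zip(reduced_names, args))
        full = [by_name[p.name] if p.name in by_name else p.default
                for p in parent_params]
        return fn(*full)
    return wrapper


def _container_last(fn, container_index: int):
    """Normalize a computer whose container is not the final parameter."""
    def wrapper(*args):
        args = list(args)
        cont = args.pop()
        args.insert(container_index, cont)
        return fn(*args)
    return wrapper


def match(env: OpEnvironment, request: OpRequest) -> InfoTree:
    return env.match(request)


def match_cached(env: OpEnvironment, request: OpRequest) -> InfoTree:
    return env.match_cached(request)
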