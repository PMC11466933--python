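"""Independent oracles used by the test suite.

Everything here is deliberately written from scratch against the documented
contracts — straightforward enumeration and loops, no reuse of the engine's
candidate machinery — so agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from declops.model import (
    IORole, OpInfo, ParameterSpec, Shape,
)
from declops.typesys import TypeRegistry

# ---------------------------------------------------------------------------
# Brute-force matcher oracle
# ---------------------------------------------------------------------------

ADAPTER_NAMES = (
    "engine.adapt.computer_to_function",
    "engine.adapt.function_to_computer",
)


def _closure(type_names, edges):
    g = nx.DiGraph()
    g.add_nodes_from(type_names)
    g.add_edges_from(edges)  # child -> parent
    return set(nx.transitive_closure(g, reflexive=True).edges())


def _flat_sig(op):
    """(in_types, container_type, mutable_index, out_type) read off the params."""
    call = [p for p in op.parameters if p.io_role is not IORole.OUTPUT]
    if op.shape is Shape.FUNCTION:
        out = next(p.type_name for p in op.parameters if p.io_role is IORole.OUTPUT)
        return tuple(p.type_name for p in call), None, None, out
    if op.shape is Shape.COMPUTER:
        ins = tuple(p.type_name for p in call if p.io_role is not IORole.CONTAINER)
        ct = next(p.type_name for p in call if p.io_role is IORole.CONTAINER)
        return ins, ct, None, ct
    ins = tuple(p.type_name for p in call)
    m = next(i for i, p in enumerate(call) if p.io_role is IORole.MUTABLE)
    return ins, None, m, ins[m]


class BruteForceMatcher:
    """Exhaustive enumerator over ops x single adapters x single-hop converters.

    Works on dependency-free environments; produces a summary tuple
    (root source, root param types, adapter name, conversions) for the winner,
    or None when nothing matches.
    """

    def __init__(self, ops, type_names, edges):
        self.ops = list(ops)
        self.tc = _closure(type_names, edges)

    def assignable(self, a, b):
        return (a, b) in self.tc

    def _converters(self, frm, to):
        opts = []
        for op in self.ops:
            if op.shape is not Shape.FUNCTION:
                continue
            if not any(n.startswith("engine.convert") for n in op.names):
                continue
            ins, _, _, out = _flat_sig(op)
            if len(ins) != 1:
                continue
            if self.assignable(frm, ins[0]) and self.assignable(out, to):
                opts.append(op)
        return sorted(opts, key=lambda o: (-o.priority, o.source))

    def _helper_exists(self, name, shape, type_name):
        for op in self.ops:
            if name not in op.names or op.shape is not shape:
                continue
            ins, ct, _, out = _flat_sig(op)
            if shape is Shape.FUNCTION:
                if len(ins) == 1 and self.assignable(type_name, ins[0]) \
                        and self.assignable(out, type_name):
                    return True
            else:  # computer copy: one input + container
                if len(ins) == 1 and self.assignable(type_name, ins[0]) \
                        and self.assignable(type_name, ct):
                    return True
        return False

    def _variants(self, request):
        """(op, adapter_name, sig) triples: unadapted plus each adapter form."""
        named = [op for op in self.ops if request["name"] in op.names]
        adapters = [op.names[0] for op in self.ops if op.names[0] in ADAPTER_NAMES]
        out = []
        for op in named:
            if op.shape is request["shape"]:
                out.append((op, None, _flat_sig(op)))
            if "engine.adapt.computer_to_function" in adapters \
                    and op.shape is Shape.COMPUTER \
                    and request["shape"] is Shape.FUNCTION:
                ins, ct, _, _ = _flat_sig(op)
                if any(t == ct for t in ins) and \
                        self._helper_exists("engine.create", Shape.FUNCTION, ct):
                    out.append((op, "engine.adapt.computer_to_function",
                                (ins, None, None, ct)))
            if "engine.adapt.function_to_computer" in adapters \
                    and op.shape is Shape.FUNCTION \
                    and request["shape"] is Shape.COMPUTER:
                ins, _, _, fo = _flat_sig(op)
                if self._helper_exists("engine.copy", Shape.COMPUTER, fo):
                    out.append((op, "engine.adapt.function_to_computer",
                                (ins, fo, None, fo)))
        return out

    def _fits(self, sig, request):
        ins, ct, m, out = sig
        if len(ins) != len(request["in"]):
            return False
        if request["shape"] is Shape.COMPUTER and \
                not self.assignable(request["container"], ct):
            return False
        if request["shape"] is Shape.INPLACE and m != request["mutable"]:
            return False
        for ut, pt in zip(request["in"], ins):
            if not self.assignable(ut, pt):
                return False
        if request["shape"] is Shape.FUNCTION and request.get("out") and \
                not self.assignable(out, request["out"]):
            return False
        return True

    def _converted(self, op, adapter, sig, request):
        ins, ct, m, out = sig
        if len(ins) != len(request["in"]):
            return []
        if request["shape"] is Shape.INPLACE and m != request["mutable"]:
            return []
        needs = {}
        for i, (ut, pt) in enumerate(zip(request["in"], ins)):
            if m is not None and i == m:
                continue
            if self.assignable(ut, pt):
                continue
            if i == m:
                continue
            opts = self._converters(ut, pt)
            if not opts:
                return []
            needs[i] = [(o, None) for o in opts]
        if m is not None and not self.assignable(request["in"][m], ins[m]):
            entry = self._copyback(request["in"][m], ins[m])
            if not entry:
                return []
            needs["mutable"] = entry
        if request["shape"] is Shape.COMPUTER and \
                not self.assignable(request["container"], ct):
            entry = self._copyback(request["container"], ct)
            if not entry:
                return []
            needs["container"] = entry
        if request["shape"] is Shape.FUNCTION and request.get("out") and \
                not self.assignable(out, request["out"]):
            opts = self._converters(out, request["out"])
            if not opts:
                return []
            needs["out"] = [(o, None) for o in opts]
        if not needs:
            return []
        keys = sorted(needs, key=str)
        combos = []
        for combo in itertools.product(*(needs[k] for k in keys)):
            combos.append((op, adapter, dict(zip(keys, combo))))
        return combos

    def _copyback(self, user_type, op_type):
        forwards = self._converters(user_type, op_type)
        backs = self._converters(op_type, user_type)
        copy_ok = self._helper_exists("engine.copy", Shape.COMPUTER, user_type)
        if not forwards or not backs or not copy_ok:
            return []
        return [(f, backs[0]) for f in forwards]

    @staticmethod
    def _rank_key(cand, adapter_sources):
        op, adapter, convs = cand
        conv_key = tuple(
            (str(k), convs[k][0].source, convs[k][1].source if convs[k][1] else "")
            for k in sorted(convs, key=str)
        )
        return (-op.priority, (1 if adapter else 0) + len(convs),
                op.source, tuple(p.type_name for p in op.parameters),
                adapter_sources.get(adapter, ""), conv_key)

    def match(self, request):
        """Summary of the winner or None: (source, param-types, adapter, convs)."""
        adapter_sources = {
            op.names[0]: op.source for op in self.ops if op.names[0] in ADAPTER_NAMES
        }
        variants = self._variants(request)
        routines = [
            [(op, a, {}) for op, a, sig in variants if a is None
             and self._fits(sig, request)],
            [(op, a, {}) for op, a, sig in variants if a is not None
             and self._fits(sig, request)],
            [c for op, a, sig in variants if a is None
             for c in self._converted(op, a, sig, request)],
            [c for op, a, sig in variants if a is not None
             for c in self._converted(op, a, sig, request)],
        ]
        for cands in routines:
            if cands:
                op, adapter, convs = min(
                    cands, key=lambda c: self._rank_key(c, adapter_sources))
                return summarize(op, adapter, convs)
        return None


def summarize(op, adapter, convs):
    conv_summary = tuple(
        (str(k), convs[k][0].source, convs[k][1].source if convs[k][1] else "")
        for k in sorted(convs, key=str)
    )
    return (op.source, tuple(p.type_name for p in op.parameters),
            adapter, conv_summary)


def summarize_tree(tree):
    """The same summary extracted from an engine InfoTree."""
    convs = tuple(
        (str(k),
         tree.conversions[k]["forward"].root.source,
         tree.conversions[k]["back"].root.source
         if tree.conversions[k].get("back") else "")
        for k in sorted(tree.conversions, key=str)
    )
    adapter = tree.adaptation.adapter.names[0] if tree.adaptation else None
    return (tree.root.source,
            tuple(p.type_name for p in tree.root.parameters), adapter, convs)


# ---------------------------------------------------------------------------
# Random environment generator for matcher stress tests
# ---------------------------------------------------------------------------

OP_NAME_POOL = ("alg.a", "alg.b", "alg.c")


def _param(name, type_name, role=IORole.INPUT):
    return ParameterSpec(name=name, type_name=type_name, io_role=role)


def random_environment(rng: np.random.Generator):
    """A random type DAG plus <=10 dependency-free ops (plain ops, converters,
    create/copy helpers, adapters).  Returns (op_infos, type_names, edges)."""
    n_types = int(rng.integers(3, 7))
    type_names = [f"T{i}" for i in range(n_types)]
    edges = []
    for j in range(1, n_types):
        for i in range(j):
            if rng.random() < 0.3:
                edges.append((type_names[j], type_names[i]))  # Tj is-a Ti
    ops = []
    counter = itertools.count()

    def t():
        return type_names[int(rng.integers(n_types))]

    n_plain = int(rng.integers(3, 7))
    for _ in range(n_plain):
        name = OP_NAME_POOL[int(rng.integers(len(OP_NAME_POOL)))]
        shape = [Shape.FUNCTION, Shape.COMPUTER, Shape.INPLACE][int(rng.integers(3))]
        arity = int(rng.integers(1, 3))
        i = next(counter)
        if shape is Shape.FUNCTION:
            params = [_param(f"p{k}", t()) for k in range(arity)]
            params.append(_param("out", t(), IORole.OUTPUT))
        elif shape is Shape.COMPUTER:
            params = [_param(f"p{k}", t()) for k in range(arity)]
            params.append(_param("cont", t(), IORole.CONTAINER))
        else:
            params = [_param("mut", t(), IORole.MUTABLE)]
            params += [_param(f"p{k}", t()) for k in range(arity - 1)]
        ops.append(OpInfo(
            names=(name,), shape=shape, parameters=tuple(params),
            source=f"dummy:f{i}",
            priority=float(rng.choice([0.0, 0.0, 1.0, 10.0])),
        ))
    for _ in range(int(rng.integers(0, 4))):
        i = next(counter)
        ops.append(OpInfo(
            names=(f"engine.convert.c{i}",), shape=Shape.FUNCTION,
            parameters=(_param("x", t()), _param("out", t(), IORole.OUTPUT)),
            source=f"dummy:f{i}",
        ))
    for _ in range(int(rng.integers(0, 3))):
        i, ct = next(counter), t()
        ops.append(OpInfo(
            names=("engine.create.like", "engine.create"), shape=Shape.FUNCTION,
            parameters=(_param("ref", ct), _param("out", ct, IORole.OUTPUT)),
            source=f"dummy:f{i}",
        ))
    for _ in range(int(rng.integers(0, 3))):
        i, ct = next(counter), t()
        ops.append(OpInfo(
            names=("engine.copy",), shape=Shape.COMPUTER,
            parameters=(_param("src", ct), _param("tgt", ct, IORole.CONTAINER)),
            source=f"dummy:f{i}",
        ))
    for adapter_name in ADAPTER_NAMES:
        if rng.random() < 0.5:
            i = next(counter)
            ops.append(OpInfo(
                names=(adapter_name,), shape=Shape.FUNCTION,
                parameters=(_param("op", "T0"), _param("out", "T0", IORole.OUTPUT)),
                source=f"dummy:f{i}",
            ))
    return ops, type_names, edges


def random_request(rng: np.random.Generator, type_names):
    shape = [Shape.FUNCTION, Shape.COMPUTER, Shape.INPLACE][int(rng.integers(3))]
    arity = int(rng.integers(1, 3))

    def t():
        return type_names[int(rng.integers(len(type_names)))]

    req = {
        "name": OP_NAME_POOL[int(rng.integers(len(OP_NAME_POOL)))],
        "shape": shape,
        "in": tuple(t() for _ in range(arity)),
        "out": None,
        "container": None,
        "mutable": None,
    }
    if shape is Shape.COMPUTER:
        req["container"] = t()
    if shape is Shape.INPLACE:
        req["in"] = (t(),)
        req["mutable"] = 0
    if shape is Shape.FUNCTION and rng.random() < 0.5:
        req["out"] = t()
    return req


def registry_from(type_names, edges) -> TypeRegistry:
    reg = TypeRegistry()
    parents = {}
    for child, parent in edges:
        parents.setdefault(child, []).append(parent)
    for name in type_names:  # T-indices ascend so parents are always registered
        reg.register(name, parents=parents.get(name, []))
    return reg


# ---------------------------------------------------------------------------
# Numeric oracles
# ---------------------------------------------------------------------------

def dense_gauss_2d(values: np.ndarray, sigma: float) -> np.ndarray:
    """Non-separable 2-D Gaussian convolution with mirrored borders."""
    r = math.ceil(4.0 * sigma)
    x = np.arange(-r, r + 1, dtype=np.float64)
    k1 = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    padded = np.pad(values.astype(np.float64), r, mode="reflect")
    out = np.empty_like(values, dtype=np.float64)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            out[i, j] = float(np.sum(padded[i:i + 2 * r + 1, j:j + 2 * r + 1] * kernel))
    return out


def otsu_exhaustive(values: np.ndarray) -> int:
    """Lowest uint8 threshold t maximizing between-class variance of
    {v <= t} vs {v > t}, searched over all 255 candidates."""
    v = values.ravel().astype(np.float64)
    best_t, best_var = None, -1.0
    for t in range(255):
        c0 = v[v <= t]
        c1 = v[v > t]
        if c0.size == 0 or c1.size == 0:
            continue
        var = c0.size * c1.size * (c0.sum() / c0.size - c1.sum() / c1.size) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def histogram_loop(values: np.ndarray, bins: int, lo: float, hi: float):
    """Plain counting loop with floor assignment, last bin right-closed."""
    counts = [0] * bins
    width = (hi - lo) / bins
    for v in values.ravel():
        idx = int(math.floor((float(v) - lo) / width))
        if idx == bins:
            idx = bins - 1
        counts[idx] += 1
    return counts
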