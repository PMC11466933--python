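"""Semantic type registry: names, subtype edges, descriptions, recognizers.

Matching is purely name-based: every op parameter carries a type *name* and
assignability is the reflexive-transitive closure of declared subtype edges
(a DAG).  Each type may also carry a recognizer predicate so runtime values
staged in the builder can be resolved to a type name; the most specific
(deepest) recognizing type wins, and a tie at equal depth is an error rather
than a guess.
"""

from __future__ import annotations

from typing import Callable, Iterable

from .errors import AmbiguousTypeError, TypeLookupError


class TypeRegistry:
    def __init__(self) -> None:
        self._parents: dict[str, tuple[str, ...]] = {}
        self._descriptions: dict[str, str] = {}
        self._recognizers: dict[str, Callable[[object], bool]] = {}

    # -- registration -----------------------------------------------------
    def register(
        self,
        name: str,
        parents: Iterable[str] = (),
        description: str | None = None,
        recognizer: Callable[[object], bool] | None = None,
    ) -> None:
        parents = tuple(parents)
        for p in parents:
            if p not in self._parents:
                raise TypeLookupError(f"unknown parent type {p!r} for {name!r}")
            if name in self._parents and self._reaches(p, name):
                raise TypeLookupError(f"edge {name}->{p} would create a cycle")
        self._parents[name] = self._parents.get(name, ()) + parents
        if description is not None:
            self._descriptions[name] = description
        if recognizer is not None:
            self._recognizers[name] = recognizer

    def __contains__(self, name: str) -> bool:
        return name in self._parents

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(sorted(self._parents))

    # -- assignability ----------------------------------------------------
    def _reaches(self, frm: str, to: str) -> bool:
        seen = set()
        stack = [frm]
        while stack:
            t = stack.pop()
            if t == to:
                return True
            if t in seen:
                continue
            seen.add(t)
            stack.extend(self._parents.get(t, ()))
        return False

    def assignable(self, from_type: str, to_type: str) -> bool:
        """True iff a value of ``from_type`` is acceptable where ``to_type`` is required."""
        for t in (from_type, to_type):
            if t not in self._parents:
                raise TypeLookupError(f"type {t!r} is not registered")
        return self._reaches(from_type, to_type)

    def depth(self, name: str) -> int:
        """Length of the longest parent chain above ``name`` (roots have depth 0)."""
        if name not in self._parents:
            raise TypeLookupError(f"type {name!r} is not registered")
        parents = self._parents[name]
        if not parents:
            return 0
        return 1 + max(self.depth(p) for p in parents)

    # -- runtime value resolution -----------------------------------------
    def resolve_value(self, value: object) -> str:
        """Resolve a runtime value to the most specific recognizing type name."""
        hits = [n for n, rec in self._recognizers.items() if rec(value)]
        if not hits:
            raise TypeLookupError(
                f"no registered type recognizes value of {type(value).__name__!r}"
            )
        best = max(self.depth(n) for n in hits)
        deepest = sorted(n for n in hits if self.depth(n) == best)
        if len(deepest) > 1:
            raise AmbiguousTypeError(
                f"value of {type(value).__name__!r} is recognized by "
                f"{deepest} at equal depth"
            )
        return deepest[0]

    def description(self, name: str) -> str:
        return self._descriptions.get(name, name)
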