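"""A small hash-consed reduced ordered BDD (ROBDD).

Variables are the integers ``0 .. n-1`` in fixed order (position i of the
Boolean vectors corresponds to the i-th transportable of the model).  The
manager supports the handful of operations the enumeration algorithm needs:
conjunction/disjunction, negation, cofactor restriction, and path tracing from
the root to the *true* terminal to recover implicants.
"""

from __future__ import annotations

from typing import Iterator

__all__ = ["BDDManager", "FALSE", "TRUE"]

FALSE = 0
TRUE = 1


class BDDManager:
    def __init__(self, n_vars: int) -> None:
        self.n_vars = n_vars
        # node id -> (var, lo, hi); terminals use var = n_vars as a sentinel.
        self._nodes: list[tuple[int, int, int]] = [
            (n_vars, FALSE, FALSE),
            (n_vars, TRUE, TRUE),
        ]
        self._unique: dict[tuple[int, int, int], int] = {}
        self._ite_cache: dict[tuple[int, int, int], int] = {}
        self._restrict_cache: dict[tuple[int, int, int], int] = {}

    def _mk(self, var: int, lo: int, hi: int) -> int:
        if lo == hi:
            return lo
        key = (var, lo, hi)
        node = self._unique.get(key)
        if node is None:
            node = len(self._nodes)
            self._nodes.append(key)
            self._unique[key] = node
        return node

    def var(self, i: int) -> int:
        if not 0 <= i < self.n_vars:
            raise IndexError(f"variable index {i} out of range")
        return self._mk(i, FALSE, TRUE)

    def top_var(self, f: int) -> int:
        return self._nodes[f][0]

    def ite(self, f: int, g: int, h: int) -> int:
        """Canonical if-then-else: f ? g : h."""
        if f == TRUE:
            return g
        if f == FALSE:
            return h
        if g == h:
            return g
        if g == TRUE and h == FALSE:
            return f
        key = (f, g, h)
        cached = self._ite_cache.get(key)
        if cached is not None:
            return cached
        v = min(self.top_var(x) for x in (f, g, h) if x > TRUE)

        def cof(x: int, val: int) -> int:
            var, lo, hi = self._nodes[x]
            if x <= TRUE or var != v:
                return x
            return hi if val else lo

        lo = self.ite(cof(f, 0), cof(g, 0), cof(h, 0))
        hi = self.ite(cof(f, 1), cof(g, 1), cof(h, 1))
        result = self._mk(v, lo, hi)
        self._ite_cache[key] = result
        return result

    def apply_and(self, f: int, g: int) -> int:
        return self.ite(f, g, FALSE)

    def apply_or(self, f: int, g: int) -> int:
        return self.ite(f, TRUE, g)

    def negate(self, f: int) -> int:
        return self.ite(f, FALSE, TRUE)

    def restrict(self, f: int, var: int, value: bool) -> int:
        """Cofactor of f with the given variable fixed."""
        if f <= TRUE:
            return f
        v, lo, hi = self._nodes[f]
        if v > var:
            return f
        key = (f, var, int(value))
        cached = self._restrict_cache.get(key)
        if cached is not None:
            return cached
        if v == var:
            result = hi if value else lo
        else:
            result = self._mk(
                v,
                self.restrict(lo, var, value),
                self.restrict(hi, var, value),
            )
        self._restrict_cache[key] = result
        return result

    def evaluate(self, f: int, vector: tuple[bool, ...]) -> bool:
        node = f
        while node > TRUE:
            v, lo, hi = self._nodes[node]
            node = hi if vector[v] else lo
        return node == TRUE

    def iter_implicants(self, f: int) -> Iterator[tuple[bool, ...]]:
        """Yield all satisfying vectors by tracing root-to-*true* paths.

        Depth-first, false-branch first.  Variables skipped along a path are
        expanded to both values with false preferred, so the iteration order
        is deterministic and does not depend on BDD node sharing.
        """
        n = self.n_vars

        def walk(node: int, depth: int, prefix: list[bool]) -> Iterator[tuple[bool, ...]]:
            if node == FALSE:
                return
            if node == TRUE:
                if depth == n:
                    yield tuple(prefix)
                else:
                    for value in (False, True):
                        prefix.append(value)
                        yield from walk(TRUE, depth + 1, prefix)
                        prefix.pop()
                return
            v, lo, hi = self._nodes[node]
            if depth < v:  # don't-care variable on this path
                for value in (False, True):
                    prefix.append(value)
                    yield from walk(node, depth + 1, prefix)
                    prefix.pop()
                return
            for value, child in ((False, lo), (True, hi)):
                prefix.append(value)
                yield from walk(child, depth + 1, prefix)
                prefix.pop()

        yield from walk(f, 0, [])

    def size(self, f: int) -> int:
        """Number of distinct internal nodes reachable from f."""
        seen: set[int] = set()
        stack = [f]
        while stack:
            node = stack.pop()
            if node <= TRUE or node in seen:
                continue
            seen.add(node)
            _, lo, hi = self._nodes[node]
            stack.extend((lo, hi))
        return len(seen)
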