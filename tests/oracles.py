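"""Independent oracles used by the test suite.

These are deliberately naive implementations kept separate from the package
so the tests compare two routes to the same answer.
"""

from __future__ import annotations

from functools import lru_cache


def osa_distance_oracle(x: str, y: str) -> int:
    """Restricted-transposition edit distance by memoized recursive enumeration.

    Enumerates edit scripts from the end of both strings (insert, delete,
    substitute, adjacent transposition), memoizing subproblems; structurally
    independent of the package's iterative rolling-row implementation.
    """

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        best = min(
            d(i - 1, j) + 1,  # delete from x
            d(i, j - 1) + 1,  # insert into x
            d(i - 1, j - 1) + (0 if x[i - 1] == y[j - 1] else 1),
        )
        if i > 1 and j > 1 and x[i - 1] == y[j - 2] and x[i - 2] == y[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(x), len(y))


def levenshtein_oracle(x: str, y: str) -> int:
    """Plain Levenshtein (no transpositions), as an outer bound check."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (0 if x[i - 1] == y[j - 1] else 1),
        )

    return d(len(x), len(y))


def bfs_closure_oracle(edges: set[tuple[str, str]], nodes: set[str]) -> set[tuple[str, str]]:
    """Transitive closure of (child, parent) edges by per-node BFS."""
    parents: dict[str, set[str]] = {n: set() for n in nodes}
    for child, parent in edges:
        parents[child].add(parent)
    closure: set[tuple[str, str]] = set()
    for start in nodes:
        frontier = [start]
        seen: set[str] = set()
        while frontier:
            node = frontier.pop()
            for p in parents[node]:
                if p not in seen:
                    seen.add(p)
                    closure.add((start, p))
                    frontier.append(p)
    return closure


def all_strings(alphabet: str, max_len: int) -> list[str]:
    """Every string over ``alphabet`` with length 0..max_len."""
    out = [""]
    layer = [""]
    for _ in range(max_len):
        layer = [s + ch for s in layer for ch in alphabet]
        out.extend(layer)
    return out
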