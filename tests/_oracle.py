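"""Independent oracles used to cross-check library results.

Deliberately naive implementations: the full-matrix dynamic-programming
edit distance here shares no code with taxonames.match.levenshtein (which
uses a two-row band with early abandon).
"""

from __future__ import annotations


def dp_levenshtein(a: str, b: str) -> int:
    """Quadratic full-matrix Levenshtein distance."""
    n, m = len(a), len(b)
    matrix = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        matrix[i][0] = i
    for j in range(m + 1):
        matrix[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            matrix[i][j] = min(
                matrix[i - 1][j] + 1,
                matrix[i][j - 1] + 1,
                matrix[i - 1][j - 1] + cost,
            )
    return matrix[n][m]


def brute_force_lca(store, a_id: int, b_id: int) -> int:
    """Last common element of the two root-ordered lineage id lists."""

    def root_path(tax_id: int) -> list[int]:
        path = [tax_id]
        while path[-1] != 1:
            path.append(store.nodes[path[-1]].parent_tax_id)
        return list(reversed(path))

    path_a, path_b = root_path(a_id), root_path(b_id)
    last = 1
    for x, y in zip(path_a, path_b):
        if x != y:
            break
        last = x
    return last
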