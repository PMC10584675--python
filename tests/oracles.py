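"""Independent reference implementations used only to cross-check results.

These are deliberately written in the most transparent way possible
(explicit loops, no shared code with the package) so they can serve as
oracles for the optimized implementations.
"""

from __future__ import annotations

import numpy as np


def gotoh_local_score(q_tdi: str, t_tdi: str, q_aa: str, t_aa: str,
                      tdi_mat: np.ndarray, aa_mat: np.ndarray,
                      w_tdi: float, w_aa: float,
                      gap_open: float, gap_extend: float,
                      alphabet: str) -> float:
    """Plain three-matrix local affine-gap DP; returns the best score."""
    idx = {c: i for i, c in enumerate(alphabet)}
    n, m = len(q_tdi), len(t_tdi)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = (w_tdi * tdi_mat[idx[q_tdi[i - 1]], idx[t_tdi[j - 1]]]
                 + w_aa * aa_mat[idx[q_aa[i - 1]], idx[t_aa[j - 1]]])
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def best_segment_score(scores: list[float]) -> float:
    """Brute force over all contiguous segments of a 1-D score vector."""
    best = 0.0
    for i in range(len(scores)):
        for j in range(i + 1, len(scores) + 1):
            best = max(best, sum(scores[i:j]))
    return best


def greedy_set_cover(ids: list[str], edges: list[tuple[str, str]]
                     ) -> dict[str, list[str]]:
    """Reference greedy set-cover clustering (same tie rules, new code)."""
    neighbours: dict[str, set[str]] = {i: set() for i in ids}
    for a, b in edges:
        if a != b:
            neighbours[a].add(b)
            neighbours[b].add(a)
    remaining = set(ids)
    result: dict[str, list[str]] = {}
    while remaining:
        scored = []
        for node in remaining:
            covered = {node} | (neighbours[node] & remaining)
            scored.append((len(covered), len(neighbours[node]), node, covered))
        scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
        _, _, rep, covered = scored[0]
        result[rep] = [rep] + sorted(covered - {rep})
        remaining -= covered
    return result


def lca_by_path_intersection(parent: dict[int, int], root: int,
                             taxids: list[int]) -> int | None:
    """LCA as the deepest node present on every root-path."""
    if not taxids:
        return None

    def path(t: int) -> list[int]:
        p = [t]
        while p[-1] != root:
            p.append(parent[p[-1]])
        return p  # leaf ... root

    paths = [path(t) for t in taxids]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    for node in paths[0]:
        if node in common:
            return node
    return None


def lddt_enumeration(cols: list[tuple[int, int]], qc: np.ndarray,
                     tc: np.ndarray, radius: float = 15.0,
                     thresholds=(0.5, 1.0, 2.0, 4.0)) -> float:
    """Direct enumeration of all aligned-column pairs and thresholds."""
    fracs = []
    for thr in thresholds:
        kept = hit = 0
        for x in range(len(cols)):
            for y in range(x + 1, len(cols)):
                dq = np.linalg.norm(qc[cols[x][0]] - qc[cols[y][0]])
                dt = np.linalg.norm(tc[cols[x][1]] - tc[cols[y][1]])
                if dq < radius:
                    kept += 1
                    if abs(dq - dt) < thr:
                        hit += 1
        fracs.append(hit / kept)
    return float(np.mean(fracs))
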