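"""Independent brute-force oracles used by the tests.

Everything here is written with plain Python loops against the textbook
definitions, deliberately sharing no code with the package implementation.
``L`` is an integer gray-level grid with 0 marking out-of-ROI voxels.
"""

from __future__ import annotations

import numpy as np

NEIGHBORS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def anova_mean_squares(m: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) via explicit elementwise sums."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = sum(m[i, j] for i in range(n) for j in range(k)) / (n * k)
    ss_rows = 0.0
    for i in range(n):
        rowmean = sum(m[i, j] for j in range(k)) / k
        ss_rows += k * (rowmean - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        colmean = sum(m[i, j] for i in range(n)) / n
        ss_cols += n * (colmean - grand) ** 2
    ss_total = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc3_bruteforce(m: np.ndarray) -> float:
    ms_r, _, ms_e = anova_mean_squares(m)
    k = np.asarray(m).shape[1]
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)


def _in(L: np.ndarray, p) -> bool:
    return all(0 <= c < s for c, s in zip(p, L.shape)) and L[tuple(p)] > 0


def glcm_count(L: np.ndarray, d: tuple[int, int, int], ng: int) -> np.ndarray:
    """Symmetric raw co-occurrence counts for one direction."""
    C = np.zeros((ng, ng))
    for z in range(L.shape[0]):
        for y in range(L.shape[1]):
            for x in range(L.shape[2]):
                if L[z, y, x] == 0:
                    continue
                q = (z + d[0], y + d[1], x + d[2])
                if _in(L, q):
                    C[L[z, y, x] - 1, L[q] - 1] += 1
                    C[L[q] - 1, L[z, y, x] - 1] += 1
    return C


def run_lengths(L: np.ndarray, d: tuple[int, int, int]) -> dict[tuple[int, int], int]:
    """{(level, run length): count} of maximal runs along direction d."""
    runs: dict[tuple[int, int], int] = {}
    for z in range(L.shape[0]):
        for y in range(L.shape[1]):
            for x in range(L.shape[2]):
                p = (z, y, x)
                if L[p] == 0:
                    continue
                prev = (z - d[0], y - d[1], x - d[2])
                if _in(L, prev) and L[prev] == L[p]:
                    continue  # not a run start
                length = 1
                q = (z + d[0], y + d[1], x + d[2])
                while _in(L, q) and L[q] == L[p]:
                    length += 1
                    q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
                key = (int(L[p]), length)
                runs[key] = runs.get(key, 0) + 1
    return runs


def size_zones(L: np.ndarray) -> dict[tuple[int, int], int]:
    """{(level, zone size): count} of 26-connected constant-level zones."""
    visited = np.zeros(L.shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for z in range(L.shape[0]):
        for y in range(L.shape[1]):
            for x in range(L.shape[2]):
                if L[z, y, x] == 0 or visited[z, y, x]:
                    continue
                lvl = int(L[z, y, x])
                stack = [(z, y, x)]
                visited[z, y, x] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in NEIGHBORS_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if _in(L, q) and not visited[q] and L[q] == lvl:
                            visited[q] = True
                            stack.append(q)
                key = (lvl, size)
                zones[key] = zones.get(key, 0) + 1
    return zones


def dependence_counts(L: np.ndarray) -> dict[tuple[int, int], int]:
    """{(level, 1 + #equal 26-neighbors): count} over in-ROI voxels."""
    deps: dict[tuple[int, int], int] = {}
    for z in range(L.shape[0]):
        for y in range(L.shape[1]):
            for x in range(L.shape[2]):
                if L[z, y, x] == 0:
                    continue
                dep = 1
                for d in NEIGHBORS_26:
                    q = (z + d[0], y + d[1], x + d[2])
                    if _in(L, q) and L[q] == L[z, y, x]:
                        dep += 1
                key = (int(L[z, y, x]), dep)
                deps[key] = deps.get(key, 0) + 1
    return deps


def ngtdm_table(L: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray, int]:
    """(n_i, s_i, Nvp) over in-ROI voxels with >= 1 in-ROI neighbor."""
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    nvp = 0
    for z in range(L.shape[0]):
        for y in range(L.shape[1]):
            for x in range(L.shape[2]):
                if L[z, y, x] == 0:
                    continue
                nbrs = []
                for d in NEIGHBORS_26:
                    q = (z + d[0], y + d[1], x + d[2])
                    if _in(L, q):
                        nbrs.append(L[q])
                if not nbrs:
                    continue
                nvp += 1
                lvl = int(L[z, y, x])
                n_i[lvl - 1] += 1
                s_i[lvl - 1] += abs(lvl - sum(nbrs) / len(nbrs))
    return n_i, s_i, nvp


def spearman_bruteforce(x, y) -> float:
    """Spearman rho via average ranks and Pearson on the ranks."""

    def ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) ** 0.5 * sum((b - my) ** 2 for b in ry) ** 0.5
    )
    return num / den
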