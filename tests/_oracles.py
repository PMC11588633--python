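"""Brute-force reference implementations of the texture-matrix constructions.

These enumerate voxel pairs, runs, zones and neighborhoods with plain Python
loops on tiny level maps; they are deliberately independent of the
vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np

ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def oracle_glcm(levels: np.ndarray, bin_count: int, angle: int, distance: int) -> np.ndarray:
    dy, dx = ANGLE_OFFSETS[angle]
    dy, dx = dy * distance, dx * distance
    nz, ny, nx = levels.shape
    raw = np.zeros((bin_count, bin_count), dtype=np.int64)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = levels[z, y, x]
                if a <= 0:
                    continue
                yy, xx = y + dy, x + dx
                if 0 <= yy < ny and 0 <= xx < nx:
                    b = levels[z, yy, xx]
                    if b > 0:
                        raw[a - 1, b - 1] += 1
    return raw + raw.T


def oracle_glrlm(levels: np.ndarray, bin_count: int, angle: int) -> np.ndarray:
    dy, dx = ANGLE_OFFSETS[angle]
    nz, ny, nx = levels.shape
    runs: list[tuple[int, int]] = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = levels[z, y, x]
                if v <= 0:
                    continue
                py, px = y - dy, x - dx
                if 0 <= py < ny and 0 <= px < nx and levels[z, py, px] == v:
                    continue  # not a run start
                length = 1
                yy, xx = y + dy, x + dx
                while 0 <= yy < ny and 0 <= xx < nx and levels[z, yy, xx] == v:
                    length += 1
                    yy += dy
                    xx += dx
                runs.append((int(v), length))
    max_len = max((l for _, l in runs), default=1)
    counts = np.zeros((bin_count, max_len), dtype=np.int64)
    for v, l in runs:
        counts[v - 1, l - 1] += 1
    return counts


def oracle_glszm(levels: np.ndarray, bin_count: int) -> np.ndarray:
    nz, ny, nx = levels.shape
    visited = np.zeros_like(levels, dtype=bool)
    zones: list[tuple[int, int]] = []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = levels[z, y, x]
                if v <= 0 or visited[z, y, x]:
                    continue
                stack = [(z, y, x)]
                visited[z, y, x] = True
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz, dy, dx in offsets:
                        zz, yy, xx = cz + dz, cy + dy, cx + dx
                        if (
                            0 <= zz < nz
                            and 0 <= yy < ny
                            and 0 <= xx < nx
                            and not visited[zz, yy, xx]
                            and levels[zz, yy, xx] == v
                        ):
                            visited[zz, yy, xx] = True
                            stack.append((zz, yy, xx))
                zones.append((int(v), size))
    max_size = max((s for _, s in zones), default=1)
    counts = np.zeros((bin_count, max_size), dtype=np.int64)
    for v, s in zones:
        counts[v - 1, s - 1] += 1
    return counts


def oracle_gldm(levels: np.ndarray, bin_count: int, kernel: int, alpha: int = 0) -> np.ndarray:
    nz, ny, nx = levels.shape
    entries: list[tuple[int, int]] = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = levels[z, y, x]
                if v <= 0:
                    continue
                dep = 0
                for dy in range(-kernel, kernel + 1):
                    for dx in range(-kernel, kernel + 1):
                        if (dy, dx) == (0, 0):
                            continue
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < ny and 0 <= xx < nx:
                            w = levels[z, yy, xx]
                            if w > 0 and abs(int(w) - int(v)) <= alpha:
                                dep += 1
                entries.append((int(v), dep))
    max_dep = max((d for _, d in entries), default=0)
    counts = np.zeros((bin_count, max_dep + 1), dtype=np.int64)
    for v, d in entries:
        counts[v - 1, d] += 1
    return counts


def oracle_ngtdm(levels: np.ndarray, bin_count: int, kernel: int):
    """Returns (occurring levels, p_i, s_i, n_valid)."""
    nz, ny, nx = levels.shape
    per_level: dict[int, list[float]] = {}
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = levels[z, y, x]
                if v <= 0:
                    continue
                nb = []
                for dy in range(-kernel, kernel + 1):
                    for dx in range(-kernel, kernel + 1):
                        if (dy, dx) == (0, 0):
                            continue
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < ny and 0 <= xx < nx and levels[z, yy, xx] > 0:
                            nb.append(float(levels[z, yy, xx]))
                if nb:
                    per_level.setdefault(int(v), []).append(abs(v - sum(nb) / len(nb)))
    occurring = sorted(per_level)
    n_valid = sum(len(v) for v in per_level.values())
    p = np.array([len(per_level[v]) / n_valid for v in occurring]) if n_valid else np.empty(0)
    s = np.array([sum(per_level[v]) for v in occurring])
    return np.array(occurring), p, s, n_valid
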