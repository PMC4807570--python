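"""Independent brute-force oracles used by the test suite.

Deliberately written as literal per-voxel Python loops, with no calls
into the package or into scipy morphology, so they constitute an
independent evaluation path for the mask-arithmetic protocol.
"""

from __future__ import annotations

import numpy as np


def brute_threshold(volume, lower, upper=None):
    nz, ny, nx = volume.shape
    out = np.zeros((nz, ny, nx), dtype=bool)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = volume[z, y, x]
                ok = v >= lower
                if upper is not None:
                    ok = ok and v <= upper
                out[z, y, x] = ok
    return out


def brute_dilate26(mask):
    """One dilation with the full 3x3x3 neighbourhood, clipped at borders."""
    nz, ny, nx = mask.shape
    out = np.zeros_like(mask)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                hit = False
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                                if mask[zz, yy, xx]:
                                    hit = True
                out[z, y, x] = hit
    return out


def brute_segment(above, below, sub, *, tA=3.8, tB=12.0, tC=3.0, tD=0.0,
                  tE=(3.0, 4.0), dilation_iterations=1, h_rule="table2",
                  use_threshold_E=False):
    """Literal step-by-step evaluation of the threshold/arithmetic table."""
    A = brute_threshold(above, tA)
    B = brute_threshold(above, tB)
    C = brute_threshold(sub, tC)
    negative = np.zeros_like(A)
    nz, ny, nx = sub.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                negative[z, y, x] = sub[z, y, x] < tD
    D = brute_dilate26(negative)
    E = brute_threshold(below, tE[0], tE[1])

    f = A & C & ~D
    g = f.copy()
    for _ in range(dilation_iterations):
        g = brute_dilate26(g)
    if h_rule == "table2":
        h = g & C
    else:
        h = g & ~C
    excl = B & C
    if use_threshold_E:
        excl = excl | (E & C)
    return h & ~excl


def flood_fill_components(mask):
    """26-connectivity component sizes via explicit BFS flood fill."""
    nz, ny, nx = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                queue = [(z, y, x)]
                seen[z, y, x] = True
                size = 0
                while queue:
                    cz, cy, cx = queue.pop()
                    size += 1
                    for dz in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                zz, yy, xx = cz + dz, cy + dy, cx + dx
                                if (
                                    0 <= zz < nz
                                    and 0 <= yy < ny
                                    and 0 <= xx < nx
                                    and mask[zz, yy, xx]
                                    and not seen[zz, yy, xx]
                                ):
                                    seen[zz, yy, xx] = True
                                    queue.append((zz, yy, xx))
                sizes.append(size)
    return sorted(sizes)
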