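"""Independent oracles shared by the test modules.

Everything here is deliberately written without reference to the package
internals it checks: brute-force enumeration, list-scan flooding, direct
pairwise arithmetic.
"""

from __future__ import annotations

import itertools

import numpy as np


def mann_whitney_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all C(n+m, n) labelings.

    U is computed by direct pairwise comparison for the first sample; the
    two-sided p doubles the smaller tail and caps at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_stat(sel):
        sel = set(sel)
        xs = pooled[sorted(sel)]
        ys = pooled[[i for i in range(len(pooled)) if i not in sel]]
        return float(sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys))

    u_obs = u_stat(range(n))
    us = np.array([u_stat(s) for s in itertools.combinations(range(len(pooled)), n)])
    lo = float((us <= u_obs).mean())
    hi = float((us >= u_obs).mean())
    return u_obs, min(1.0, 2 * min(lo, hi))


def priority_flood_oracle(data: np.ndarray, seeds, tau: float) -> np.ndarray:
    """Brute-force two-seed (or k-seed) best-first region growth.

    Frontier kept as a plain list scanned for the globally best voxel each
    step (highest intensity, earliest insertion on ties); seeds are inserted
    in lexicographic voxel order. Restricted to voxels >= tau, 26-connected.
    """
    shape = data.shape
    labels = np.zeros(shape, dtype=int)
    domain = data >= tau
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    frontier = []
    counter = 0
    for (z, y, x), k in sorted(seeds):
        if not domain[z, y, x] or labels[z, y, x]:
            continue
        labels[z, y, x] = k
        frontier.append((-float(data[z, y, x]), counter, (z, y, x), k))
        counter += 1
    while frontier:
        i_best = min(range(len(frontier)), key=lambda i: frontier[i][:2])
        _, _, (z, y, x), k = frontier.pop(i_best)
        for dz, dy, dx in offsets:
            nz, ny, nx = z + dz, y + dy, x + dx
            if not (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]):
                continue
            if labels[nz, ny, nx] or not domain[nz, ny, nx]:
                continue
            labels[nz, ny, nx] = k
            frontier.append((-float(data[nz, ny, nx]), counter, (nz, ny, nx), k))
            counter += 1
    return labels


def random_two_blob(seed: int):
    """A randomized <= 32^3 two-blob intensity field with its seed voxels."""
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in rng.integers(16, 33, 3))
    zz, yy, xx = np.indices(shape, dtype=float)
    c1 = rng.uniform(4, 9, 3)
    c2 = rng.uniform([s - 9 for s in shape], [s - 4 for s in shape], 3)
    width = rng.uniform(25, 60)
    img = (
        100 * np.exp(-((zz - c1[0]) ** 2 + (yy - c1[1]) ** 2 + (xx - c1[2]) ** 2) / width)
        + 100 * np.exp(-((zz - c2[0]) ** 2 + (yy - c2[1]) ** 2 + (xx - c2[2]) ** 2) / width)
        + rng.normal(0, 1.5, shape)
    )
    img = np.maximum(img, 0.0)
    seeds = [
        (tuple(int(v) for v in np.rint(c1)), 1),
        (tuple(int(v) for v in np.rint(c2)), 2),
    ]
    return img, np.array([c1, c2]), seeds


def digital_ball(radius_um: float, spacing_um: float):
    """Binary ball mask on an isotropic grid plus the analytic sphere values."""
    n = int(np.ceil(2 * (radius_um + 2) / spacing_um))
    coords = np.indices((n, n, n), dtype=float) * spacing_um
    center = n * spacing_um / 2
    d = np.sqrt(((coords - center) ** 2).sum(axis=0))
    mask = d <= radius_um
    vol = 4.0 / 3.0 * np.pi * radius_um**3
    area = 4.0 * np.pi * radius_um**2
    return mask, vol, area


def tube_mask(shape, spacing, p0, p1, radius):
    """Voxel-center rasterized capsule between two physical points."""
    coords = np.stack(np.indices(shape, dtype=float), axis=-1) * np.asarray(spacing)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    v = p1 - p0
    t = np.clip(((coords - p0) @ v) / (v @ v), 0.0, 1.0)
    d = np.linalg.norm(coords - (p0 + t[..., None] * v), axis=-1)
    return d <= radius
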