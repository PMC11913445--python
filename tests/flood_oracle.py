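"""Independent brute-force oracles used by the tests.

The flood-fill here is deliberately naive (python BFS over explicit
neighbour offsets) and shares no code with the package's labeling path.
"""

from collections import deque

import numpy as np


def neighbour_offsets(connectivity: int):
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def flood_fill_components(binary, connectivity):
    """Partition of the foreground into connected components, as a set of
    frozensets of (z, y, x) tuples, by breadth-first search."""
    binary = np.asarray(binary, dtype=bool)
    offs = neighbour_offsets(connectivity)
    shape = binary.shape
    visited = np.zeros(shape, dtype=bool)
    components = []
    for start in np.argwhere(binary):
        start = tuple(int(v) for v in start)
        if visited[start]:
            continue
        queue = deque([start])
        visited[start] = True
        comp = {start}
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offs:
                nz, ny, nx = z + dz, y + dy, x + dx
                if not (0 <= nz < shape[0] and 0 <= ny < shape[1]
                        and 0 <= nx < shape[2]):
                    continue
                if binary[nz, ny, nx] and not visited[nz, ny, nx]:
                    visited[nz, ny, nx] = True
                    comp.add((nz, ny, nx))
                    queue.append((nz, ny, nx))
        components.append(frozenset(comp))
    return set(components)


def label_partition(labels):
    """Partition induced by a label volume, in the same set-of-frozensets
    form, for exact comparison with the oracle."""
    labels = np.asarray(labels)
    out = {}
    for idx in np.argwhere(labels != 0):
        out.setdefault(int(labels[tuple(idx)]), set()).add(
            tuple(int(v) for v in idx))
    return {frozenset(v) for v in out.values()}


def voxel_index_for_point(coord, step, n):
    """Independent physical-coordinate -> voxel-index mapping by interval
    search (a coordinate exactly on an edge belongs to the higher voxel)."""
    k = 0
    while k + 1 < n and coord >= (k + 1) * step:
        k += 1
    return k
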