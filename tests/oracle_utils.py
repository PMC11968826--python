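"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration or
simulation, sharing no code path with the library implementations they
check.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

AXIAL_W = 0.948
DIAG_W = 1.340


def isodata_fixpoints(hist: np.ndarray) -> list[int]:
    """All thresholds t satisfying the iterative-intermeans fixpoint
    condition t == floor((mean_below + mean_above)/2), by scanning
    every candidate."""
    hist = np.asarray(hist, dtype=float)
    idx = np.arange(hist.size, dtype=float)
    nz = np.nonzero(hist)[0]
    out = []
    for t in range(int(nz[0]), int(nz[-1])):
        lo, hi = hist[: t + 1], hist[t + 1 :]
        if lo.sum() == 0 or hi.sum() == 0:
            continue
        m0 = (idx[: t + 1] * lo).sum() / lo.sum()
        m1 = (idx[t + 1 :] * hi).sum() / hi.sum()
        if int(math.floor((m0 + m1) / 2.0)) == t:
            out.append(t)
    return out


def convex_boundary_perimeter(mask: np.ndarray) -> float:
    """Independent boundary-walk perimeter: a counterclockwise
    left-hand-rule Moore trace starting from the bottom-most, right-most
    pixel, with step weights 0.948 axial / 1.340 diagonal. Written
    separately from the library's clockwise tracer; the closed walk has
    the same length either way round."""
    m = np.asarray(mask, bool)
    if m.sum() == 1:
        return 4 * AXIAL_W
    pad = np.pad(m, 1)
    rs, cs = np.nonzero(pad)
    # bottom-most then right-most foreground pixel
    k = np.lexsort((cs, rs))[-1]
    start = (int(rs[k]), int(cs[k]))
    # counterclockwise neighbor ring starting east
    ring = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
    cur = start
    incoming = 2  # pretend we arrived heading north -> look right of travel
    lengths = []
    visited_states: dict[tuple, int] = {}
    cycle_from = 0
    while True:
        state = (cur, incoming)
        if state in visited_states:
            cycle_from = visited_states[state]
            break
        visited_states[state] = len(lengths)
        # left-hand rule: scan CCW starting just past the backtrack
        back = (incoming + 4) % 8
        step = None
        for j in range(1, 9):
            d = (back + j) % 8
            nr, nc = cur[0] + ring[d][0], cur[1] + ring[d][1]
            if pad[nr, nc]:
                step = d
                cur = (nr, nc)
                break
        if step is None:
            break
        lengths.append(AXIAL_W if step % 2 == 0 else DIAG_W)
        incoming = step
    # sum only the closed cycle, dropping any non-cyclic lead-in
    return float(sum(lengths[cycle_from:]))


def label_components_bfs(mask: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """8-connected component labeling by explicit BFS; returns the label
    raster and per-component pixel counts."""
    m = np.asarray(mask, bool)
    lab = np.zeros(m.shape, dtype=int)
    areas = []
    nxt = 0
    for r0 in range(m.shape[0]):
        for c0 in range(m.shape[1]):
            if not m[r0, c0] or lab[r0, c0]:
                continue
            nxt += 1
            q = deque([(r0, c0)])
            lab[r0, c0] = nxt
            area = 0
            while q:
                r, c = q.popleft()
                area += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < m.shape[0]
                            and 0 <= cc < m.shape[1]
                            and m[rr, cc]
                            and not lab[rr, cc]
                        ):
                            lab[rr, cc] = nxt
                            q.append((rr, cc))
            areas.append(area)
    return lab, areas


def _component_containing(mask: np.ndarray, seed_rc: tuple[int, int]) -> np.ndarray:
    lab, _ = label_components_bfs(mask)
    return lab == lab[seed_rc]


def _regional_maxima(img: np.ndarray) -> list[list[tuple[int, int]]]:
    """Plateau components that are regional maxima (8-connectivity)."""
    H, W = img.shape
    visited = np.zeros(img.shape, bool)
    maxima = []
    for r0 in range(H):
        for c0 in range(W):
            if visited[r0, c0]:
                continue
            v = img[r0, c0]
            plateau = []
            q = deque([(r0, c0)])
            visited[r0, c0] = True
            is_max = True
            while q:
                r, c = q.popleft()
                plateau.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < H and 0 <= cc < W):
                            continue
                        if img[rr, cc] == v and not visited[rr, cc]:
                            visited[rr, cc] = True
                            q.append((rr, cc))
                        elif img[rr, cc] > v:
                            is_max = False
            if is_max:
                maxima.append(plateau)
    return maxima


def _dynamics(img: np.ndarray, plateau: list[tuple[int, int]]) -> float:
    """Dynamics of a regional maximum by brute force over flood levels:
    peak height minus the highest level at which the maximum's
    superlevel component reaches a strictly higher pixel (infinite for
    global maxima)."""
    v = img[plateau[0]]
    levels = sorted({float(x) for x in img.ravel() if x <= v}, reverse=True)
    for lvl in levels:
        comp = _component_containing(img >= lvl, plateau[0])
        if (img[comp] > v).any():
            return float(v - lvl)
    return math.inf


def flood_simulation_oracle(
    img: np.ndarray,
    seed_dynamics: float,
    intensity_threshold: float,
    peak_flooding: float = 100.0,
    allow_splitting: bool = False,
):
    """Explicit flood-simulation reference for the H-maxima watershed.

    Returns (n_regions, flooded_mask). Seeds are regional maxima with
    dynamics >= seed_dynamics lying on the support; each seed floods
    the connected superlevel set at its flood level. With splitting,
    each surviving seed is one region; without, regions are the
    connected components of the union of flooded sets.
    """
    img = np.asarray(img, dtype=float)
    support = img >= intensity_threshold
    seeds = []
    for plateau in _regional_maxima(img):
        peak = img[plateau[0]]
        if peak < intensity_threshold:
            continue
        if _dynamics(img, plateau) >= seed_dynamics:
            seeds.append((plateau[0], peak))
    if not seeds:
        return 0, np.zeros(img.shape, bool)
    flooded = np.zeros(img.shape, bool)
    for rc, peak in seeds:
        lvl = peak - (peak_flooding / 100.0) * (peak - intensity_threshold)
        flooded |= _component_containing(img >= lvl, rc) & support
    if allow_splitting:
        return len(seeds), flooded
    _, areas = label_components_bfs(flooded)
    return len(areas), flooded


def grid_search_4pl_sse(
    doses: np.ndarray, responses: np.ndarray, n_ic50: int = 300, n_hill: int = 80
) -> tuple[float, float]:
    """Best (ic50, SSE) over a dense (ic50, hill) grid with top/bottom
    pinned to the response extremes."""
    x = np.asarray(doses, float)
    y = np.asarray(responses, float)
    top, bot = y.max(), y.min()
    ic_grid = np.geomspace(x.min() / 10, x.max() * 10, n_ic50)
    hill_grid = np.linspace(0.1, 8.0, n_hill)
    best_ic, best_sse = math.nan, math.inf
    for ic in ic_grid:
        pred = bot + (top - bot) / (1 + (x[None, :] / ic) ** hill_grid[:, None])
        sse = ((pred - y[None, :]) ** 2).sum(axis=1)
        k = int(sse.argmin())
        if sse[k] < best_sse:
            best_ic, best_sse = float(ic), float(sse[k])
    return best_ic, best_sse
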