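"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from the geometric / optimization
definitions, avoiding the package's KD-tree neighbor search, its closed-form
coefficient solution and its vectorized lineshape projection.
"""

from __future__ import annotations

import numpy as np

from hydrashell.frame import Frame, Roles


def min_image(delta: np.ndarray, box) -> np.ndarray:
    if box is None:
        return delta
    return delta - box * np.floor(delta / box + 0.5)


def brute_classify(frame: Frame, shell_cutoff: float = 3.5, bulk_min: float = 10.0):
    """All-pairs water classification by direct distance scan."""
    ref = [
        i
        for i in range(frame.n_atoms)
        if frame.roles[i] in (Roles.PROTEIN_C, Roles.PROTEIN_O)
    ]
    shell, bulk, inter = [], [], []
    for o in frame.water_o:
        dmin = np.inf
        for j in ref:
            delta = min_image(frame.positions[o] - frame.positions[j], frame.box)
            dmin = min(dmin, float(np.sqrt(np.dot(delta, delta))))
        if dmin <= shell_cutoff:
            shell.append(int(o))
        elif dmin > bulk_min:
            bulk.append(int(o))
        else:
            inter.append(int(o))
    return set(shell), set(bulk), set(inter)


def _brute_geometry(frame: Frame, donor_row: int, acceptor: int):
    pos = frame.positions
    o = int(frame.water_o[donor_row])
    best = None
    for h in frame.water_h[donor_row]:
        va = min_image(pos[acceptor] - pos[h], frame.box)
        dist_ha = np.linalg.norm(va)
        if best is None or dist_ha < best[0]:
            best = (dist_ha, h, va)
    _, h, va = best
    vo = min_image(pos[o] - pos[h], frame.box)
    d = float(np.linalg.norm(min_image(pos[acceptor] - pos[o], frame.box)))
    cos = float(np.dot(vo, va) / (np.linalg.norm(vo) * np.linalg.norm(va)))
    return d, cos


def brute_enumerate(
    frame: Frame,
    population: str,
    pair_cutoff: float = 3.5,
    shell_cutoff: float = 3.5,
    bulk_min: float = 10.0,
) -> list[tuple[float, float]]:
    """Double-loop enumeration; returns (d, cos_theta) tuples (unordered)."""
    shell, bulk, _ = brute_classify(frame, shell_cutoff, bulk_min)
    wo = list(frame.water_o)
    out: list[tuple[float, float]] = []

    def ww(acceptors: set[int]):
        for di, o_d in enumerate(wo):
            for o_a in wo:
                if o_a == o_d or o_a not in acceptors:
                    continue
                delta = min_image(
                    frame.positions[o_a] - frame.positions[o_d], frame.box
                )
                if np.linalg.norm(delta) <= pair_cutoff:
                    out.append(_brute_geometry(frame, di, int(o_a)))

    def wp(carbox_only: bool):
        acceptors = [
            i
            for i in range(frame.n_atoms)
            if frame.roles[i] in (Roles.PROTEIN_O, Roles.PROTEIN_N)
            and (not carbox_only or frame.carboxylate[i])
        ]
        for di, o_d in enumerate(wo):
            for a in acceptors:
                delta = min_image(frame.positions[a] - frame.positions[o_d], frame.box)
                if np.linalg.norm(delta) <= pair_cutoff:
                    out.append(_brute_geometry(frame, di, a))

    if population in ("WW1", "SHELL_ALL", "WW1_WC1"):
        ww(shell)
    if population in ("WP1", "SHELL_ALL"):
        wp(False)
    if population in ("WC1", "WW1_WC1"):
        wp(True)
    if population == "BULK":
        ww(bulk)
    return out


def sample_multiset(samples, ndigits: int = 8):
    """Canonical sortable form of (d, cos) collections for comparison."""
    def key(item):
        d, c = (item.d, item.cos_theta) if hasattr(item, "d") else item
        return (round(d, ndigits), round(c, ndigits))

    return sorted(key(s) for s in samples)


# ---------------------------------------------------------------------------
# spectroscopy oracles
# ---------------------------------------------------------------------------

def boxcar_independent(y: np.ndarray, width: int) -> np.ndarray:
    """Edge-normalized moving average via an explicit loop."""
    if width <= 1:
        return np.asarray(y, dtype=float)
    out = np.empty_like(np.asarray(y, dtype=float))
    half = width // 2
    for i in range(len(y)):
        lo, hi = max(0, i - half), min(len(y), i - half + width)
        out[i] = np.mean(y[lo:hi])
    return out


def grid_scan_coefficient(
    sample,
    reference,
    region,
    tolerance: float,
    smooth_points: int = 1,
    reference_floor: float = 0.0,
    step: float = 1e-4,
) -> float:
    """Dense scan for the largest c with min residual >= -tolerance."""
    w = sample.wavenumbers
    m = (w >= region[0]) & (w <= region[1])
    s = boxcar_independent(sample.intensities, smooth_points)[m]
    r = boxcar_independent(reference.intensities, smooth_points)[m]
    valid = r > reference_floor * r.max()
    s, r = s[valid], r[valid]
    c_upper = 1.0
    while np.min(s - c_upper * r) >= -tolerance:
        c_upper *= 2.0
        if c_upper > 1e6:
            raise RuntimeError("coefficient appears unbounded")
    grid = np.arange(0.0, c_upper + step, step)
    best = 0.0
    for chunk in np.array_split(grid, max(1, len(grid) // 512)):
        mins = (s[None, :] - chunk[:, None] * r[None, :]).min(axis=1)
        ok = chunk[mins >= -tolerance]
        if len(ok):
            best = max(best, float(ok[-1]))
    return best


def naive_oh_projection(density, fmap, grid: np.ndarray) -> np.ndarray:
    """Per-bin lineshape summation with explicit loops (no vectorization)."""
    d_centers = 0.5 * (density.d_edges[:-1] + density.d_edges[1:])
    out = np.zeros_like(grid, dtype=float)
    for i, dc in enumerate(d_centers):
        for j in range(len(density.cos_edges) - 1):
            mass = density.density[i, j] * (
                density.d_edges[i + 1] - density.d_edges[i]
            ) * (density.cos_edges[j + 1] - density.cos_edges[j])
            if mass == 0.0:
                continue
            nu = fmap.nu_free - fmap.amplitude * np.exp(-(dc - fmap.d0) / fmap.lam)
            out += mass * np.exp(-0.5 * ((grid - nu) / fmap.sigma_nu) ** 2) / (
                fmap.sigma_nu * np.sqrt(2 * np.pi)
            )
    return out


# ---------------------------------------------------------------------------
# random frames for oracle parity tests
# ---------------------------------------------------------------------------

def build_random_frame(
    rng: np.random.Generator,
    n_protein: int = 12,
    n_waters: int = 60,
    box_edge: float | None = None,
    spread: float = 26.0,
) -> Frame:
    """A disordered frame (no prescribed geometry) for stress-testing."""
    size = box_edge if box_edge is not None else spread
    positions, roles, carbox = [], [], []
    center = size / 2.0
    for i in range(n_protein):
        positions.append(center + rng.uniform(-4.0, 4.0, 3))
        role = [Roles.PROTEIN_C, Roles.PROTEIN_O, Roles.PROTEIN_N, Roles.PROTEIN_OTHER][
            i % 4
        ]
        roles.append(role)
        carbox.append(role == Roles.PROTEIN_O and i % 8 == 1)
    water_h = np.empty((n_waters, 2), dtype=int)
    for k in range(n_waters):
        o = rng.uniform(0.0, size, 3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        t = rng.normal(size=3)
        t -= np.dot(t, u) * u
        t /= np.linalg.norm(t)
        ang = np.deg2rad(104.5)
        base = len(positions)
        positions.extend([o, o + 0.97 * u, o + 0.97 * (np.cos(ang) * u + np.sin(ang) * t)])
        roles.extend([Roles.WATER_O, Roles.WATER_H, Roles.WATER_H])
        carbox.extend([False, False, False])
        water_h[k] = (base + 1, base + 2)
    return Frame(
        positions=np.array(positions),
        roles=np.array(roles),
        carboxylate=np.array(carbox, dtype=bool),
        water_h=water_h,
        box=None if box_edge is None else np.full(3, box_edge),
    )
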