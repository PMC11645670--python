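"""Water classification and hydrogen-bond geometry enumeration.

The solvation shell is defined purely geometrically: a water oxygen within
``shell_cutoff`` (default 3.5 A) of at least one protein carbon or oxygen
atom belongs to the first shell; a water oxygen farther than ``bulk_min``
(default 10 A) from *all* protein C/O atoms is bulk; everything else is
intermediate and excluded from both populations.  Protein nitrogens do not
define the shell, although they do act as hydrogen-bond acceptors.

For every retained donor--acceptor pair two numbers are recorded: the
heavy-atom distance d and cos(theta) of the hydrogen-centered angle
(donor-heavy, H, acceptor-heavy), evaluated at the donor hydrogen closest to
the acceptor.  cos(theta) = -1 corresponds to a perfectly linear (strongest)
hydrogen bond.  No angular filter is applied: each geometric neighbor pair
within the cutoff contributes exactly one sample, so the "hydrogen bond"
populations are short-hand for neighbor configurations.

Populations
-----------
``WW1``   water->water bonds accepted by a first-shell water oxygen
          (the donor may be any water);
``WP1``   water->protein bonds, acceptor a protein O or N within the cutoff
          of the donor water oxygen;
``WC1``   the subset of WP1 whose acceptor is an Asp/Glu carboxylate oxygen;
``SHELL_ALL``  WW1 plus WP1;
``WW1_WC1``    WW1 plus WC1 (the composite shown in some density figures);
``BULK``  water->water bonds accepted by a bulk water oxygen.

Neighbor searches use a cell-based KD-tree (periodic when a box is present);
tests verify sample-for-sample agreement with a brute-force O(N^2) scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .frame import Frame, Roles

POPULATIONS = ("SHELL_ALL", "WW1", "WP1", "WC1", "BULK", "WW1_WC1")


class ClassificationError(ValueError):
    """Raised when the shell/bulk partition is undefined for a frame."""


@dataclass(frozen=True)
class HBondSample:
    """One donor--acceptor geometric record."""

    d: float
    cos_theta: float
    population: str
    frame_index: int = 0


@dataclass(frozen=True)
class WaterPartition:
    """Water oxygen atom indices split into shell / bulk / intermediate."""

    shell: np.ndarray
    bulk: np.ndarray
    intermediate: np.ndarray


def _tree(frame: Frame, points: np.ndarray) -> cKDTree:
    if frame.box is None:
        return cKDTree(points)
    return cKDTree(np.mod(points, frame.box), boxsize=frame.box)


def classify_waters(
    frame: Frame, shell_cutoff: float = 3.5, bulk_min: float = 10.0
) -> WaterPartition:
    """Partition water oxygens into shell, bulk and intermediate sets.

    Shell: distance <= ``shell_cutoff`` to at least one protein C or O atom
    (boundary inclusive).  Bulk: distance > ``bulk_min`` to all protein C/O
    atoms.  Minimum-image distances are used when the frame has a box.
    """
    if not 0 < shell_cutoff < bulk_min:
        raise ValueError("require 0 < shell_cutoff < bulk_min")
    ref = frame.protein_heavy(include_nitrogen=False)
    if len(ref) == 0:
        raise ClassificationError("frame has no protein C/O atoms; shell undefined")
    wo = frame.water_o
    if len(wo) == 0:
        return WaterPartition(*(np.empty(0, dtype=int),) * 3)
    tree = _tree(frame, frame.positions[ref])
    pts = frame.positions[wo]
    if frame.box is not None:
        pts = np.mod(pts, frame.box)
    dmin, _ = tree.query(pts, k=1)
    shell = wo[dmin <= shell_cutoff]
    bulk = wo[dmin > bulk_min]
    inter = wo[(dmin > shell_cutoff) & (dmin <= bulk_min)]
    return WaterPartition(shell=shell, bulk=bulk, intermediate=inter)


def _cos_theta_at_donor_h(frame: Frame, donor_row: int, acceptor: int) -> tuple[float, float]:
    """(d, cos_theta) for water donor (row in water_o) toward acceptor atom."""
    pos = frame.positions
    o = frame.water_o[donor_row]
    h1, h2 = frame.water_h[donor_row]
    va1 = frame.delta(pos[h1], pos[acceptor])
    va2 = frame.delta(pos[h2], pos[acceptor])
    h = h1 if np.dot(va1, va1) <= np.dot(va2, va2) else h2
    va = va1 if h == h1 else va2
    vo = frame.delta(pos[h], pos[o])
    d = float(np.linalg.norm(frame.delta(pos[o], pos[acceptor])))
    cos = float(np.dot(vo, va) / (np.linalg.norm(vo) * np.linalg.norm(va)))
    return d, min(1.0, max(-1.0, cos))


def _water_water_samples(
    frame: Frame,
    acceptor_rows: np.ndarray,
    pair_cutoff: float,
    population: str,
    frame_index: int,
) -> list[HBondSample]:
    """Ordered (donor water, acceptor water-O) samples for a set of acceptors."""
    wo = frame.water_o
    row_of = {int(a): r for r, a in enumerate(wo)}
    acceptor_set = set(int(wo[r]) for r in acceptor_rows)
    tree = _tree(frame, frame.positions[wo])
    out: list[HBondSample] = []
    for i, j in sorted(tree.query_pairs(pair_cutoff)):
        ai, aj = int(wo[i]), int(wo[j])
        if aj in acceptor_set:
            d, c = _cos_theta_at_donor_h(frame, row_of[ai], aj)
            out.append(HBondSample(d, c, population, frame_index))
        if ai in acceptor_set:
            d, c = _cos_theta_at_donor_h(frame, row_of[aj], ai)
            out.append(HBondSample(d, c, population, frame_index))
    return out


def _water_protein_samples(
    frame: Frame,
    acceptors: np.ndarray,
    pair_cutoff: float,
    population: str,
    frame_index: int,
) -> list[HBondSample]:
    wo = frame.water_o
    if len(acceptors) == 0 or len(wo) == 0:
        return []
    wtree = _tree(frame, frame.positions[wo])
    atree = _tree(frame, frame.positions[acceptors])
    out: list[HBondSample] = []
    for arow, donors in enumerate(atree.query_ball_tree(wtree, pair_cutoff)):
        a = int(acceptors[arow])
        for drow in sorted(donors):
            d, c = _cos_theta_at_donor_h(frame, drow, a)
            out.append(HBondSample(d, c, population, frame_index))
    return out


def enumerate_hbonds(
    frame: Frame,
    population: str,
    pair_cutoff: float = 3.5,
    shell_cutoff: float = 3.5,
    bulk_min: float = 10.0,
    frame_index: int = 0,
) -> list[HBondSample]:
    """Enumerate hydrogen-bond geometry samples for one population.

    Each ordered (donor, acceptor) pair within ``pair_cutoff`` yields exactly
    one :class:`HBondSample`; see the module docstring for the population
    definitions.  Raises on unknown population labels.
    """
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}; choose from {POPULATIONS}")
    part = classify_waters(frame, shell_cutoff=shell_cutoff, bulk_min=bulk_min)
    row_index = {int(a): r for r, a in enumerate(frame.water_o)}

    def ww1() -> list[HBondSample]:
        rows = np.array([row_index[int(a)] for a in part.shell], dtype=int)
        return _water_water_samples(frame, rows, pair_cutoff, population, frame_index)

    def wp1(carboxylate_only: bool) -> list[HBondSample]:
        m = (frame.roles == Roles.PROTEIN_O) | (frame.roles == Roles.PROTEIN_N)
        if carboxylate_only:
            m &= frame.carboxylate
        return _water_protein_samples(
            frame, np.flatnonzero(m), pair_cutoff, population, frame_index
        )

    def bulk() -> list[HBondSample]:
        rows = np.array([row_index[int(a)] for a in part.bulk], dtype=int)
        return _water_water_samples(frame, rows, pair_cutoff, population, frame_index)

    if population == "WW1":
        return ww1()
    if population == "WP1":
        return wp1(False)
    if population == "WC1":
        return wp1(True)
    if population == "SHELL_ALL":
        return ww1() + wp1(False)
    if population == "WW1_WC1":
        return ww1() + wp1(True)
    return bulk()


def samples_to_arrays(samples: list[HBondSample]) -> tuple[np.ndarray, np.ndarray]:
    """(d, cos_theta) arrays from a sample list."""
    d = np.array([s.d for s in samples], dtype=float)
    c = np.array([s.cos_theta for s in samples], dtype=float)
    return d, c


def collect_samples(
    frames,
    population: str,
    pair_cutoff: float = 3.5,
    shell_cutoff: float = 3.5,
    bulk_min: float = 10.0,
    stride: int = 1,
) -> list[HBondSample]:
    """Enumerate over a trajectory, keeping every ``stride``-th frame.

    The stride mirrors the sparser sampling used for the bulk reference
    density (every 100th saved configuration in the source trajectories).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    out: list[HBondSample] = []
    for i, fr in enumerate(frames):
        if i % stride:
            continue
        out.extend(
            enumerate_hbonds(
                fr,
                population,
                pair_cutoff=pair_cutoff,
                shell_cutoff=shell_cutoff,
                bulk_min=bulk_min,
                frame_index=i,
            )
        )
    return out
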