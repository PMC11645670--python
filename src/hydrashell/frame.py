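"""Molecular configuration container used by the hydrogen-bond analyses.

A :class:`Frame` is deliberately minimal: typed atoms with coordinates in
Angstrom, an explicit water-molecule grouping (each water oxygen linked to
exactly two hydrogens), a carboxylate flag on protein oxygens, and an
optional orthorhombic periodic box.  Trajectories are plain lists of frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class Roles:
    """Atom role labels understood by the analyses."""

    PROTEIN_C = "protein_C"
    PROTEIN_O = "protein_O"
    PROTEIN_N = "protein_N"
    PROTEIN_OTHER = "protein_other"
    WATER_O = "water_O"
    WATER_H = "water_H"
    ION = "ion"

    ALL = (PROTEIN_C, PROTEIN_O, PROTEIN_N, PROTEIN_OTHER, WATER_O, WATER_H, ION)


@dataclass
class Frame:
    """One molecular configuration.

    Parameters
    ----------
    positions:
        ``(n_atoms, 3)`` coordinates in Angstrom.
    roles:
        Array of role labels (see :class:`Roles`), one per atom.
    carboxylate:
        Boolean flag per atom; True only on protein oxygens belonging to
        Asp/Glu side-chain carboxylate groups.
    water_h:
        ``(n_waters, 2)`` integer array: for each water oxygen (row order of
        ``water_o``) the indices of its two hydrogens.
    box:
        Optional orthorhombic box edge lengths (3,) in Angstrom.  Only
        orthorhombic boxes are supported; minimum-image distances are used
        whenever a box is present.
    """

    positions: np.ndarray
    roles: np.ndarray
    carboxylate: np.ndarray
    water_h: np.ndarray
    box: np.ndarray | None = None
    water_o: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.roles = np.asarray(self.roles)
        self.carboxylate = np.asarray(self.carboxylate, dtype=bool)
        self.water_h = np.asarray(self.water_h, dtype=int).reshape(-1, 2)
        if self.water_o is None:
            self.water_o = np.flatnonzero(self.roles == Roles.WATER_O)
        self.water_o = np.asarray(self.water_o, dtype=int)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.roles.shape != (n,) or self.carboxylate.shape != (n,):
            raise ValueError("roles/carboxylate must have one entry per atom")
        unknown = set(np.unique(self.roles)) - set(Roles.ALL)
        if unknown:
            raise ValueError(f"unknown atom roles: {sorted(unknown)}")
        if np.any(self.carboxylate & (self.roles != Roles.PROTEIN_O)):
            raise ValueError("carboxylate flag allowed only on protein_O atoms")
        n_wo = int(np.sum(self.roles == Roles.WATER_O))
        n_wh = int(np.sum(self.roles == Roles.WATER_H))
        if self.water_h.shape != (n_wo, 2) or n_wh != 2 * n_wo:
            raise ValueError(
                f"every water oxygen needs exactly two hydrogens "
                f"(got {n_wo} O, {n_wh} H, map shape {self.water_h.shape})"
            )
        if n_wo and (
            np.any(self.roles[self.water_h.ravel()] != Roles.WATER_H)
            or len(np.unique(self.water_h)) != 2 * n_wo
        ):
            raise ValueError("water_h must map each oxygen to two distinct water_H atoms")
        if self.box is not None:
            if np.any(self.box <= 7.0):
                raise ValueError("periodic box edges must exceed 7 A (twice the pair cutoff)")

    # -- geometry helpers ------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def delta(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Displacement b - a under the minimum-image convention."""
        d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
        if self.box is not None:
            d = d - self.box * np.round(d / self.box)
        return d

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.delta(self.positions[i], self.positions[j])))

    def protein_heavy(self, include_nitrogen: bool = False) -> np.ndarray:
        """Indices of protein C and O atoms (optionally also N)."""
        m = (self.roles == Roles.PROTEIN_C) | (self.roles == Roles.PROTEIN_O)
        if include_nitrogen:
            m |= self.roles == Roles.PROTEIN_N
        return np.flatnonzero(m)

    def translated(self, shift) -> "Frame":
        """Rigidly translated copy (used by invariance tests)."""
        return Frame(
            positions=self.positions + np.asarray(shift, dtype=float),
            roles=self.roles.copy(),
            carboxylate=self.carboxylate.copy(),
            water_h=self.water_h.copy(),
            box=None if self.box is None else self.box.copy(),
            water_o=self.water_o.copy(),
        )

    def wrapped_positions(self) -> np.ndarray:
        """Coordinates wrapped into [0, box) per axis; identity without a box."""
        if self.box is None:
            return self.positions
        return np.mod(self.positions, self.box)
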