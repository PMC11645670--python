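"""Synthetic molecular frames and FTIR spectra with known ground truth.

The frame generator does not run dynamics: it places a protein-like atom
cluster in a box and builds hydrogen-bonded water *pairs* whose
(d, cos theta) geometry is drawn exactly from prescribed distributions, so
the downstream densitometry can be validated against the generating
distributions.  Construction guarantees:

* every shell water oxygen lies within 3.5 A of a protein carbon and
  farther than 3.5 A from every protein O/N (so only water->water samples
  carry the prescribed geometry);
* every bulk water oxygen lies more than 10 A from all protein C/O atoms;
* waters belonging to different pairs are separated by more than the pair
  cutoff, so each water forms a bond with its partner and nothing else;
* each water has one O and two H at 0.97 A with a 104.5 degree H-O-H angle
  (rigid TIP3P-like geometry), the bonding hydrogen oriented to realize the
  drawn cos theta and the second hydrogen pointing away from the partner.

Each pair contributes both ordered donor->acceptor samples: the two waters
share one distance draw and receive independent cos theta draws.  The
effective number of independent distance draws is therefore the pair count,
which the recovery tests account for.

The spectrum generator composes a bulk-solvent reference from Gaussian
bands, mixes it into a sample with coefficient c_true, adds a non-negative
solute-correlated (SC) component, a linear baseline drift and i.i.d.
Gaussian noise — exactly the two-component model the IR-SSS extraction
assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .distributions import ParametricDist
from .frame import Frame, Roles
from .spectra import Spectrum

OH_LENGTH = 0.97  # A
HOH_ANGLE = np.deg2rad(104.5)
PAIR_CUTOFF = 3.5
BULK_MIN = 10.0

# geometric margins used by the placement scheme (A)
_ACCEPTOR_RANGE = (2.6, 3.4)  # anchor -> acceptor-O radial distance
_DONOR_TARGET = 3.2  # preferred anchor -> donor-O distance
_DONOR_MAX = 3.45
_INTERIOR_GAP = 7.5  # surface-to-interior-atom clearance
_PAIR_SEP = 10.5  # required anchor separation
_BULK_CENTROID_SEP = 7.1


def _default_shell_d() -> ParametricDist:
    return ParametricDist("truncnorm", loc=2.70, scale=0.12, support=(2.3, 3.5))


def _default_shell_cos() -> ParametricDist:
    return ParametricDist("truncnorm", loc=-0.95, scale=0.08, support=(-1.0, 0.0))


def _default_bulk_d() -> ParametricDist:
    return ParametricDist("truncnorm", loc=2.90, scale=0.15, support=(2.3, 3.5))


def _default_bulk_cos() -> ParametricDist:
    return ParametricDist("truncnorm", loc=-0.85, scale=0.15, support=(-1.0, 0.0))


@dataclass
class SyntheticShellModel:
    """Ground-truth description of the synthetic frames.

    Defaults give a small protein-like cluster in the ~100 A box used by
    the source simulations, with shell hydrogen bonds centered at short
    distance (2.70 A, nearly linear) and bulk bonds longer and less linear,
    mimicking the shell-vs-bulk contrast the difference maps resolve.
    """

    n_protein_atoms: int = 80
    protein_radius: float = 16.0
    frac_carboxylate_O: float = 0.3
    n_shell_waters: int = 40
    n_bulk_waters: int = 40
    shell_d_dist: ParametricDist = field(default_factory=_default_shell_d)
    shell_cos_dist: ParametricDist = field(default_factory=_default_shell_cos)
    bulk_d_dist: ParametricDist = field(default_factory=_default_bulk_d)
    bulk_cos_dist: ParametricDist = field(default_factory=_default_bulk_cos)
    box_edge: float = 100.0
    periodic: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_protein_atoms", "n_shell_waters", "n_bulk_waters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_protein_atoms < 1:
            raise ValueError("at least one protein atom is required")
        if self.n_shell_waters % 2:
            raise ValueError("n_shell_waters must be even (waters are placed as bonded pairs)")
        if self.n_bulk_waters % 2:
            raise ValueError("n_bulk_waters must be even (waters are placed as bonded pairs)")
        if not 0.0 <= self.frac_carboxylate_O <= 1.0:
            raise ValueError("frac_carboxylate_O must be in [0, 1]")
        for name, dist, lo, hi in (
            ("shell_d_dist", self.shell_d_dist, 2.3, PAIR_CUTOFF),
            ("bulk_d_dist", self.bulk_d_dist, 2.3, PAIR_CUTOFF),
            ("shell_cos_dist", self.shell_cos_dist, -1.0, 0.0),
            ("bulk_cos_dist", self.bulk_cos_dist, -1.0, 0.0),
        ):
            if not dist.within(lo, hi):
                raise ValueError(
                    f"{name} support {dist.support} outside histogram domain [{lo}, {hi}]"
                )
        if self.n_shell_waters and self.protein_radius < _INTERIOR_GAP + 1.5:
            raise ValueError(
                f"protein_radius must be >= {_INTERIOR_GAP + 1.5} A to separate "
                "surface anchors from interior acceptors"
            )
        if self.n_bulk_waters:
            if self.box_edge <= 2 * BULK_MIN:
                raise ValueError("box_edge must exceed 20 A when bulk waters are requested")
            required = 2 * (self.protein_radius + BULK_MIN + 3.0 + 4.0)
            if self.box_edge < required:
                raise ValueError(
                    f"box too small to host a bulk region: need box_edge >= "
                    f"{required:.1f} A for protein_radius={self.protein_radius}"
                )
        n_pairs = self.n_shell_waters // 2
        if n_pairs:
            anchors = _fibonacci_sphere(n_pairs)
            if n_pairs > 1:
                sep = self.protein_radius * _min_separation(anchors)
                if sep < _PAIR_SEP:
                    raise ValueError(
                        f"anchor separation {sep:.1f} A < {_PAIR_SEP} A; increase "
                        "protein_radius or reduce n_shell_waters"
                    )
            if self.n_protein_atoms < n_pairs:
                raise ValueError(
                    f"need n_protein_atoms >= {n_pairs} surface anchor carbons"
                )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistant unit vectors."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _min_separation(points: np.ndarray) -> float:
    d, _ = cKDTree(points).query(points, k=2)
    return float(d[:, 1].min())


def _perp_basis(e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row orthonormal vectors perpendicular to unit rows of e."""
    # pick, per row, the coordinate axis least aligned with e
    helper = np.zeros_like(e)
    idx = np.argmin(np.abs(e), axis=1)
    helper[np.arange(len(e)), idx] = 1.0
    p1 = np.cross(e, helper)
    p1 /= np.linalg.norm(p1, axis=1, keepdims=True)
    p2 = np.cross(e, p1)
    return p1, p2


def _bonding_direction_cos(d: np.ndarray, cos_theta: np.ndarray) -> np.ndarray:
    """cos(alpha) of the O-H direction from the O->partner axis.

    Solves the hydrogen-centered-angle relation
    cos(theta) = (r - d cos a) / sqrt(d^2 + r^2 - 2 d r cos a), r = OH length,
    in closed form, picking the root with the correct sign of r - d cos a.
    """
    r = OH_LENGTH
    t = cos_theta
    disc = np.sqrt(np.maximum(0.0, d * d - r * r * (1.0 - t * t)))
    root = np.where(t < 0, np.abs(t) * disc, -np.abs(t) * disc)
    return (r * (1.0 - t * t) + root) / d


def _place_hydrogens(
    o_pos: np.ndarray, partner: np.ndarray, cos_theta: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """H1 realizes the prescribed cos theta toward the partner; H2 points away."""
    delta = partner - o_pos
    d = np.linalg.norm(delta, axis=1)
    e = delta / d[:, None]
    x = _bonding_direction_cos(d, cos_theta)
    x = np.clip(x, -1.0, 1.0)
    s = np.sqrt(1.0 - x * x)
    p1, p2 = _perp_basis(e)
    psi = rng.uniform(0.0, 2.0 * np.pi, size=len(e))
    p = np.cos(psi)[:, None] * p1 + np.sin(psi)[:, None] * p2
    u1 = x[:, None] * e + s[:, None] * p
    # in-plane unit vector orthogonal to u1 on the partner side: rotate away
    q = s[:, None] * e - x[:, None] * p
    u2 = np.cos(HOH_ANGLE) * u1 - np.sin(HOH_ANGLE) * q
    return o_pos + OH_LENGTH * u1, o_pos + OH_LENGTH * u2


def _annulus_points(
    n: int, r_in: float, r_out: float, min_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """n points in a spherical annulus with pairwise separation >= min_sep."""
    kept: list[np.ndarray] = []
    for _ in range(200):
        m = max(4 * n, 64)
        v = rng.normal(size=(m, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        rad = (rng.uniform(size=m) * (r_out**3 - r_in**3) + r_in**3) ** (1.0 / 3.0)
        for point in v * rad[:, None]:
            if all(np.linalg.norm(point - k) >= min_sep for k in kept):
                kept.append(point)
                if len(kept) == n:
                    return np.array(kept)
    raise RuntimeError("could not place bulk waters; enlarge the box")


def gen_frames(model: SyntheticShellModel, n_frames: int) -> list[Frame]:
    """Generate seeded frames realizing the model's prescribed geometry.

    Pure function of (model, n_frames): repeated calls return byte-identical
    coordinates.
    """
    model.validate()
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(model.seed)
    center = np.full(3, model.box_edge / 2.0)
    n_pairs = model.n_shell_waters // 2
    n_bpairs = model.n_bulk_waters // 2
    anchors_u = _fibonacci_sphere(n_pairs) if n_pairs else np.empty((0, 3))

    # fixed role assignment: anchors are surface carbons, the rest interior
    n_int = model.n_protein_atoms - n_pairs
    n_o = int(round(0.3 * n_int))
    n_n = int(round(0.2 * n_int))
    int_roles = (
        [Roles.PROTEIN_O] * n_o + [Roles.PROTEIN_N] * n_n + [Roles.PROTEIN_C] * (n_int - n_o - n_n)
    )
    n_carbox = int(round(model.frac_carboxylate_O * n_o))

    frames: list[Frame] = []
    for _ in range(n_frames):
        positions: list[np.ndarray] = []
        roles: list[str] = []
        carbox: list[bool] = []

        anchor_pos = center + model.protein_radius * anchors_u
        positions.extend(anchor_pos)
        roles.extend([Roles.PROTEIN_C] * n_pairs)
        carbox.extend([False] * n_pairs)

        # interior atoms, well inside the surface so they never accept
        if n_int:
            r_int = max(model.protein_radius - _INTERIOR_GAP, 1.0)
            v = rng.normal(size=(n_int, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            rad = r_int * rng.uniform(size=n_int) ** (1.0 / 3.0)
            positions.extend(center + v * rad[:, None])
            roles.extend(int_roles)
            carbox.extend(
                [int_roles[i] == Roles.PROTEIN_O and i < n_carbox for i in range(n_int)]
            )

        water_o_pos: list[np.ndarray] = []
        water_h_pos: list[tuple[np.ndarray, np.ndarray]] = []

        def add_pair(o_a, o_b, cos_a, cos_b):
            """Two mutually bonded waters; each donates toward the other."""
            h_a = _place_hydrogens(o_a[None], o_b[None], np.array([cos_a]), rng)
            h_b = _place_hydrogens(o_b[None], o_a[None], np.array([cos_b]), rng)
            water_o_pos.extend([o_a, o_b])
            water_h_pos.append((h_a[0][0], h_a[1][0]))
            water_h_pos.append((h_b[0][0], h_b[1][0]))

        if n_pairs:
            d = model.shell_d_dist.rvs(n_pairs, rng)
            cos_a = model.shell_cos_dist.rvs(n_pairs, rng)
            cos_b = model.shell_cos_dist.rvs(n_pairs, rng)
            r_a = rng.uniform(*_ACCEPTOR_RANGE, size=n_pairs)
            acceptor = anchor_pos + r_a[:, None] * anchors_u
            # donor direction chosen so its anchor distance stays in the shell
            t = np.clip(_DONOR_TARGET, np.abs(r_a - d) + 0.05, np.minimum(_DONOR_MAX, r_a + d - 0.05))
            alpha = (t * t - r_a * r_a - d * d) / (2.0 * d * r_a)
            alpha = np.clip(alpha, -1.0, 1.0)
            p1, p2 = _perp_basis(anchors_u)
            psi = rng.uniform(0.0, 2.0 * np.pi, size=n_pairs)
            perp = np.cos(psi)[:, None] * p1 + np.sin(psi)[:, None] * p2
            w = alpha[:, None] * anchors_u + np.sqrt(1.0 - alpha * alpha)[:, None] * perp
            donor = acceptor + d[:, None] * w
            for k in range(n_pairs):
                add_pair(acceptor[k], donor[k], cos_a[k], cos_b[k])

        if n_bpairs:
            r_in = model.protein_radius + BULK_MIN + 3.0
            r_out = model.box_edge / 2.0 - 4.0
            centroids = center + _annulus_points(
                n_bpairs, r_in, r_out, _BULK_CENTROID_SEP, rng
            )
            d = model.bulk_d_dist.rvs(n_bpairs, rng)
            cos_a = model.bulk_cos_dist.rvs(n_bpairs, rng)
            cos_b = model.bulk_cos_dist.rvs(n_bpairs, rng)
            v = rng.normal(size=(n_bpairs, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            for k in range(n_bpairs):
                o_a = centroids[k] - 0.5 * d[k] * v[k]
                o_b = centroids[k] + 0.5 * d[k] * v[k]
                add_pair(o_a, o_b, cos_a[k], cos_b[k])

        n_w = len(water_o_pos)
        water_h = np.empty((n_w, 2), dtype=int)
        base = len(positions)
        all_pos = list(positions)
        all_roles = list(roles)
        all_carbox = list(carbox)
        for i, (o, (h1, h2)) in enumerate(zip(water_o_pos, water_h_pos)):
            all_pos.append(o)
            all_roles.append(Roles.WATER_O)
            all_carbox.append(False)
            water_h[i] = (base + 3 * i + 1, base + 3 * i + 2)
            all_pos.extend([h1, h2])
            all_roles.extend([Roles.WATER_H] * 2)
            all_carbox.extend([False] * 2)

        frames.append(
            Frame(
                positions=np.array(all_pos, dtype=float).reshape(-1, 3),
                roles=np.array(all_roles),
                carboxylate=np.array(all_carbox, dtype=bool),
                water_h=water_h,
                box=np.full(3, model.box_edge) if model.periodic else None,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Synthetic FTIR spectra
# ---------------------------------------------------------------------------

#: (center cm^-1, width cm^-1, amplitude) Gaussian bands of the bulk-solvent
#: reference: libration tail, HOH bend, association band and the split OH
#: stretch, with near-zero intensity in the baseline anchor windows.
DEFAULT_REFERENCE_BANDS = (
    (1050.0, 150.0, 0.25),
    (1640.0, 45.0, 0.45),
    (2130.0, 90.0, 0.08),
    (3280.0, 130.0, 0.85),
    (3480.0, 110.0, 0.65),
)

#: Solute-correlated bands: amide II, amide I and a perturbed-shell OH band.
DEFAULT_SC_BANDS = (
    (1540.0, 18.0, 0.15),
    (1656.0, 26.0, 0.22),
    (3250.0, 90.0, 0.12),
)


@dataclass
class SyntheticSpectrumModel:
    """Two-component spectrum mixture with known coefficient and SC part.

    sample = c_true * reference_bands + sc_bands + baseline line + noise.
    Default noise corresponds to a signal-to-noise ratio of ~100 relative
    to the SC amide I peak.
    """

    grid: np.ndarray = field(default_factory=lambda: np.arange(1000.0, 4000.5, 1.0))
    reference_bands: tuple = DEFAULT_REFERENCE_BANDS
    sc_bands: tuple = DEFAULT_SC_BANDS
    c_true: float = 0.97
    baseline_slope: float = 5e-6
    baseline_intercept: float = -5e-3
    noise_sigma: float = 2.2e-3
    concentration: float = 0.15
    label: str | None = None
    seed: int = 0

    def validate(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not 0.0 < self.c_true <= 1.2:
            raise ValueError("c_true must lie in (0, 1.2]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for bands, name in ((self.reference_bands, "reference"), (self.sc_bands, "sc")):
            for center, width, amp in bands:
                if width <= 0 or amp < 0:
                    raise ValueError(f"{name} band ({center}, {width}, {amp}) invalid")
        if self.sc_bands:
            sc = _bands(grid, self.sc_bands)
            peak = sc.max()
            for lo, hi, name in (1500.1, 1550.0, "amide II"), (2600.0, 3800.0, "OH"):
                m = (grid >= lo) & (grid <= hi)
                if not m.any() or sc[m].max() < 1e-6 * peak:
                    raise ValueError(
                        f"sc_bands carry no intensity in the {name} region [{lo}, {hi}]"
                    )


def _bands(grid: np.ndarray, bands) -> np.ndarray:
    y = np.zeros_like(grid)
    for center, width, amp in bands:
        y = y + amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return y


def gen_spectrum_pair(
    model: SyntheticSpectrumModel,
) -> tuple[Spectrum, Spectrum, dict]:
    """(sample, reference, truth) with truth = {c_true, sc_spectrum}.

    ``sample`` mixes the *noise-free* reference (scaled by c_true) with the
    SC component and baseline before adding its own noise, so the two-
    component assumption holds exactly at zero noise.  Pure function of the
    model, including its seed.
    """
    model.validate()
    rng = np.random.default_rng(model.seed)
    grid = np.asarray(model.grid, dtype=float)
    ref_clean = _bands(grid, model.reference_bands)
    sc_clean = _bands(grid, model.sc_bands)
    line = model.baseline_intercept + model.baseline_slope * grid
    noise_s = rng.normal(0.0, model.noise_sigma, size=grid.shape) if model.noise_sigma else 0.0
    noise_r = rng.normal(0.0, model.noise_sigma, size=grid.shape) if model.noise_sigma else 0.0
    sample = Spectrum(
        wavenumbers=grid,
        intensities=model.c_true * ref_clean + sc_clean + line + noise_s,
        concentration=model.concentration,
        role="solution",
        label=model.label,
    )
    reference = Spectrum(
        wavenumbers=grid,
        intensities=ref_clean + noise_r,
        concentration=model.concentration,
        role="reference",
    )
    truth = {
        "c_true": model.c_true,
        "sc_spectrum": Spectrum(
            wavenumbers=grid,
            intensities=sc_clean,
            concentration=model.concentration,
            role="solute_correlated",
            label=model.label,
        ),
    }
    return sample, reference, truth
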