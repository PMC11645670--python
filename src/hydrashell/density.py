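"""2D hydrogen-bond geometry densities and their differences.

A :class:`GeometryDensity` is the normalized probability density
p_{b,x}(d, cos(theta)) of one hydrogen-bond population x at salt molality b,
on a fixed rectangular grid.  Differences of densities measure the
perturbation of the solvation shell relative to the bulk solvent,

    dp_{b,x}   = p_{b,x} - p_{b,bulk}          (first order, same b),
    ddp_x      = dp_{b_high,x} - dp_{b_low,x}  (second order, same x),

positive where a (d, cos theta) configuration is more frequent in the
minuend.  Every density integrates to one and every difference to zero.

The default grid spans d in [2.3, 3.5] A and cos(theta) in [-1, 0] with
0.025-wide bins, matching the plotted range of the source density maps;
samples outside the grid are tallied as overflow, never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hbonds import HBondSample

DEFAULT_D_EDGES = np.round(np.arange(2.3, 3.5 + 1e-9, 0.025), 10)
DEFAULT_COS_EDGES = np.round(np.arange(-1.0, 0.0 + 1e-9, 0.025), 10)

_INTEGRAL_TOL = 1e-9


def _check_edges(edges: np.ndarray, name: str) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError(f"{name} must be strictly increasing with >= 2 entries")
    return edges


def _bin_areas(d_edges: np.ndarray, cos_edges: np.ndarray) -> np.ndarray:
    return np.outer(np.diff(d_edges), np.diff(cos_edges))


@dataclass
class GeometryDensity:
    """Normalized p(d, cos theta) for one population at one molality."""

    d_edges: np.ndarray
    cos_edges: np.ndarray
    density: np.ndarray  # (n_d_bins, n_cos_bins), units 1/(A * unit cos)
    n_samples: int
    molality: float
    population: str
    overflow: int = 0

    def __post_init__(self) -> None:
        self.d_edges = _check_edges(self.d_edges, "d_edges")
        self.cos_edges = _check_edges(self.cos_edges, "cos_edges")
        self.density = np.asarray(self.density, dtype=float)
        shape = (len(self.d_edges) - 1, len(self.cos_edges) - 1)
        if self.density.shape != shape:
            raise ValueError(f"density shape {self.density.shape} != grid {shape}")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if abs(self.integral() - 1.0) > _INTEGRAL_TOL:
            raise ValueError(f"density integral {self.integral()} != 1")

    def integral(self) -> float:
        return float(np.sum(self.density * _bin_areas(self.d_edges, self.cos_edges)))

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            0.5 * (self.d_edges[:-1] + self.d_edges[1:]),
            0.5 * (self.cos_edges[:-1] + self.cos_edges[1:]),
        )

    def same_grid(self, other) -> bool:
        return (
            len(self.d_edges) == len(other.d_edges)
            and len(self.cos_edges) == len(other.cos_edges)
            and np.allclose(self.d_edges, other.d_edges)
            and np.allclose(self.cos_edges, other.cos_edges)
        )


@dataclass
class DensityDifference:
    """dp (order 1) or ddp (order 2) on the same grid as its operands."""

    d_edges: np.ndarray
    cos_edges: np.ndarray
    values: np.ndarray
    minuend_tag: tuple[float, str]
    subtrahend_tag: tuple[float, str]
    order: int = 1

    def __post_init__(self) -> None:
        self.d_edges = _check_edges(self.d_edges, "d_edges")
        self.cos_edges = _check_edges(self.cos_edges, "cos_edges")
        self.values = np.asarray(self.values, dtype=float)
        shape = (len(self.d_edges) - 1, len(self.cos_edges) - 1)
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != grid {shape}")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if abs(self.integral()) > _INTEGRAL_TOL:
            raise ValueError(f"difference integral {self.integral()} != 0")

    def integral(self) -> float:
        return float(np.sum(self.values * _bin_areas(self.d_edges, self.cos_edges)))

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            0.5 * (self.d_edges[:-1] + self.d_edges[1:]),
            0.5 * (self.cos_edges[:-1] + self.cos_edges[1:]),
        )

    same_grid = GeometryDensity.same_grid


def accumulate_density(
    samples: list[HBondSample],
    d_edges: np.ndarray | None = None,
    cos_edges: np.ndarray | None = None,
    molality: float = 0.0,
    population: str | None = None,
) -> GeometryDensity:
    """Histogram (d, cos theta) samples into a normalized density.

    All samples must share one population label (taken as the density's
    label when ``population`` is not given).  Samples outside the grid are
    counted in ``overflow`` and excluded from the normalization; the
    in-grid integral is exactly one.
    """
    if not samples:
        raise ValueError("empty sample list: density undefined")
    labels = {s.population for s in samples}
    if len(labels) > 1:
        raise ValueError(f"mixed populations in sample list: {sorted(labels)}")
    label = labels.pop()
    if population is not None and population != label:
        raise ValueError(f"samples are {label!r}, not {population!r}")
    d_edges = DEFAULT_D_EDGES if d_edges is None else np.asarray(d_edges, float)
    cos_edges = DEFAULT_COS_EDGES if cos_edges is None else np.asarray(cos_edges, float)
    d = np.array([s.d for s in samples])
    c = np.array([s.cos_theta for s in samples])
    counts, _, _ = np.histogram2d(d, c, bins=[d_edges, cos_edges])
    n_in = int(counts.sum())
    overflow = len(samples) - n_in
    if n_in == 0:
        raise ValueError("no samples fall inside the histogram grid")
    density = counts / (n_in * _bin_areas(d_edges, cos_edges))
    return GeometryDensity(
        d_edges=d_edges,
        cos_edges=cos_edges,
        density=density,
        n_samples=len(samples),
        molality=molality,
        population=label,
        overflow=overflow,
    )


def density_difference(p_x: GeometryDensity, p_ref: GeometryDensity) -> DensityDifference:
    """dp = p_x - p_ref, both at the same molality (shell vs bulk at equal b)."""
    if not p_x.same_grid(p_ref):
        raise ValueError("operand grids differ")
    if not np.isclose(p_x.molality, p_ref.molality):
        raise ValueError(
            f"molality mismatch ({p_x.molality} vs {p_ref.molality}); "
            "the bulk reference must be taken at the same salt concentration"
        )
    return DensityDifference(
        d_edges=p_x.d_edges,
        cos_edges=p_x.cos_edges,
        values=p_x.density - p_ref.density,
        minuend_tag=(p_x.molality, p_x.population),
        subtrahend_tag=(p_ref.molality, p_ref.population),
        order=1,
    )


def double_difference(
    dp_high: DensityDifference, dp_low: DensityDifference
) -> DensityDifference:
    """ddp = dp(b_high) - dp(b_low) for one population x."""
    if dp_high.order != 1 or dp_low.order != 1:
        raise ValueError("double difference requires two first-order differences")
    if not dp_high.same_grid(dp_low):
        raise ValueError("operand grids differ")
    if dp_high.minuend_tag[1] != dp_low.minuend_tag[1]:
        raise ValueError(
            f"population mismatch: {dp_high.minuend_tag[1]} vs {dp_low.minuend_tag[1]}"
        )
    if not dp_high.minuend_tag[0] > dp_low.minuend_tag[0]:
        raise ValueError("first operand must be tagged with the larger molality")
    return DensityDifference(
        d_edges=dp_high.d_edges,
        cos_edges=dp_high.cos_edges,
        values=dp_high.values - dp_low.values,
        minuend_tag=dp_high.minuend_tag,
        subtrahend_tag=dp_low.minuend_tag,
        order=2,
    )


@dataclass(frozen=True)
class Region:
    """Axis-aligned (d, cos theta) box; open bounds default to the full grid."""

    name: str
    d_min: float = -np.inf
    d_max: float = np.inf
    cos_min: float = -np.inf
    cos_max: float = np.inf

    def mask(self, d_centers: np.ndarray, cos_centers: np.ndarray) -> np.ndarray:
        md = (d_centers >= self.d_min) & (d_centers < self.d_max)
        mc = (cos_centers >= self.cos_min) & (cos_centers < self.cos_max)
        return np.outer(md, mc)


#: Regions of the difference maps discussed in the density-map analysis:
#: very strong hydrogen bonds (d < 2.8 A, enriched in the shell) and
#: moderately strong ones (d > 2.8 A, nearly linear, depleted in the shell).
DEFAULT_REGIONS = (
    Region("VERY_STRONG", d_max=2.8),
    Region("MODERATE", d_min=2.8, cos_min=-1.0, cos_max=-0.75),
)


def region_summary(
    diff: DensityDifference | GeometryDensity,
    regions: tuple[Region, ...] = DEFAULT_REGIONS,
) -> dict[str, float]:
    """Signed integral of a difference (or density) over each named region.

    Bins straddling a region edge are assigned by bin-center membership.
    """
    values = diff.values if isinstance(diff, DensityDifference) else diff.density
    dc, cc = diff.bin_centers()
    areas = _bin_areas(diff.d_edges, diff.cos_edges)
    out: dict[str, float] = {}
    for region in regions:
        m = region.mask(dc, cc)
        if not m.any():
            raise ValueError(f"region {region.name!r} selects no bins")
        out[region.name] = float(np.sum(values[m] * areas[m]))
    return out


# ---------------------------------------------------------------------------
# CSV I/O: matrix with two leading rows of bin edges + JSON metadata sidecar
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_density_csv(obj: GeometryDensity | DensityDifference, path) -> None:
    path = Path(path)
    matrix = obj.density if isinstance(obj, GeometryDensity) else obj.values
    with path.open("w") as fh:
        fh.write(",".join(f"{v:.17g}" for v in obj.d_edges) + "\n")
        fh.write(",".join(f"{v:.17g}" for v in obj.cos_edges) + "\n")
        for row in matrix:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")
    if isinstance(obj, GeometryDensity):
        meta = {
            "kind": "density",
            "molality": obj.molality,
            "population": obj.population,
            "n_samples": obj.n_samples,
            "overflow": obj.overflow,
        }
    else:
        meta = {
            "kind": "difference",
            "order": obj.order,
            "minuend": list(obj.minuend_tag),
            "subtrahend": list(obj.subtrahend_tag),
        }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_density_csv(path) -> GeometryDensity | DensityDifference:
    path = Path(path)
    with path.open() as fh:
        d_edges = np.array([float(v) for v in fh.readline().split(",")])
        cos_edges = np.array([float(v) for v in fh.readline().split(",")])
        matrix = np.array(
            [[float(v) for v in line.split(",")] for line in fh if line.strip()]
        )
    meta = json.loads(_sidecar(path).read_text())
    if meta["kind"] == "density":
        return GeometryDensity(
            d_edges=d_edges,
            cos_edges=cos_edges,
            density=matrix,
            n_samples=meta["n_samples"],
            molality=meta["molality"],
            population=meta["population"],
            overflow=meta["overflow"],
        )
    return DensityDifference(
        d_edges=d_edges,
        cos_edges=cos_edges,
        values=matrix,
        minuend_tag=tuple(meta["minuend"]),
        subtrahend_tag=tuple(meta["subtrahend"]),
        order=meta["order"],
    )
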