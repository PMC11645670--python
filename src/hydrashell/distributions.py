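"""Small parametric distributions used by the synthetic generators.

Only the families the generators need are exposed: a truncated normal, a
uniform on an interval, and a point mass.  Each distribution carries its own
support so that generator models can be validated against the histogram
domain before any frame is produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_FAMILIES = ("truncnorm", "uniform", "point")


@dataclass(frozen=True)
class ParametricDist:
    """A 1D distribution described by family + location + scale + support.

    Parameters
    ----------
    family:
        One of ``"truncnorm"``, ``"uniform"``, ``"point"``.
    loc, scale:
        Location and scale.  For ``truncnorm`` these are the mean and
        standard deviation of the parent normal; for ``uniform`` the draw is
        uniform on ``support`` and loc/scale are ignored; for ``point`` every
        draw equals ``loc``.
    support:
        Closed interval ``(lo, hi)`` outside which the distribution has no
        mass.  ``truncnorm`` is truncated to it.
    """

    family: str
    loc: float = 0.0
    scale: float = 1.0
    support: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {_FAMILIES}")
        lo, hi = self.support
        if not lo <= hi:
            raise ValueError(f"empty support {self.support}")
        if self.family == "point" and not lo <= self.loc <= hi:
            raise ValueError("point mass lies outside declared support")
        if self.family == "truncnorm" and self.scale <= 0:
            raise ValueError("truncnorm requires scale > 0")

    def _frozen(self):
        lo, hi = self.support
        if self.family == "truncnorm":
            a, b = (lo - self.loc) / self.scale, (hi - self.loc) / self.scale
            return stats.truncnorm(a, b, loc=self.loc, scale=self.scale)
        if self.family == "uniform":
            return stats.uniform(loc=lo, scale=hi - lo)
        return None  # point

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "point":
            return np.full(n, self.loc)
        return self._frozen().rvs(size=n, random_state=rng)

    def mean(self) -> float:
        if self.family == "point":
            return self.loc
        return float(self._frozen().mean())

    def var(self) -> float:
        if self.family == "point":
            return 0.0
        return float(self._frozen().var())

    def cdf(self, x) -> np.ndarray:
        """CDF, used to compute exact per-bin probabilities in recovery tests."""
        x = np.asarray(x, dtype=float)
        if self.family == "point":
            return (x >= self.loc).astype(float)
        return self._frozen().cdf(x)

    def within(self, lo: float, hi: float) -> bool:
        """True if the full support lies inside [lo, hi]."""
        return self.support[0] >= lo and self.support[1] <= hi
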