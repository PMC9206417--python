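"""Resource-utilization trade-off curves.

A strain's phenotype is its allocation of uptake capacity between two
sugars.  Feasible phenotypes are bounded by a trade-off curve in the
(u1, u2) plane, where u1 is the utilization rate of the preferred
resource (fructose) and u2 of the unpreferred resource (galactose).
Evolving strains sit *on* the curve: any interior point is dominated by
a boundary point with higher uptake of both resources, so the evolving
trait is the single coordinate u1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TradeoffCurve", "Phenotype"]


@dataclass(frozen=True)
class TradeoffCurve:
    """Feasibility boundary ``u2 = u_max * (1 - (u1/u_max)**p)**(1/p)``.

    Parameters
    ----------
    shape_p:
        Dimensionless trade-off exponent.  ``p < 1`` bulges the boundary
        inward (a *strong* trade-off penalizing generalists); ``p > 1``
        bulges it outward (a *weak* trade-off favoring generalists);
        ``p = 1`` is the straight line ``u1 + u2 = u_max``.
    u_max:
        Maximal utilization of a single resource when the other is
        abandoned entirely.
    """

    shape_p: float
    u_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.shape_p > 0:
            raise ValueError(f"shape_p must be positive, got {self.shape_p}")
        if not self.u_max > 0:
            raise ValueError(f"u_max must be positive, got {self.u_max}")

    def u2(self, u1):
        """Boundary value of u2 for a given u1 (scalar or array)."""
        u1 = np.asarray(u1, dtype=float)
        if np.any(u1 < 0) or np.any(u1 > self.u_max):
            raise ValueError(
                f"u1 must lie in [0, {self.u_max}], got values outside the domain"
            )
        p = self.shape_p
        frac = np.clip(u1 / self.u_max, 0.0, 1.0)
        out = self.u_max * (1.0 - frac**p) ** (1.0 / p)
        return float(out) if out.ndim == 0 else out

    def __call__(self, u1):
        return self.u2(u1)


@dataclass(frozen=True)
class Phenotype:
    """A point on the trade-off boundary, parameterized by u1."""

    u1: float
    curve: TradeoffCurve

    @property
    def u2(self) -> float:
        return self.curve.u2(self.u1)

    @property
    def uptake(self) -> np.ndarray:
        """Utilization vector (u1, u2)."""
        return np.array([self.u1, self.u2])


def tradeoff_boundary(u1, curve: TradeoffCurve):
    """Functional alias for :meth:`TradeoffCurve.u2`."""
    return curve.u2(u1)
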