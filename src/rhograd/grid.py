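"""Uniform spatial grids along the cell axis.

All model and quantification profiles live on a 1-D grid of distances from
the cell edge, in micrometres.  ``x = 0`` is the protruding edge (or the
bright edge of an optogenetic gradient); the default domain spans a 35 µm
micropattern diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

DEFAULT_LENGTH_UM = 35.0
DEFAULT_SPACING_UM = 0.05


@dataclass(frozen=True)
class SpatialGrid:
    """Uniformly spaced positions from the cell edge inward.

    Parameters
    ----------
    length : float
        Domain length in µm (default 35, the micropattern diameter).
    spacing : float
        Grid step in µm; must be positive.  The default 0.05 µm resolves
        the sharpest model length scale (γ = 5 µm) by two orders of
        magnitude.
    """

    length: float = DEFAULT_LENGTH_UM
    spacing: float = DEFAULT_SPACING_UM
    positions: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise InvalidParameterError("grid spacing must be > 0")
        if self.length <= 0:
            raise InvalidParameterError("grid length must be > 0")
        n = int(round(self.length / self.spacing)) + 1
        x = np.linspace(0.0, self.spacing * (n - 1), n)
        object.__setattr__(self, "positions", x)

    @classmethod
    def from_positions(cls, positions: np.ndarray) -> "SpatialGrid":
        """Build a grid from an explicit, uniformly spaced position array."""
        x = np.asarray(positions, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise InvalidParameterError("need at least two positions")
        dx = np.diff(x)
        if x[0] != 0.0 or np.any(dx <= 0):
            raise InvalidParameterError("positions must start at 0 and increase")
        if not np.allclose(dx, dx[0], rtol=1e-8, atol=1e-10):
            raise InvalidParameterError("positions must be uniformly spaced")
        return cls(length=float(x[-1]), spacing=float(dx[0]))

    @property
    def n(self) -> int:
        return self.positions.size

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.positions.size
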