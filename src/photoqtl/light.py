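"""Light-intensity axis handling.

Chlorophyll-fluorescence light-response experiments expose each plant to a
strictly increasing ladder of actinic light intensities (PAR,
μmol·m⁻²·s⁻¹).  All curve modelling in this package is done on the natural
logarithm of intensity, which compresses the several-orders-of-magnitude
raw range onto a roughly unit-scale axis where sigmoidal growth families
behave well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class LightGrid:
    """A shared, ordered light-intensity axis.

    Attributes
    ----------
    raw_levels : ndarray
        Actinic light intensities in μmol·m⁻²·s⁻¹, strictly positive and
        strictly increasing.
    log_levels : ndarray
        Natural log of ``raw_levels``; the working independent variable ``l``.
    """

    raw_levels: np.ndarray
    log_levels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_levels, dtype=float)
        if raw.ndim != 1 or raw.size < 3:
            raise ValueError("light grid needs at least 3 one-dimensional levels")
        if np.any(raw <= 0):
            raise ValueError("light intensities must be strictly positive")
        if np.any(np.diff(raw) <= 0):
            raise ValueError("light intensities must be strictly increasing")
        object.__setattr__(self, "raw_levels", raw)
        object.__setattr__(self, "log_levels", np.log(raw))

    @property
    def L(self) -> int:
        """Number of light levels."""
        return self.raw_levels.size

    def dense(self, n_points: int) -> np.ndarray:
        """Uniform dense grid on the log-light axis spanning the same range."""
        if n_points < self.L:
            raise ValueError("dense grid must have at least as many points as the original")
        return np.linspace(self.log_levels[0], self.log_levels[-1], n_points)


def make_light_grid(raw_levels) -> LightGrid:
    """Validate raw intensities and return the log-transformed axis."""
    return LightGrid(raw_levels=np.asarray(raw_levels, dtype=float))


#: The 11-step actinic ladder used throughout the examples: log-spaced PAR
#: values from 7.243 to 2701.536 μmol·m⁻²·s⁻¹, i.e. ln-endpoints ≈ 1.980–7.902.
DEFAULT_RAW_LEVELS = tuple(np.exp(np.linspace(np.log(7.243), np.log(2701.536), 11)))


def default_light_grid(L: int = 11) -> LightGrid:
    """Log-spaced grid of ``L`` levels over the default PAR range."""
    raw = np.exp(np.linspace(np.log(7.243), np.log(2701.536), L))
    return make_light_grid(raw)
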