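"""Greenwood frequency–position function and its inverse.

F = A·(10^(a·x) − k), where x is the distance from the *apex* as a fraction
of BM length. Species constants for the rhesus macaque: A = 395 Hz, a = 2,
k = 1, so the apex maps to 0 Hz and the base to 395·99 = 39,105 Hz.

Everything outside this module works in mm from the *base* (the solver
convention); the apex-ratio coordinate of the Greenwood formula is internal,
with explicit converters, to avoid off-by-direction mistakes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "GreenwoodParams",
    "greenwood_frequency",
    "greenwood_position",
    "apex_ratio_to_mm_from_base",
    "mm_from_base_to_apex_ratio",
]


@dataclass(frozen=True)
class GreenwoodParams:
    """Greenwood constants plus the BM length used for mm conversions."""

    A: float = 395.0
    a: float = 2.0
    k: float = 1.0
    bm_length: float = 27.0  # mm

    def __post_init__(self) -> None:
        if self.A <= 0 or self.a <= 0:
            raise ConfigurationError("Greenwood A and a must be positive")
        if not 0.0 <= self.k <= 1.0:
            raise ConfigurationError("Greenwood k must lie in [0, 1]")
        if self.bm_length <= 0:
            raise ConfigurationError("bm_length must be positive")

    @property
    def max_frequency(self) -> float:
        """Frequency mapped to the extreme base (x_apex_ratio = 1)."""
        return self.A * (10.0 ** self.a - self.k)


def apex_ratio_to_mm_from_base(ratio, p: GreenwoodParams):
    """Convert apex-referenced fractional position to mm from the base."""
    return p.bm_length * (1.0 - np.asarray(ratio, dtype=float))


def mm_from_base_to_apex_ratio(x_mm, p: GreenwoodParams):
    """Convert mm from the base to the apex-referenced fraction."""
    return 1.0 - np.asarray(x_mm, dtype=float) / p.bm_length


def greenwood_frequency(x_apex_ratio, p: GreenwoodParams = GreenwoodParams()):
    """Resonant frequency (Hz) at fractional distance x from the apex.

    Strictly increasing in x; at k = 1 the apex (x = 0) maps to exactly
    0 Hz. Accepts scalars or arrays.
    """
    x = np.asarray(x_apex_ratio, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise DomainError("x_apex_ratio must lie in [0, 1]")
    out = p.A * (10.0 ** (p.a * x) - p.k)
    return out if out.ndim else float(out)


def greenwood_position(f, p: GreenwoodParams = GreenwoodParams()):
    """Position (mm from the base) whose resonant frequency is ``f`` Hz.

    Inverse of :func:`greenwood_frequency`; round-trips to better than
    1e-9 relative. Frequencies at or above the basal limit A·(10^a − k)
    are outside the map.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise DomainError("frequency must be non-negative")
    if np.any(f >= p.max_frequency):
        raise DomainError(
            f"frequency exceeds the basal limit {p.max_frequency:.0f} Hz"
        )
    ratio = np.log10(f / p.A + p.k) / p.a
    out = apex_ratio_to_mm_from_base(ratio, p)
    return out if out.ndim else float(out)
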