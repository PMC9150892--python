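"""Velocity- and TE-dependent vessel displacement in phase-encoding directions.

Blood that moves between the phase-encoding blip and the echo is mapped
to a shifted position along that phase-encode axis. The shift is
delta_y = -v_y * (TE - t_pe), linear in both the velocity component and
the blip-to-echo delay. The same relation applies independently to the
secondary (slab) phase-encode axis with that axis's velocity component.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DisplacementQuery", "vessel_shift_mm", "shift_range_um"]


@dataclass(frozen=True)
class DisplacementQuery:
    """Velocity component along a phase-encode axis plus sequence timing."""

    velocity_mm_s: float
    te_ms: float
    t_pe_ms: float = 0.0

    def __post_init__(self):
        if self.t_pe_ms < 0:
            raise ValueError("t_pe_ms must be >= 0")
        if self.te_ms < self.t_pe_ms:
            raise ValueError(
                f"te_ms ({self.te_ms}) must be >= t_pe_ms ({self.t_pe_ms})")


def vessel_shift_mm(q: DisplacementQuery) -> float:
    """Signed displacement -v (TE - t_pe), in mm.

    Positive velocity along the positive phase-encode axis yields a
    negative shift (sign convention as printed; report magnitude and sign
    separately where a magnitude is wanted).
    """
    return -q.velocity_mm_s * (q.te_ms - q.t_pe_ms) / 1000.0


def shift_range_um(v_min_mm_s: float, v_max_mm_s: float, delay_ms: float):
    """Displacement magnitudes (micrometres) at both velocity bounds.

    ``delay_ms`` is TE - t_pe. Returns (min_um, max_um).
    """
    if v_min_mm_s > v_max_mm_s:
        raise ValueError("v_min must be <= v_max")
    lo = abs(v_min_mm_s) * delay_ms
    hi = abs(v_max_mm_s) * delay_ms
    return (min(lo, hi), max(lo, hi))
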