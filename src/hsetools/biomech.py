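"""Suction-deformation viscoelasticity ratios.

A suction elastometer (e.g. a Cutometer-class device) pulls the skin
surface into a probe under negative pressure for a fixed time, releases,
and records surface displacement throughout.  From one suction/relax
cycle three amplitudes are read:

* ``Uf`` — final distension: the maximum displacement during suction;
* ``Ur`` — immediate retraction: the drop shortly after release;
* ``Ua`` — total recovery: the drop from Uf by the end of relaxation.

The reported ratios are ``R2 = Ua / Uf`` (gross elasticity) and
``R7 = Ur / Uf`` (elastic portion; higher means more elastic, less
viscous).  "Immediate" is read at a configurable window after release
(default 0.1 s) because devices differ in their internal definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SuctionCurve", "RParameters", "compute_r_parameters"]


@dataclass(frozen=True)
class SuctionCurve:
    """Displacement time series with suction/release/end phase marks."""

    time_s: np.ndarray
    displacement_mm: np.ndarray
    suction_start_s: float
    release_s: float
    end_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        d = np.asarray(self.displacement_mm, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "displacement_mm", d)
        if t.ndim != 1 or t.shape != d.shape:
            raise ValueError("time and displacement must be equal-length 1D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if np.any(d < 0):
            raise ValueError("displacement must be nonnegative")
        if not self.suction_start_s < self.release_s < self.end_s:
            raise ValueError("phase order must be suction_start < release < end")
        if self.suction_start_s < t[0] or self.end_s > t[-1]:
            raise ValueError("phase timestamps must lie within the sampled range")


@dataclass(frozen=True)
class RParameters:
    """Amplitudes (mm) and ratios from one suction cycle."""

    Uf: float
    Ur: float
    Ua: float
    R2: float
    R7: float

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.R2)


def compute_r_parameters(
    curve: SuctionCurve, immediate_window_s: float = 0.1
) -> RParameters:
    """Read Uf, Ur, Ua and the R2/R7 ratios off a suction curve.

    ``Uf`` is the maximum displacement within the suction phase,
    ``Ur = Uf - d(release + immediate_window)`` and
    ``Ua = Uf - d(end)``, with displacement linearly interpolated at the
    query times.  A flat curve (Uf = 0) yields NaN ratios and is flagged
    degenerate rather than raising.
    """
    if immediate_window_s < 0:
        raise ValueError("immediate_window_s must be nonnegative")
    t = curve.time_s
    d = curve.displacement_mm

    in_suction = (t >= curve.suction_start_s) & (t <= curve.release_s)
    in_relax = (t >= curve.release_s) & (t <= curve.end_s)
    if in_suction.sum() < 2 or in_relax.sum() < 2:
        raise ValueError("need at least 2 samples in each phase")

    # include interpolated boundary values so the phase maximum is exact
    uf = float(
        max(
            d[in_suction].max(),
            np.interp(curve.suction_start_s, t, d),
            np.interp(curve.release_s, t, d),
        )
    )
    t_immediate = min(curve.release_s + immediate_window_s, curve.end_s)
    ur = uf - float(np.interp(t_immediate, t, d))
    ua = uf - float(np.interp(curve.end_s, t, d))
    if uf == 0.0:
        return RParameters(0.0, ur, ua, float("nan"), float("nan"))
    return RParameters(uf, ur, ua, ua / uf, ur / uf)
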