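"""Thin-lens model of a beryllium CRL transfocator.

A compound refractive lens (CRL) stack of N parabolic lenses of apex
radius R focuses X-rays with focal length f = R / (2 N delta), where
delta is the refractive-index decrement of the lens material.  A
transfocator switches lens groups in and out of the beam to approximate,
at each photon energy, the focal length required to image the secondary
source aperture (SSA) onto the sample; residual mismatch can be absorbed
by translating the transfocator along the beam at the cost of a slightly
different demagnification.

The default stack models 43 lenses of 0.1 mm radius in groups of
1, 2, 4, 8, 16 and 12, plus four 0.5 mm-radius lenses for fine control.
delta uses the far-from-edge free-electron approximation
delta = r_e * lambda^2 * rho_e / (2 pi), adequate for beryllium over the
7-18 keV operating range to about 2%.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

from .geometry import energy_to_wavelength

__all__ = [
    "LensStack", "BeamlineLayout", "delta_beryllium", "focal_length",
    "demagnification", "required_focal_length", "solve_configuration",
    "ENERGY_RANGE_KEV", "LENS_TRAVEL_M",
]

#: classical electron radius, m
R_E = 2.818e-15
#: Avogadro constant, 1/mol
N_A = 6.02214076e23
#: beryllium: density g/cm^3, atomic number, molar mass g/mol
BE_DENSITY = 1.848
BE_Z = 4
BE_A = 9.0122
#: advisory beamline operating range, keV
ENERGY_RANGE_KEV = (7.0, 18.0)
#: transfocator translation range along the beam, m (stage travel)
LENS_TRAVEL_M = (0.5, 1.5)


def delta_beryllium(energy: float) -> float:
    """Refractive-index decrement of beryllium at ``energy`` keV.

    Far-from-edge model: delta = r_e * lambda^2 * rho_e / (2 pi) with the
    electron density rho_e from Be's bulk density; warns (does not fail)
    outside the 7-18 keV advisory range.
    """
    lam_m = energy_to_wavelength(energy) * 1e-10
    if not ENERGY_RANGE_KEV[0] <= energy <= ENERGY_RANGE_KEV[1]:
        warnings.warn(f"{energy} keV is outside the {ENERGY_RANGE_KEV} keV "
                      "operating range; far-from-edge delta may degrade")
    rho_e_m3 = BE_DENSITY * N_A * BE_Z / BE_A * 1e6   # electrons / m^3
    return R_E * lam_m ** 2 * rho_e_m3 / (2.0 * math.pi)


@dataclass(frozen=True)
class LensStack:
    """Ordered CRL groups with per-group in/out state.

    ``groups`` is a tuple of (n_lenses, radius_mm); ``state`` flags which
    groups sit in the beam.
    """

    groups: tuple
    state: tuple = None

    def __post_init__(self):
        groups = tuple((int(n), float(r)) for n, r in self.groups)
        for n, r in groups:
            if n <= 0 or r <= 0:
                raise ValueError("lens counts and radii must be positive")
        object.__setattr__(self, "groups", groups)
        state = (tuple(bool(s) for s in self.state) if self.state is not None
                 else (True,) * len(groups))
        if len(state) != len(groups):
            raise ValueError("state must have one flag per group")
        object.__setattr__(self, "state", state)

    @classmethod
    def default_lix(cls, split_large_group: bool = False) -> "LensStack":
        """The default stack: 0.1 mm groups (1, 2, 4, 8, 16, 12) plus four
        0.5 mm lenses — one switchable group by default, or four
        individual groups with ``split_large_group``."""
        groups = [(n, 0.1) for n in (1, 2, 4, 8, 16, 12)]
        if split_large_group:
            groups += [(1, 0.5)] * 4
        else:
            groups += [(4, 0.5)]
        return cls(tuple(groups))

    def with_state(self, state) -> "LensStack":
        return replace(self, state=tuple(bool(s) for s in state))

    @property
    def n_lenses_in(self) -> int:
        return sum(n for (n, _), s in zip(self.groups, self.state) if s)

    @property
    def total_lenses(self) -> int:
        return sum(n for n, _ in self.groups)


@dataclass(frozen=True)
class BeamlineLayout:
    """SSA-to-sample imaging distances (m).

    The CRLs image the SSA (object distance p = ssa_to_sample -
    lens_to_sample) onto the sample (image distance q = lens_to_sample).
    """

    ssa_to_sample: float = 8.0
    lens_to_sample: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.lens_to_sample < self.ssa_to_sample:
            raise ValueError("require 0 < lens_to_sample < ssa_to_sample")

    @property
    def p(self) -> float:
        return self.ssa_to_sample - self.lens_to_sample

    @property
    def q(self) -> float:
        return self.lens_to_sample


def focal_length(stack: LensStack, energy: float) -> float:
    """Combined thin-lens focal length (m) of the in-beam groups.

    1/f = sum over in-beam groups of 2 n delta / R; a single-radius stack
    reduces to f = R / (2 N delta).  All groups out -> +infinity.
    """
    delta = delta_beryllium(energy)
    inv = sum(2.0 * n * delta / (r * 1e-3)
              for (n, r), s in zip(stack.groups, stack.state) if s)
    return math.inf if inv == 0.0 else 1.0 / inv


def demagnification(layout: BeamlineLayout) -> float:
    """Source demagnification ratio p/q of the SSA image at the sample."""
    return layout.p / layout.q


def required_focal_length(layout: BeamlineLayout) -> float:
    """Focal length satisfying the imaging condition 1/p + 1/q = 1/f."""
    return layout.p * layout.q / (layout.p + layout.q)


@dataclass
class SolveResult:
    """Best lens configuration found for one energy/layout."""

    state: tuple
    lens_to_sample: float
    residual: float            # |f_stack - f_required|, m
    f_achieved: float
    f_required: float
    n_lenses: int = field(default=0)


def solve_configuration(energy: float, layout: BeamlineLayout,
                        allow_position_shift: bool = False,
                        stack: LensStack | None = None,
                        position_step: float = 0.001) -> SolveResult:
    """Exhaustive search for the lens state best matching the imaging
    condition.

    All 2^G group states are scored by |f_stack - f_required|; with
    ``allow_position_shift`` the transfocator position is additionally
    scanned on a ``position_step`` (default 1 mm) grid over its travel
    range.  Ties break toward fewer lenses in the beam (less absorption).
    """
    stack = stack or LensStack.default_lix()
    n_groups = len(stack.groups)

    delta = delta_beryllium(energy)
    powers = [2.0 * n * delta / (r * 1e-3) for n, r in stack.groups]

    if allow_position_shift:
        lo, hi = LENS_TRAVEL_M
        n_steps = int(round((hi - lo) / position_step))
        positions = [lo + i * position_step for i in range(n_steps + 1)]
    else:
        positions = [layout.lens_to_sample]

    best = None
    for state in itertools.product((False, True), repeat=n_groups):
        inv = sum(p for p, s in zip(powers, state) if s)
        f = math.inf if inv == 0 else 1.0 / inv
        n_in = sum(n for (n, _), s in zip(stack.groups, state) if s)
        for pos in positions:
            f_req = required_focal_length(
                replace(layout, lens_to_sample=pos))
            resid = abs(f - f_req)
            key = (resid, n_in)
            if best is None or key < best[0]:
                best = (key, state, pos, f, f_req, n_in)
    (_, state, pos, f, f_req, n_in) = best
    return SolveResult(state, pos, abs(f - f_req), f, f_req, n_in)
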