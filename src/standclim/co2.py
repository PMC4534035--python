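"""Atmospheric CO2 effect on water use efficiency.

Rising CO2 lowers stomatal conductance to water vapour while raising the
relative net assimilation rate.  The model carries this into the water
balance as an *adjusted canopy resistance*: relative assimilation A_n(rel)
is a saturating hyperbola of the ambient concentration c_a anchored at a
reference concentration c_a0 and the CO2 compensation point r'
(assimilation is zero at c_a = r'); relative conductance is
g_w(rel) = A_n(rel) / (c_a / c_a0); and the species' reference canopy
resistance is inflated by the fractional conductance loss,

    R_adj = R_ref + R_ref * (1 - g_w(rel)).

At c_a = c_a0 the whole chain is the identity, so the reference climate
is unaffected.  There is no direct CO2 fertilization of growth.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CO2Params:
    """Reference concentration and compensation point (both ppm).

    ``c_a0`` is taken from the reference climate (360 ppm in published
    conductance compilations; 380 ppm for a 2005-pinned reference
    scenario) and is always configurable, never hard-coded.  ``r_prime``
    defaults to the standard 40 ppm compensation point.
    """

    c_a0: float = 380.0
    r_prime: float = 40.0

    def __post_init__(self):
        if not self.c_a0 > self.r_prime > 0:
            raise ValueError("require c_a0 > r_prime > 0")


def relative_assimilation(c_a: float, params: CO2Params, clamp: bool = False) -> float:
    """Relative net assimilation rate at ambient CO2 ``c_a`` (ppm).

    Closed form ``[(c_a - r')(c_a0 + 2r')] / [(c_a + 2r')(c_a0 - r')]``:
    1 at the reference concentration, 0 at the compensation point,
    increasing and saturating in c_a.  With ``clamp`` the (nonphysical)
    negative branch below the compensation point is floored at 0.
    """
    if not c_a > 0:
        raise ValueError("c_a must be > 0")
    r = params.r_prime
    an = ((c_a - r) * (params.c_a0 + 2.0 * r)) / ((c_a + 2.0 * r) * (params.c_a0 - r))
    if clamp and an < 0.0:
        return 0.0
    return an


def relative_conductance(c_a: float, params: CO2Params) -> float:
    """Relative stomatal conductance for water vapour.

    ``g_w(rel) = A_n(rel) / c_a(rel)`` with ``c_a(rel) = c_a / c_a0``;
    equals 1 at the reference concentration and declines as CO2 rises
    beyond it (the assimilation gain saturates while c_a(rel) keeps
    growing).  Assimilation is clamped at zero below the compensation
    point so conductance never goes negative.
    """
    an = relative_assimilation(c_a, params, clamp=True)
    return an / (c_a / params.c_a0)


def adjusted_canopy_resistance(c_a: float, params: CO2Params, r_can_ref: float) -> float:
    """Canopy resistance adjusted for the ambient CO2 concentration.

    ``R_adj = R_ref + R_ref * (1 - g_w(rel))``: equal to the species'
    reference resistance at the reference concentration and increasing
    with CO2 beyond it, which lowers transpiration demand (higher water
    use efficiency).
    """
    if r_can_ref < 0:
        raise ValueError("reference canopy resistance must be >= 0")
    gw = relative_conductance(c_a, params)
    return r_can_ref + r_can_ref * (1.0 - gw)
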