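"""Human physiology for the CAT oral-absorption PBPK model.

Compartment inventory
---------------------
Lumen segments (drug transits in unreleased / undissolved / dissolved
states):  stomach -> duodenum -> jejunum1 -> jejunum2 -> ileum1 -> ileum2
-> ileum3 -> colon -> fecal loss.

Tissues (perfusion-limited): stomach wall, duodenum, jejunum, ileum and
colon walls (absorbing, portal drainage to the liver), liver, kidney,
rest-of-body, plus a central blood compartment.

Scaling
-------
Organ volumes scale linearly with body mass from reference fractions at
70 kg; cardiac output scales allometrically as ``(BW/70)**0.75``; blood-flow
fractions of cardiac output are fixed, so tissue flows always sum to
cardiac output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np

__all__ = ["Physiology", "build_physiology", "LUMEN_SEGMENTS", "TISSUES"]

#: Lumen segments in transit order.
LUMEN_SEGMENTS: Tuple[str, ...] = (
    "stomach",
    "duodenum",
    "jejunum1",
    "jejunum2",
    "ileum1",
    "ileum2",
    "ileum3",
    "colon",
)

#: Tissue compartments in canonical order (gut walls first, portal order).
TISSUES: Tuple[str, ...] = (
    "stomach",
    "duodenum",
    "jejunum",
    "ileum",
    "colon",
    "liver",
    "kidney",
    "rest",
)

#: Which tissue each lumen segment absorbs into.
SEGMENT_TISSUE: Dict[str, str] = {
    "stomach": "stomach",
    "duodenum": "duodenum",
    "jejunum1": "jejunum",
    "jejunum2": "jejunum",
    "ileum1": "ileum",
    "ileum2": "ileum",
    "ileum3": "ileum",
    "colon": "colon",
}

REFERENCE_BODY_MASS = 70.0  # kg
REFERENCE_CARDIAC_OUTPUT = 336.0  # l/h (5.6 l/min) at 70 kg

#: Tissue volumes at 70 kg [l]; rest-of-body closes the balance to 70 l
#: assuming unit density.
_REF_VOLUMES: Dict[str, float] = {
    "stomach": 0.15,
    "duodenum": 0.09,
    "jejunum": 0.28,
    "ileum": 0.21,
    "colon": 0.35,
    "liver": 1.82,
    "kidney": 0.31,
    "rest": 61.59,
}
_REF_BLOOD_VOLUME = 5.2  # l

#: Arterial blood-flow fractions of cardiac output.  The liver additionally
#: receives the portal outflow of the five gut walls; fractions sum to 1.
_FLOW_FRACTIONS: Dict[str, float] = {
    "stomach": 0.011,
    "duodenum": 0.016,
    "jejunum": 0.054,
    "ileum": 0.033,
    "colon": 0.056,
    "liver": 0.065,  # hepatic artery only
    "kidney": 0.190,
    "rest": 0.575,
}

# small-intestine mean transit time 3.32 h over its six segments; gastric
# emptying half-time 0.25 h; colon residence 13.5 h
_SI_TRANSIT_H = 3.32
_GASTRIC_HALF_TIME_H = 0.25
_COLON_TRANSIT_H = 13.5
_K_SI = 6.0 / _SI_TRANSIT_H

#: (radius [cm], fluid volume [l], pH, transit rate [1/h]) per segment.
_REF_SEGMENTS: Dict[str, Tuple[float, float, float, float]] = {
    "stomach": (10.0, 0.25, 1.7, math.log(2.0) / _GASTRIC_HALF_TIME_H),
    "duodenum": (1.6, 0.06, 6.0, _K_SI),
    "jejunum1": (1.5, 0.09, 6.2, _K_SI),
    "jejunum2": (1.5, 0.09, 6.4, _K_SI),
    "ileum1": (1.2, 0.07, 6.8, _K_SI),
    "ileum2": (1.2, 0.07, 7.0, _K_SI),
    "ileum3": (1.2, 0.07, 7.4, _K_SI),
    "colon": (2.5, 0.10, 6.8, 1.0 / _COLON_TRANSIT_H),
}


@dataclass(frozen=True)
class Physiology:
    """Body-mass-scaled volumes, flows and GI geometry.

    Attributes
    ----------
    body_mass : float
        Subject body mass [kg].
    tissue_volumes, tissue_flows : dict
        Per-tissue volume [l] and arterial blood flow [l/h], keyed by
        :data:`TISSUES`.
    blood_volume : float
        Central blood volume [l].
    cardiac_output : float
        Total arterial outflow [l/h]; equals ``sum(tissue_flows.values())``.
    segment_radius, segment_volume, segment_ph, segment_transit : dict
        Lumen geometry [cm, l], luminal pH and transit rate constants [1/h],
        keyed by :data:`LUMEN_SEGMENTS`.
    absorb_from_stomach : bool
        Gastric absorption is off by default; intestinal and colonic
        segments always absorb.
    mppgl : float
        Microsomal protein per gram of liver [mg/g].
    liver_mass_fraction : float
        Liver mass as a fraction of body mass.
    """

    body_mass: float
    tissue_volumes: Dict[str, float]
    tissue_flows: Dict[str, float]
    blood_volume: float
    cardiac_output: float
    segment_radius: Dict[str, float]
    segment_volume: Dict[str, float]
    segment_ph: Dict[str, float]
    segment_transit: Dict[str, float]
    absorb_from_stomach: bool = False
    mppgl: float = 40.0
    liver_mass_fraction: float = 0.026

    def __post_init__(self) -> None:
        for name, v in self.tissue_volumes.items():
            if v <= 0:
                raise ValueError(f"non-positive volume for tissue {name!r}")
        for name, q in self.tissue_flows.items():
            if q <= 0:
                raise ValueError(f"non-positive flow for tissue {name!r}")
        if not math.isclose(
            self.cardiac_output, sum(self.tissue_flows.values()), rel_tol=1e-9
        ):
            raise ValueError("tissue flows must sum to cardiac output")
        for name, ph in self.segment_ph.items():
            if not 1.0 <= ph <= 8.5:
                raise ValueError(f"pH out of range for segment {name!r}: {ph}")
        if any(k <= 0 for k in self.segment_transit.values()):
            raise ValueError("transit rate constants must be > 0")

    @property
    def liver_mass_g(self) -> float:
        return self.liver_mass_fraction * self.body_mass * 1e3

    def with_overrides(self, **kwargs) -> "Physiology":
        """Return a copy with replaced fields (dicts replaced wholesale)."""
        return replace(self, **kwargs)


def build_physiology(body_mass: float) -> "Physiology":
    """Scale the 70-kg reference physiology to ``body_mass``.

    Volumes scale linearly; cardiac output as ``(BW/70)**0.75`` with fixed
    flow fractions.  Deterministic.  Body masses outside the 45-125 kg
    sampling range are accepted with a warning.
    """
    if body_mass <= 0:
        raise ValueError(f"body mass must be positive, got {body_mass}")
    if not 45.0 <= body_mass <= 125.0:
        warnings.warn(
            f"body mass {body_mass} kg outside the sampled 45-125 kg range",
            stacklevel=2,
        )
    scale_v = body_mass / REFERENCE_BODY_MASS
    co = REFERENCE_CARDIAC_OUTPUT * (body_mass / REFERENCE_BODY_MASS) ** 0.75
    flows = {t: f * co for t, f in _FLOW_FRACTIONS.items()}
    # rounding guard: renormalize so flows sum exactly to cardiac output
    total = sum(flows.values())
    flows = {t: q * co / total for t, q in flows.items()}
    return Physiology(
        body_mass=body_mass,
        tissue_volumes={t: v * scale_v for t, v in _REF_VOLUMES.items()},
        tissue_flows=flows,
        blood_volume=_REF_BLOOD_VOLUME * scale_v,
        cardiac_output=co,
        segment_radius={s: r for s, (r, _, _, _) in _REF_SEGMENTS.items()},
        segment_volume={s: v * scale_v for s, (_, v, _, _) in _REF_SEGMENTS.items()},
        segment_ph={s: ph for s, (_, _, ph, _) in _REF_SEGMENTS.items()},
        segment_transit={s: k for s, (_, _, _, k) in _REF_SEGMENTS.items()},
    )
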