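"""Sampling ranges for virtual-drug properties.

Each virtual drug is a point in a box of drug-specific and regimen-specific
quantities.  The default box is a literature-derived set of ranges spanning
all four Biopharmaceutics Classification System (BCS) classes:

===========================  =============  ==========================================
quantity                     range          units
===========================  =============  ==========================================
molecular_mass               20 - 1700      g/gmol
molar_volume                 30 - 1200      ml/gmol
pka                          0 - 14         (acidic dissociation constant)
particle_radius              5 - 50         um
drug_density                 0.1 - 0.7      g/ml
solubility                   0.001 - 1000   mg/ml (intrinsic aqueous solubility)
precipitation_rate           0.01 - 1       1/h
effective_permeability       0.015 - 8      1e-4 cm/s (human jejunal Peff scale)
fupc                         0.01 - 100     unbound fraction / partition coefficient,
                                            sampled independently per tissue
body_mass                    45 - 125       kg
dose                         1e3 - 50e3     umol
km                           0.04 - 10      mM
vmax                         1e-6 - 1e-2    umol/(min * mg microsomal protein)
===========================  =============  ==========================================

Effective permeability is stored in multiples of 1e-4 cm/s: human jejunal
permeabilities are of order 0.1-10 x 1e-4 cm/s, so the 0.015-8 range is read
on that scale.  Molar volume is in ml/gmol, the unit required by the
diffusion-coefficient correlation.
"""

from __future__ import annotations

from typing import Dict, Tuple

from pydantic import BaseModel, model_validator


class ConfigurationError(Exception):
    """Raised for invalid sampling or pipeline configuration.

    Deliberately not a ValueError subclass so it escapes pydantic's
    validation-error wrapping and surfaces with the offending parameter
    named.
    """


#: Tissues carrying an independent FuPC value, in canonical order.  The gut
#: tissues (stomach..colon) drain to the liver via the portal vein in the
#: PBPK model; liver, kidney and rest-of-body are systemic.
FUPC_TISSUES: Tuple[str, ...] = (
    "stomach",
    "duodenum",
    "jejunum",
    "ileum",
    "colon",
    "liver",
    "kidney",
    "rest",
)

#: Canonical feature column order used by every downstream stage.
FEATURE_COLUMNS: Tuple[str, ...] = (
    "molecular_mass",
    "molar_volume",
    "pka",
    "particle_radius",
    "drug_density",
    "solubility",
    "precipitation_rate",
    "effective_permeability",
    *(f"fupc_{t}" for t in FUPC_TISSUES),
    "body_mass",
    "dose",
    "km",
    "vmax",
)

#: Normalized summary-PK-metric label columns.
LABEL_COLUMNS: Tuple[str, ...] = ("cmax_over_dose", "tmax", "auc_over_dose")

Bounds = Tuple[float, float]


class ParameterRanges(BaseModel):
    """(low, high) sampling bounds for every virtual-drug quantity.

    The single ``fupc`` range applies independently to each tissue in
    :data:`FUPC_TISSUES`.  All lows must be strictly positive except ``pka``
    (which may start at 0), and low < high for every pair.
    """

    molecular_mass: Bounds = (20.0, 1700.0)
    molar_volume: Bounds = (30.0, 1200.0)
    pka: Bounds = (0.0, 14.0)
    particle_radius: Bounds = (5.0, 50.0)
    drug_density: Bounds = (0.1, 0.7)
    solubility: Bounds = (0.001, 1000.0)
    precipitation_rate: Bounds = (0.01, 1.0)
    effective_permeability: Bounds = (0.015, 8.0)
    fupc: Bounds = (0.01, 100.0)
    body_mass: Bounds = (45.0, 125.0)
    dose: Bounds = (1e3, 50e3)
    km: Bounds = (0.04, 10.0)
    vmax: Bounds = (1e-6, 1e-2)
    #: sample on a log-uniform scale instead of linear-uniform (off by
    #: default: the reference conditions are uniform on the linear scale,
    #: even for quantities spanning several decades)
    log_uniform: bool = False

    @model_validator(mode="after")
    def _check_bounds(self) -> "ParameterRanges":
        for name, (low, high) in self.bounds().items():
            if not low < high:
                raise ConfigurationError(
                    f"invalid range for {name!r}: low={low} must be < high={high}"
                )
            floor = 0.0 if name == "pka" else None
            if floor is not None:
                if low < floor:
                    raise ConfigurationError(f"{name!r} low must be >= 0, got {low}")
            elif low <= 0:
                raise ConfigurationError(f"{name!r} low must be > 0, got {low}")
        return self

    def bounds(self) -> Dict[str, Bounds]:
        """Bounds for each sampled quantity (single ``fupc`` entry)."""
        return {
            name: tuple(getattr(self, name))
            for name in type(self).model_fields
            if name != "log_uniform"
        }

    def feature_bounds(self) -> Dict[str, Bounds]:
        """Bounds keyed by feature column, fupc expanded per tissue."""
        out: Dict[str, Bounds] = {}
        for name, b in self.bounds().items():
            if name == "fupc":
                for t in FUPC_TISSUES:
                    out[f"fupc_{t}"] = b
            else:
                out[name] = b
        return out
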