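"""Virtual-drug library generation, BCS classification, real-drug matching.

The library is a :class:`pandas.DataFrame` with one row per virtual drug,
an ``id`` column, the canonical feature columns of
:data:`pkdistill.ranges.FEATURE_COLUMNS`, and a ``bcs_class`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .ranges import (
    FEATURE_COLUMNS,
    FUPC_TISSUES,
    ConfigurationError,
    ParameterRanges,
)

__all__ = [
    "sample_virtual_drugs",
    "classify_bcs",
    "match_real_drugs",
    "MatchReport",
    "DEFAULT_SOLUBILITY_THRESHOLD",
    "DEFAULT_PERMEABILITY_THRESHOLD",
]

#: Default BCS cut points.  Solubility above 250 mg/ml counts as "high",
#: effective permeability above 3.5 (in 1e-4 cm/s) counts as "high".
DEFAULT_SOLUBILITY_THRESHOLD = 250.0
DEFAULT_PERMEABILITY_THRESHOLD = 3.5

#: The six physicochemical properties used for real-drug matching.
MATCH_PROPERTIES = (
    "molecular_mass",
    "density",
    "molar_volume",
    "pka",
    "solubility",
    "effective_permeability",
)


def sample_virtual_drugs(
    ranges: Optional[ParameterRanges] = None,
    n: int = 15_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n`` virtual drugs by uniform Monte Carlo sampling.

    Every quantity is drawn independently and uniformly from its configured
    range (log-uniformly if ``ranges.log_uniform``); each tissue's FuPC is an
    independent draw from the shared fupc range.  Identical
    ``(ranges, n, seed)`` produce an identical library.

    Parameters
    ----------
    ranges
        Sampling box; defaults to the literature-derived ranges.
    n
        Library size (>= 1).
    seed
        Seed for the underlying PCG64 generator.

    Returns
    -------
    DataFrame with columns ``id``, the canonical features, and ``bcs_class``
    assigned with the default thresholds.
    """
    ranges = ranges or ParameterRanges()
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    data: Dict[str, np.ndarray] = {}
    for name in FEATURE_COLUMNS:
        low, high = ranges.feature_bounds()[name]
        if ranges.log_uniform and low > 0:
            data[name] = np.exp(rng.uniform(np.log(low), np.log(high), size=n))
        else:
            data[name] = rng.uniform(low, high, size=n)
    lib = pd.DataFrame(data, columns=list(FEATURE_COLUMNS))
    lib.insert(0, "id", [f"vd{i:06d}" for i in range(n)])
    lib["bcs_class"] = classify_bcs(lib)
    return lib


def classify_bcs(
    drugs: pd.DataFrame,
    solubility_threshold: float = DEFAULT_SOLUBILITY_THRESHOLD,
    permeability_threshold: float = DEFAULT_PERMEABILITY_THRESHOLD,
) -> pd.Series:
    """Assign BCS classes from solubility/permeability thresholds.

    "High" means strictly greater than the threshold; a value exactly at the
    threshold is "low".  Class I = high/high, II = low solubility & high
    permeability, III = high solubility & low permeability, IV = low/low.
    """
    high_sol = drugs["solubility"].to_numpy() > solubility_threshold
    high_perm = drugs["effective_permeability"].to_numpy() > permeability_threshold
    cls = np.where(
        high_perm,
        np.where(high_sol, "I", "II"),
        np.where(high_sol, "III", "IV"),
    )
    return pd.Series(cls, index=drugs.index, name="bcs_class")


@dataclass
class MatchReport:
    """Representativeness of the virtual library against real drugs.

    A virtual drug matches a real drug at tolerance ``t`` iff
    ``|v_p - r_p| <= t * r_p`` simultaneously for all six properties in
    :data:`MATCH_PROPERTIES`.  ``close_frac`` is the fraction of real drugs
    with at least one close match, ``any_frac`` with at least one match at
    the moderate tolerance (close matches are a subset of moderate ones).
    """

    per_drug: pd.DataFrame = field(repr=False)
    close_frac: float = 0.0
    any_frac: float = 0.0


def match_real_drugs(
    real_drugs: pd.DataFrame,
    virtual: pd.DataFrame,
    close_tol: float = 0.15,
    moderate_tol: float = 0.50,
) -> MatchReport:
    """Grade each real drug's best match in the virtual library.

    ``real_drugs`` must carry the six :data:`MATCH_PROPERTIES` columns
    (case-insensitive; ``density`` maps onto the library's ``drug_density``).
    The best match is the virtual drug minimizing the worst-case relative
    difference across the six properties.
    """
    if close_tol > moderate_tol:
        raise ConfigurationError("close_tol must be <= moderate_tol")
    colmap = {c.lower(): c for c in real_drugs.columns}
    missing = [p for p in MATCH_PROPERTIES if p not in colmap]
    if missing:
        raise ValueError(f"real-drug table is missing columns: {missing}")
    real = real_drugs[[colmap[p] for p in MATCH_PROPERTIES]].to_numpy(float)
    vcols = ["drug_density" if p == "density" else p for p in MATCH_PROPERTIES]
    virt = virtual[vcols].to_numpy(float)

    rows: List[dict] = []
    for i in range(real.shape[0]):
        r = real[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(virt - r) / np.abs(r)
        rel = np.where(np.isnan(rel), np.where(np.abs(virt - r) == 0, 0.0, np.inf), rel)
        worst = rel.max(axis=1)
        j = int(np.argmin(worst))
        w = float(worst[j])
        grade = "close" if w <= close_tol else "moderate" if w <= moderate_tol else "none"
        rows.append(
            {
                "best_match_id": virtual["id"].iloc[j],
                "worst_rel_diff": w,
                "match_grade": grade,
            }
        )
    per_drug = pd.DataFrame(rows, index=real_drugs.index)
    n = len(per_drug)
    close = float((per_drug["match_grade"] == "close").sum()) / n
    anym = float((per_drug["match_grade"] != "none").sum()) / n
    return MatchReport(per_drug=per_drug, close_frac=close, any_frac=anym)
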