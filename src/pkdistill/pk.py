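"""Summary PK metrics (SPKMs) and ML dataset assembly.

Each simulated blood concentration-time profile is condensed into three
dose-normalized summary metrics: Cmax/dose, tmax and AUC/dose.  AUC is the
trapezoidal area over the full output grid (0 to t_end, no extrapolation to
infinity); tmax ties break to the earliest time.  The metrics are min-max
scaled over the complete dataset before any train/test split, and the
scaler is retained so surrogate predictions can be mapped back to raw
units.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .cat import SimulationResult
from .ranges import FEATURE_COLUMNS, LABEL_COLUMNS

__all__ = [
    "SPKMRecord",
    "NormalizationScaler",
    "compute_spkm",
    "minmax_normalize",
    "assemble_dataset",
]

logger = logging.getLogger(__name__)

#: warn when the tail beyond t_end would plausibly add this fraction to AUC
_TAIL_FRACTION_WARN = 0.05


@dataclass
class SPKMRecord:
    """Raw (and optionally normalized) summary PK metrics for one drug."""

    drug_id: str
    cmax_over_dose: float  # (umol/l)/umol
    tmax: float  # h
    auc_over_dose: float  # (umol*h/l)/umol
    degenerate: bool = False  # all-zero profile despite a positive dose

    def as_dict(self) -> Dict[str, float]:
        return {
            "cmax_over_dose": self.cmax_over_dose,
            "tmax": self.tmax,
            "auc_over_dose": self.auc_over_dose,
        }


def compute_spkm(result: SimulationResult, dose: float) -> SPKMRecord:
    """Extract Cmax/dose, tmax and AUC/dose from a simulation.

    Cmax is the grid maximum of the blood concentration, tmax the earliest
    time attaining it, and AUC the trapezoidal integral over the whole
    grid.  An all-zero profile with a positive dose is returned flagged as
    degenerate rather than raised.
    """
    if dose <= 0:
        raise ValueError("dose must be positive to normalize SPKMs")
    conc = np.asarray(result.blood_conc, dtype=float)
    times = np.asarray(result.times, dtype=float)
    if conc.size == 0:
        raise ValueError("empty blood concentration series")
    i_max = int(np.argmax(conc))  # argmax returns the first maximum
    cmax = float(conc[i_max])
    tmax = float(times[i_max])
    auc = float(np.trapezoid(conc, times))
    if cmax > 0 and conc[-1] * times[-1] > _TAIL_FRACTION_WARN * auc:
        logger.warning(
            "drug %s: concentration at t_end is large relative to AUC; "
            "the truncated AUC may understate exposure",
            result.drug_id,
        )
    return SPKMRecord(
        drug_id=result.drug_id,
        cmax_over_dose=cmax / dose,
        tmax=tmax,
        auc_over_dose=auc / dose,
        degenerate=(cmax == 0.0),
    )


@dataclass
class NormalizationScaler:
    """Per-metric (min, max) pairs for min-max scaling to [0, 1]."""

    bounds: Dict[str, Tuple[float, float]]

    def normalize(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col, (lo, hi) in self.bounds.items():
            out[col] = (df[col] - lo) / (hi - lo)
        return out

    def denormalize(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col, (lo, hi) in self.bounds.items():
            out[col] = df[col] * (hi - lo) + lo
        return out

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {c: {"min": lo, "max": hi} for c, (lo, hi) in self.bounds.items()}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "NormalizationScaler":
        payload = json.loads(Path(path).read_text())
        return cls({c: (d["min"], d["max"]) for c, d in payload.items()})


def minmax_normalize(
    records: Sequence[SPKMRecord],
) -> Tuple[pd.DataFrame, NormalizationScaler]:
    """Min-max scale the three SPKMs over the full record set.

    The extrema are taken over the complete dataset, before any train/test
    split, and returned in the scaler for inverse transforms.  A metric
    with zero spread cannot be scaled and raises.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to normalize")
    raw = pd.DataFrame(
        [r.as_dict() for r in records],
        index=pd.Index([r.drug_id for r in records], name="id"),
    )
    bounds: Dict[str, Tuple[float, float]] = {}
    for col in LABEL_COLUMNS:
        lo, hi = float(raw[col].min()), float(raw[col].max())
        if not lo < hi:
            raise ValueError(f"SPKM {col!r} is constant; cannot min-max scale")
        bounds[col] = (lo, hi)
    scaler = NormalizationScaler(bounds)
    return scaler.normalize(raw), scaler


def assemble_dataset(
    drugs: pd.DataFrame,
    records: Iterable[SPKMRecord],
) -> Tuple[pd.DataFrame, NormalizationScaler]:
    """Join virtual-drug features with their normalized SPKM labels.

    Records flagged degenerate (failed or all-zero simulations) are dropped
    with a logged count; remaining record ids must be a subset of the drug
    library's ids.  Returns the modelling table (feature columns then the
    three normalized label columns, indexed by id) and the fitted scaler.
    """
    records = list(records)
    if not records:
        raise ValueError("no SPKM records supplied")
    kept = [r for r in records if not r.degenerate]
    dropped = len(records) - len(kept)
    if dropped:
        logger.warning("dropping %d degenerate simulation(s) from dataset", dropped)
    if not kept:
        raise ValueError("all SPKM records are degenerate")
    drug_ids = set(drugs["id"])
    orphans = [r.drug_id for r in kept if r.drug_id not in drug_ids]
    if orphans:
        raise ValueError(f"SPKM records with no matching drug: {orphans[:5]}")
    labels, scaler = minmax_normalize(kept)
    feats = drugs.set_index("id").loc[labels.index, list(FEATURE_COLUMNS)]
    dataset = pd.concat([feats, labels], axis=1)
    return dataset, scaler
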