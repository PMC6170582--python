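"""Allometric body-mass estimation from femoral least-shaft circumference.

Uses the Campbell-Marcus avian regression

    log10 M = 2.411 * log10 LCF - 0.065

with M the body mass in grams and LCF the least circumference of the
femoral shaft in mm (measurement code F3, the circumference at minimum
midshaft width).  Masses are carried in grams internally and converted to
kg for presentation; rounding to the nearest kg happens only at reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CAMPBELL_MARCUS_SLOPE = 2.411
CAMPBELL_MARCUS_INTERCEPT = -0.065

#: Femoral least-shaft circumference measurement code.
LCF_CODE = "F3"


@dataclass(frozen=True)
class MassEstimate:
    circumference_mm: float
    mass_g: float

    @property
    def mass_kg(self) -> float:
        return self.mass_g / 1000.0

    @property
    def mass_kg_rounded(self) -> int:
        return int(round(self.mass_kg))


def mass_from_circumference(lcf_mm: float) -> MassEstimate:
    """Body mass from femoral least-shaft circumference (mm)."""
    if not np.isfinite(lcf_mm) or lcf_mm <= 0:
        raise ValueError(f"circumference must be positive, got {lcf_mm!r}")
    log_mass = CAMPBELL_MARCUS_SLOPE * np.log10(lcf_mm) + CAMPBELL_MARCUS_INTERCEPT
    return MassEstimate(circumference_mm=float(lcf_mm), mass_g=float(10.0**log_mass))


def specimen_masses(
    f3_values: pd.Series, observed_mask: pd.Series | None = None
) -> pd.DataFrame:
    """Per-specimen masses from F3 values; ``observed`` marks cells that
    were measured rather than imputed."""
    rows = []
    for sid, value in f3_values.dropna().items():
        est = mass_from_circumference(float(value))
        rows.append(
            {
                "specimen_id": sid,
                "lcf_mm": est.circumference_mm,
                "mass_kg": est.mass_kg,
                "observed": True if observed_mask is None else bool(observed_mask.get(sid, False)),
            }
        )
    return pd.DataFrame(rows, columns=["specimen_id", "lcf_mm", "mass_kg", "observed"])


def summarize_cluster_masses(
    labels: pd.Series,
    f3_values: pd.Series,
    observed_mask: pd.Series | None = None,
    include_imputed: bool = False,
) -> pd.DataFrame:
    """Per-cluster min/max/mean/sd/n of estimated mass (kg).

    Only observed (non-imputed) F3 cells enter the summary unless
    ``include_imputed`` is set.  Clusters without a usable F3 value are
    omitted.  Single-specimen clusters report sd = 0 by convention (flagged
    by n = 1).
    """
    masses = specimen_masses(f3_values, observed_mask)
    if not include_imputed:
        masses = masses[masses["observed"]]
    masses = masses.set_index("specimen_id")
    rows = []
    for cluster in sorted(labels.dropna().unique(), key=str):
        members = labels.index[labels == cluster]
        kg = masses.loc[masses.index.intersection(members), "mass_kg"]
        if kg.empty:
            continue
        rows.append(
            {
                "cluster": cluster,
                "min_kg": kg.min(),
                "max_kg": kg.max(),
                "mean_kg": kg.mean(),
                "sd_kg": kg.std(ddof=1) if len(kg) > 1 else 0.0,
                "n": len(kg),
            }
        )
    return pd.DataFrame(rows, columns=["cluster", "min_kg", "max_kg", "mean_kg", "sd_kg", "n"])
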