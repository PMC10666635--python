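"""Normalized translational efficiencies from reporter-enzyme measurements.

A double-reporter construct yields, per biological replicate, a specific
reporter enzyme activity (kat/mg protein) and a relative transcript level
(Northern signal normalized to 16S rRNA).  Translational efficiency is the
background-subtracted activity divided by the transcript level; construct
means are then normalized to the wildtype construct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ReporterMeasurement",
    "translational_efficiency",
    "normalize_to_wildtype",
    "summarize_efficiencies",
]


@dataclass(frozen=True, slots=True)
class ReporterMeasurement:
    construct_id: str
    specific_activity: float  # kat per mg protein
    transcript_level: float  # dimensionless, normalized to 16S rRNA
    replicate: int


def translational_efficiency(
    m: ReporterMeasurement, control_activity: float
) -> float:
    """(activity − empty-vector control) / transcript level.

    May be negative when the activity falls below the control; reported as
    is, never clipped.
    """
    if m.transcript_level <= 0:
        raise ValueError(
            f"construct {m.construct_id!r}: transcript level must be positive, "
            f"got {m.transcript_level}"
        )
    return (m.specific_activity - control_activity) / m.transcript_level


def normalize_to_wildtype(
    efficiencies: Mapping[str, float], wildtype_id: str
) -> dict[str, float]:
    """Divide per-construct mean efficiencies by the wildtype's (wildtype → 1.0)."""
    if wildtype_id not in efficiencies:
        raise KeyError(f"wildtype construct {wildtype_id!r} missing")
    wt = efficiencies[wildtype_id]
    if wt == 0:
        raise ValueError("wildtype efficiency is zero; cannot normalize")
    return {cid: value / wt for cid, value in efficiencies.items()}


def summarize_efficiencies(
    measurements: Iterable[ReporterMeasurement] | pd.DataFrame,
    control_id: str,
    wildtype_id: str,
) -> pd.DataFrame:
    """Per-construct mean and sample SD of wildtype-normalized efficiencies.

    The empty-vector control's mean activity is subtracted from every
    activity (control subtraction applies to activities only, not transcript
    levels); per-replicate efficiencies are averaged per construct and the
    means divided by the wildtype mean.  SDs are computed on the normalized
    replicate values (normalization is a constant rescaling, so averaging
    before or after normalizing gives identical means).
    """
    if isinstance(measurements, pd.DataFrame):
        measurements = [
            ReporterMeasurement(
                construct_id=str(row.construct_id),
                specific_activity=float(row.specific_activity),
                transcript_level=float(row.transcript_level),
                replicate=int(row.replicate),
            )
            for row in measurements.itertuples(index=False)
        ]
    else:
        measurements = list(measurements)
    control = [m for m in measurements if m.construct_id == control_id]
    if not control:
        raise KeyError(f"control construct {control_id!r} missing")
    control_activity = float(np.mean([m.specific_activity for m in control]))

    per_construct: dict[str, list[float]] = {}
    for m in measurements:
        if m.construct_id == control_id:
            continue
        per_construct.setdefault(m.construct_id, []).append(
            translational_efficiency(m, control_activity)
        )
    means = {cid: float(np.mean(v)) for cid, v in per_construct.items()}
    normalized_means = normalize_to_wildtype(means, wildtype_id)
    wt_mean = means[wildtype_id]
    rows = []
    for cid in sorted(per_construct):
        norm_values = np.array(per_construct[cid]) / wt_mean
        rows.append(
            {
                "construct_id": cid,
                "mean_norm_eff": normalized_means[cid],
                "sd": float(np.std(norm_values, ddof=1)) if len(norm_values) > 1 else 0.0,
                "n_replicates": len(norm_values),
            }
        )
    return pd.DataFrame(rows, columns=["construct_id", "mean_norm_eff", "sd", "n_replicates"])
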