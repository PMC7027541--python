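"""Local sensitivity of time-to-peak Syk activity to copy-number changes.

Each protein copy number is perturbed one at a time by a fixed fraction
above and below its baseline and the model re-simulated.  The score

    score = (O_a - O_i) / O_a

compares the altered time-to-peak ``O_a`` against the baseline ``O_i``;
a positive score means the perturbation delayed the peak, a negative
score that it brought the peak forward.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import SimulationError
from .model_core import (
    PlateletModel,
    RateParameters,
    build_model,
    simulate,
    time_to_peak,
)

__all__ = [
    "SensitivityRecord",
    "sensitivity_score",
    "local_scan",
    "scan_to_frame",
    "SCANNED_PROTEINS",
]

SCANNED_PROTEINS = ("gpvi", "syk", "cbl", "tula2")

#: Scores below this magnitude are reported as "insensitive" in summaries.
INSENSITIVE_THRESHOLD = 0.05


def sensitivity_score(o_altered: float, o_initial: float) -> float:
    """``(O_a - O_i) / O_a`` for altered and baseline times-to-peak."""
    if o_altered <= 0:
        raise ValueError(f"altered time-to-peak must be > 0 s, got {o_altered}")
    return (o_altered - o_initial) / o_altered


@dataclass(frozen=True)
class SensitivityRecord:
    protein: str
    direction: str  # "+50%" / "-50%" (or the configured fraction)
    o_initial_s: float
    o_altered_s: float
    score: float
    failed: bool = False

    @property
    def insensitive(self) -> bool:
        return abs(self.score) < INSENSITIVE_THRESHOLD


def local_scan(
    model: PlateletModel,
    rates: RateParameters | None = None,
    fraction: float = 0.5,
    t_end: float = 120.0,
    dt_out: float = 0.1,
) -> list[SensitivityRecord]:
    """Perturb each protein by ``+/-fraction`` and score the peak shift.

    All other proteins stay at baseline.  A perturbed run that fails to
    integrate yields a flagged record (score NaN) and the scan continues.
    """
    if not (0 <= fraction < 1):
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    rates = rates or model.rates
    baseline = build_model(model.copy_numbers, rates, model.ligand_dose_ug_ml)
    o_i = time_to_peak(simulate(baseline, t_end=t_end, dt_out=dt_out))

    records = []
    for protein in SCANNED_PROTEINS:
        for sign, tag in ((+1, f"+{fraction:.0%}"), (-1, f"-{fraction:.0%}")):
            copies = getattr(model.copy_numbers, protein) * (1 + sign * fraction)
            cn = model.copy_numbers.with_copies(**{protein: copies})
            perturbed = build_model(cn, rates, model.ligand_dose_ug_ml)
            try:
                o_a = time_to_peak(simulate(perturbed, t_end=t_end, dt_out=dt_out))
            except SimulationError:
                records.append(
                    SensitivityRecord(protein, tag, o_i, float("nan"),
                                      float("nan"), failed=True)
                )
                continue
            records.append(
                SensitivityRecord(protein, tag, o_i, o_a, sensitivity_score(o_a, o_i))
            )
    return records


def scan_to_frame(records: list[SensitivityRecord]) -> pd.DataFrame:
    """Delimited-export payload (protein, direction, O_i, O_a, score)."""
    return pd.DataFrame(
        {
            "protein": [r.protein for r in records],
            "direction": [r.direction for r in records],
            "o_initial_s": [r.o_initial_s for r in records],
            "o_altered_s": [r.o_altered_s for r in records],
            "score": [r.score for r in records],
        }
    )
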