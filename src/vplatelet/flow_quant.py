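"""Copy-number quantification from calibration-bead standard curves.

Beads of known antigen binding capacity (ABC, antibody-binding sites per
bead) are stained alongside the platelets; the geometric mean
fluorescence of each bead population against its ABC gives a linear
standard curve, ``MFI = slope * ABC + intercept``.  Platelet MFI values
are then inverted through the curve — after subtracting the matched IgG
isotype-control MFI — to give antibody-binding sites, i.e. protein
copies per platelet.  Dividing by the platelet volume converts copies to
a per-volume density for cross-species comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, SaturationError

__all__ = [
    "BeadPanel",
    "CalibrationCurve",
    "CopyNumberEstimate",
    "fit_calibration",
    "mfi_to_copies",
    "surface_density",
    "compare_to_reference",
    "read_bead_panel",
    "read_platelet_records",
]

R2_THRESHOLD = 0.95


@dataclass(frozen=True)
class BeadPanel:
    """Calibration-bead records: ABC (sites/bead) vs geometric-mean MFI."""

    abc: np.ndarray
    mfi: np.ndarray

    def __post_init__(self) -> None:
        abc = np.asarray(self.abc, dtype=float)
        mfi = np.asarray(self.mfi, dtype=float)
        object.__setattr__(self, "abc", abc)
        object.__setattr__(self, "mfi", mfi)
        if abc.shape != mfi.shape or abc.ndim != 1:
            raise ConfigurationError("abc and mfi must be 1-D arrays of equal length")
        if np.unique(abc).size < 2:
            raise ConfigurationError(
                "bead panel needs at least 2 distinct ABC levels"
            )
        if np.any(abc <= 0):
            raise ConfigurationError("ABC values must be strictly positive")
        if np.any(mfi < 0):
            raise ConfigurationError("MFI values must be non-negative")

    def __len__(self) -> int:
        return int(self.abc.size)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted standard curve ``MFI = slope * ABC + intercept`` with R^2."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int = 0
    metadata: dict = field(default_factory=dict)

    def predict(self, abc: float) -> float:
        return self.slope * np.asarray(abc) + self.intercept


def fit_calibration(
    panel: BeadPanel, r2_threshold: float = R2_THRESHOLD
) -> CalibrationCurve:
    """Ordinary least squares of MFI on ABC.

    Bead saturation is confirmed by the goodness of fit: an R^2 below
    ``r2_threshold`` raises :class:`SaturationError` (an unsaturated or
    degenerate panel does not define a usable standard curve).
    """
    fit = stats.linregress(panel.abc, panel.mfi)
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0
    if r2 < r2_threshold:
        raise SaturationError(
            f"standard curve R^2 = {r2:.4f} below acceptance threshold "
            f"{r2_threshold}; bead staining not saturated or panel degenerate"
        )
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        n_points=len(panel),
    )


def mfi_to_copies(
    curve: CalibrationCurve, platelet_mfi: float, control_mfi: float = 0.0
) -> float:
    """Invert the standard curve for one platelet MFI measurement.

    ``copies = (platelet_mfi - control_mfi - intercept) / slope``,
    floored at zero.  The isotype-control MFI is subtracted first to
    remove non-specific antibody binding.
    """
    if curve.slope <= 0:
        raise ConfigurationError(
            f"standard curve slope must be > 0 (got {curve.slope}); "
            "refit the bead panel"
        )
    copies = (platelet_mfi - control_mfi - curve.intercept) / curve.slope
    return max(0.0, float(copies))


def surface_density(copies: float, volume_fl: float) -> float:
    """Protein density in copies per femtolitre of platelet volume."""
    if volume_fl <= 0:
        raise ConfigurationError(f"volume must be > 0 fL, got {volume_fl}")
    if copies < 0:
        raise ConfigurationError(f"copies must be >= 0, got {copies}")
    return copies / volume_fl


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Replicate-aggregated copy-number estimate for one protein."""

    protein: str
    copies_mean: float
    copies_sd: float | None
    density_per_fl: float
    control_mfi: float
    n_replicates: int

    @classmethod
    def from_replicates(
        cls,
        protein: str,
        curve: CalibrationCurve,
        platelet_mfis,
        control_mfi: float,
        volume_fl: float,
    ) -> "CopyNumberEstimate":
        copies = np.array(
            [mfi_to_copies(curve, m, control_mfi) for m in np.atleast_1d(platelet_mfis)]
        )
        mean = float(copies.mean())
        sd = float(copies.std(ddof=1)) if copies.size > 1 else None
        return cls(
            protein=protein,
            copies_mean=mean,
            copies_sd=sd,
            density_per_fl=surface_density(mean, volume_fl),
            control_mfi=control_mfi,
            n_replicates=int(copies.size),
        )


def compare_to_reference(
    estimates: list[CopyNumberEstimate] | dict,
    reference: dict,
    fold_limit: float = 2.0,
) -> pd.DataFrame:
    """Ratio of each estimate to a published reference copy number.

    ``reference`` maps protein name to copies/platelet (e.g. a proteomic
    dataset).  Proteins missing from the reference are excluded with a
    warning column rather than an error.  The ``within_fold`` flag marks
    ratios inside ``[1/fold_limit, fold_limit]``.
    """
    if isinstance(estimates, dict):
        est_map = dict(estimates)
    else:
        est_map = {e.protein: e.copies_mean for e in estimates}
    rows = []
    for protein, value in est_map.items():
        ref = reference.get(protein)
        if ref is None or ref <= 0:
            rows.append(
                {"protein": protein, "estimate": value, "reference": np.nan,
                 "ratio": np.nan, "within_fold": None, "matched": False}
            )
            continue
        ratio = value / ref
        rows.append(
            {"protein": protein, "estimate": value, "reference": ref,
             "ratio": ratio,
             "within_fold": bool(1.0 / fold_limit <= ratio <= fold_limit),
             "matched": True}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def read_bead_panel(path) -> BeadPanel:
    """Read a bead panel from delimited text with columns ``abc,mfi``."""
    df = pd.read_csv(path)
    missing = {"abc", "mfi"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"bead panel file missing columns {sorted(missing)}")
    return BeadPanel(abc=df["abc"].to_numpy(), mfi=df["mfi"].to_numpy())


def read_platelet_records(path) -> pd.DataFrame:
    """Read platelet MFI records.

    Expected columns: ``sample_id,antibody,mfi,control_mfi,volume_fl``;
    extra columns pass through untouched.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "antibody", "mfi", "control_mfi", "volume_fl"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(
            f"platelet record file missing columns {sorted(missing)}"
        )
    return df
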