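"""Synthetic-data generators with known ground truth.

Every wet-lab input the analysis consumes has a generator here: SMLM
localization fields (Gaussian blob clusters over a uniform background,
log-normal photon counts), calibration-bead panels (linear ABC response
with multiplicative noise), and unimodal signalling time courses
(log-normal-shaped peaks with multiplicative noise, for exercising
time-to-peak extraction on blot-like samplings).  Generators are
seed-deterministic and always emit their truth tables alongside the
data, so recovery tests can compare estimate against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .flow_quant import BeadPanel
from .model_core import TimeCourse
from .smlm import LocalizationTable

__all__ = [
    "FieldSpec",
    "NoisySignalSpec",
    "gen_localizations",
    "gen_bead_panel",
    "gen_timecourse",
]


@dataclass(frozen=True)
class FieldSpec:
    """Specification of one synthetic SMLM field of view.

    The field is a square ROI of ``roi_area_um2``.  Cluster centers are
    uniform in the ROI (kept at least ``min_separation_factor *
    cluster_sd_nm`` apart in the default well-separated mode; set the
    factor to 0 for the hard mode that allows overlaps), detections are
    isotropic Gaussians around their center with counts Poisson around
    ``detections_per_cluster``, background detections are uniform at
    ``background_rate_per_um2``, and photon counts are log-normal with
    the given median and log-sigma so that a 500-photon filter removes a
    nontrivial fraction.
    """

    roi_area_um2: float = 12.0
    n_clusters: int = 30
    detections_per_cluster: float = 60.0
    cluster_sd_nm: float = 10.0
    background_rate_per_um2: float = 2.0
    photon_median: float = 1000.0
    photon_sigma: float = 0.5
    min_separation_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_area_um2 <= 0:
            raise ConfigurationError("ROI area must be > 0 um^2")
        for name in ("n_clusters", "detections_per_cluster",
                     "background_rate_per_um2", "cluster_sd_nm",
                     "photon_median", "photon_sigma", "min_separation_factor"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def _draw_centers(rng, spec: FieldSpec, side_nm: float) -> np.ndarray:
    min_sep = spec.min_separation_factor * spec.cluster_sd_nm
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < spec.n_clusters:
        c = rng.uniform(0.0, side_nm, size=2)
        if min_sep > 0 and any(np.hypot(*(c - o)) < min_sep for o in centers):
            attempts += 1
            if attempts > 10000:
                raise ConfigurationError(
                    f"cannot place {spec.n_clusters} centers with separation "
                    f">= {min_sep} nm in a {side_nm:.0f} nm field"
                )
            continue
        centers.append(c)
    return np.array(centers).reshape(-1, 2)


def gen_localizations(spec: FieldSpec) -> tuple[LocalizationTable, pd.DataFrame]:
    """Generate a localization field plus its ground-truth table.

    Returns ``(table, truth)`` where ``truth`` has one row per detection
    with a ``source`` column: the cluster index for cluster detections,
    -1 for background.  The truth table also records the generator seed.
    """
    rng = np.random.default_rng(spec.seed)
    side_nm = float(np.sqrt(spec.roi_area_um2) * 1000.0)

    centers = _draw_centers(rng, spec, side_nm)
    xs, ys, sources = [], [], []
    for idx, center in enumerate(centers):
        n_det = rng.poisson(spec.detections_per_cluster)
        pts = rng.normal(center, spec.cluster_sd_nm, size=(n_det, 2))
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        sources.append(np.full(n_det, idx))

    n_bg = rng.poisson(spec.background_rate_per_um2 * spec.roi_area_um2)
    bg = rng.uniform(0.0, side_nm, size=(n_bg, 2))
    xs.append(bg[:, 0])
    ys.append(bg[:, 1])
    sources.append(np.full(n_bg, -1))

    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    source = np.concatenate(sources).astype(int) if sources else np.empty(0, int)
    photons = rng.lognormal(np.log(spec.photon_median), spec.photon_sigma,
                            size=x.size)

    table = LocalizationTable(x=x, y=y, photons=photons)
    truth = pd.DataFrame(
        {"x_nm": x, "y_nm": y, "photons": photons, "source": source}
    )
    truth.attrs["seed"] = spec.seed
    truth.attrs["n_clusters_true"] = int(spec.n_clusters)
    truth.attrs["roi_area_um2"] = spec.roi_area_um2
    return table, truth


def gen_bead_panel(
    slope: float,
    intercept: float,
    noise_cv: float,
    abc_levels,
    seed: int = 0,
) -> tuple[BeadPanel, dict]:
    """Generate a bead panel with a known linear MFI response.

    ``MFI = slope * ABC + intercept`` with multiplicative log-normal
    noise of coefficient of variation ``noise_cv`` (0 gives the exact
    line).  Returns the panel and a truth dict.
    """
    abc = np.asarray(abc_levels, dtype=float)
    rng = np.random.default_rng(seed)
    clean = slope * abc + intercept
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(-(sigma**2) / 2, sigma, size=abc.size)  # mean 1
    else:
        noise = np.ones_like(abc)
    panel = BeadPanel(abc=abc, mfi=clean * noise)
    truth = {"slope": slope, "intercept": intercept, "noise_cv": noise_cv,
             "seed": seed}
    return panel, truth


@dataclass(frozen=True)
class NoisySignalSpec:
    """A unimodal blot-like signal: log-normal shape peaked at ``peak_time_s``.

    ``peak_width_s`` is the log-domain width parameter of the shape;
    ``noise_cv`` applies multiplicative log-normal noise per sample.
    ``sampling_times_s`` must be increasing and start at 0.
    """

    peak_time_s: float = 34.0
    peak_width_s: float = 0.5
    amplitude: float = 1.0
    noise_cv: float = 0.0
    sampling_times_s: tuple = field(
        default_factory=lambda: tuple(np.arange(0.0, 120.5, 0.5))
    )
    seed: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.sampling_times_s, dtype=float)
        if times.size < 2 or not np.all(np.diff(times) > 0):
            raise ConfigurationError("sampling times must be strictly increasing")
        if self.noise_cv < 0:
            raise ConfigurationError("noise CV must be >= 0")
        if self.peak_time_s <= 0 or self.peak_width_s <= 0:
            raise ConfigurationError("peak time and width must be > 0")


def gen_timecourse(spec: NoisySignalSpec) -> TimeCourse:
    """Sample the unimodal curve at the spec's times, with noise.

    The clean shape is ``A * exp(-ln(t/t_peak)^2 / (2 w^2))`` (zero at
    t = 0), whose unique maximum sits exactly at ``t_peak``.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.sampling_times_s, dtype=float)
    with np.errstate(divide="ignore"):
        logratio = np.where(t > 0, np.log(np.where(t > 0, t, 1.0) / spec.peak_time_s), np.inf)
    clean = np.where(
        t > 0,
        spec.amplitude * np.exp(-(logratio**2) / (2 * spec.peak_width_s**2)),
        0.0,
    )
    if spec.noise_cv > 0:
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        clean = clean * rng.lognormal(-(sigma**2) / 2, sigma, size=t.size)
    return TimeCourse(times=t, values=clean, species="blot_signal")
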