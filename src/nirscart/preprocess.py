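"""Spectral preprocessing: Savitzky-Golay smoothing per spectrometer arm,
region trimming and arm merging, the probe-contact area statistic, repeat
and location exclusion, and the arthroscopic/in vitro coefficient of
variation.

Smoothing windows follow the two analysis families: cartilage targets use
windows (25, 13) samples for arms A and B, subchondral bone targets (45, 13).
Channels at or above 1.90 um are always discarded (water-saturated detector
region). The two arms overlap on 1.0--1.1 um; the merge keeps arm A below
1.0 um and arm B from 1.0 um so every wavelength has a single authoritative
channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .study import LIGHT_REGION, SATURATION_UM, RawSpectrum, SpectraSet

logger = logging.getLogger(__name__)

SG_ORDER = 3
SG_WINDOWS = {"cartilage": (25, 13), "bone": (45, 13)}
MERGE_CUT_UM = 1.00

REGION_FULL = (0.40, 1.90)
REGION_NIR = (0.75, 1.90)


def sg_smooth(intensity: np.ndarray, window: int, order: int = SG_ORDER) -> np.ndarray:
    """Savitzky-Golay smoothing along the last axis.

    Interior points are the centre of a least-squares polynomial fit of the
    given order over the moving window; edge points are taken from a
    polynomial fitted to the terminal full window (no padding with fabricated
    data). Polynomials of degree <= ``order`` pass through unchanged on the
    interior.
    """
    intensity = np.asarray(intensity, dtype=float)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= order:
        raise ValueError(f"window {window} must exceed polynomial order {order}")
    if window > intensity.shape[-1]:
        raise ValueError(
            f"window {window} exceeds spectrum length {intensity.shape[-1]}"
        )
    return savgol_filter(intensity, window, order, axis=-1, mode="interp")


@dataclass
class ProcessedSpectra:
    """Smoothed, trimmed, arm-merged spectra (one row per acquisition).

    ``wavelengths`` is strictly increasing with a single permitted resolution
    discontinuity at the arm boundary. ``variant`` records which smoothing
    family produced the data; ``region`` the retained wavelength interval.
    """

    wavelengths: np.ndarray
    intensity: np.ndarray  # (n, n_channels)
    variant: str
    region: tuple[float, float]
    windows: tuple[int, int]
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if np.any(self.wavelengths >= SATURATION_UM):
            raise ValueError("processed spectra must not contain channels >= 1.90 um")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return self.intensity.shape[0]

    def trim(self, region: tuple[float, float]) -> "ProcessedSpectra":
        lo, hi = region
        keep = (self.wavelengths >= lo) & (self.wavelengths < hi)
        if not np.any(keep):
            raise ValueError(f"region {region} leaves no channels")
        return replace(
            self,
            wavelengths=self.wavelengths[keep],
            intensity=self.intensity[:, keep],
            region=(max(lo, self.region[0]), min(hi, self.region[1])),
        )

    def mean_by_location(self) -> "ProcessedSpectra":
        """Average repeats within each (pony, joint, location)."""
        keys = ["pony", "joint", "location"]
        groups = self.meta.groupby(keys, sort=True).indices
        rows, metas = [], []
        for key in sorted(groups):
            idx = groups[key]
            rows.append(self.intensity[idx].mean(axis=0))
            m = self.meta.iloc[idx[0]].to_dict()
            m["repeat_index"] = -1
            metas.append(m)
        return replace(
            self,
            intensity=np.array(rows).reshape(len(rows), -1),
            meta=pd.DataFrame(metas).reset_index(drop=True),
        )


def preprocess_for(
    parameter_family: str,
    raw: RawSpectrum | SpectraSet,
    region: tuple[float, float] = REGION_FULL,
) -> ProcessedSpectra:
    """Smooth both arms with the family's windows, merge at 1.0 um, and trim
    to the requested region (upper bound capped at 1.90 um)."""
    if parameter_family not in SG_WINDOWS:
        raise ValueError(f"unknown parameter family {parameter_family!r}")
    lo, hi = region
    if not (lo < hi <= SATURATION_UM):
        raise ValueError(f"region {region} invalid (must end at or below 1.90 um)")
    win_a, win_b = SG_WINDOWS[parameter_family]

    if isinstance(raw, RawSpectrum):
        spectra = SpectraSet.from_spectra([raw])
    else:
        spectra = raw
    from .study import ARM_A_GRID, ARM_B_GRID

    if spectra.arm_a.shape[-1] != ARM_A_GRID.size or spectra.arm_b.shape[-1] != ARM_B_GRID.size:
        raise ValueError("spectra do not match the study wavelength grids")

    smooth_a = sg_smooth(spectra.arm_a, win_a)
    smooth_b = sg_smooth(spectra.arm_b, win_b)
    keep_a = (ARM_A_GRID >= lo) & (ARM_A_GRID < min(hi, MERGE_CUT_UM))
    keep_b = (ARM_B_GRID >= max(lo, MERGE_CUT_UM)) & (ARM_B_GRID < hi)
    wavelengths = np.concatenate([ARM_A_GRID[keep_a], ARM_B_GRID[keep_b]])
    intensity = np.concatenate([smooth_a[:, keep_a], smooth_b[:, keep_b]], axis=1)
    return ProcessedSpectra(
        wavelengths=wavelengths,
        intensity=intensity,
        variant=parameter_family,
        region=(lo, hi),
        windows=(win_a, win_b),
        meta=spectra.meta.copy().reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Probe-contact quality statistic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContactQualityScore:
    """Area between a spectrum and the straight line joining its values at the
    region endpoints; large areas indicate poor probe contact or strong
    arthroscope-light contamination."""

    area: float
    repeat_index: int = 0
    region: tuple[float, float] = LIGHT_REGION

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("contact area must be non-negative")


def contact_area(
    raw: RawSpectrum,
    region: tuple[float, float] = LIGHT_REGION,
    smooth_window: int | None = 25,
) -> ContactQualityScore:
    """Two-point linear-fit area statistic on the visible region of arm A.

    The straight line passes through the (optionally smoothed) intensities at
    the channels nearest the region endpoints; the score is the trapezoidal
    integral of the absolute deviation between spectrum and line over the
    region.
    """
    grid = raw.arm_a_wavelengths
    lo, hi = region
    if grid[0] > lo or grid[-1] < hi:
        raise ValueError(f"arm A grid does not cover the region {region}")
    vals = raw.arm_a_intensity
    if smooth_window is not None:
        vals = sg_smooth(vals, smooth_window)
    i_lo = int(np.argmin(np.abs(grid - lo)))
    i_hi = int(np.argmin(np.abs(grid - hi)))
    sl = slice(i_lo, i_hi + 1)
    x, y = grid[sl], vals[sl]
    line = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    area = float(np.trapezoid(np.abs(y - line), x))
    return ContactQualityScore(
        area=area,
        repeat_index=int(raw.metadata.get("repeat_index", 0)),
        region=region,
    )


def select_best_spectra(
    scores: list[ContactQualityScore], keep: int = 8
) -> list[ContactQualityScore]:
    """Retain the ``keep`` scores with the smallest area (ties broken by the
    earlier repeat index); the complement is the excluded poor-contact set."""
    if len(scores) < keep:
        raise ValueError(f"need at least {keep} spectra, got {len(scores)}")
    ranked = sorted(scores, key=lambda s: (s.area, s.repeat_index))
    return ranked[:keep]


def contamination_threshold(invitro_areas: np.ndarray, n_robust_sd: float = 3.0) -> float:
    """Default location-exclusion threshold: ``n_robust_sd`` robust standard
    deviations (1.4826 * MAD) above the median of the study-wide in vitro
    area distribution."""
    areas = np.asarray(invitro_areas, dtype=float)
    med = float(np.median(areas))
    mad = float(np.median(np.abs(areas - med)))
    return med + n_robust_sd * 1.4826 * mad


def flag_contaminated_location(
    retained_scores: list[ContactQualityScore], threshold: float
) -> bool:
    """True iff the median retained-spectrum area exceeds the threshold
    (location-level exclusion for arthroscope-light contamination)."""
    if not retained_scores:
        return False
    median_area = float(np.median([s.area for s in retained_scores]))
    return bool(median_area > threshold)


def coefficient_of_variation(
    mean_arthro: ProcessedSpectra,
    mean_invitro: ProcessedSpectra,
    region: tuple[float, float] = REGION_NIR,
) -> float:
    """Per-channel coefficient of variation between a paired arthroscopic and
    in vitro mean spectrum, averaged over channels, in percent.

    Each channel contributes SD/mean of its two paired values (population
    SD); channels with non-positive mean are skipped with a log message.
    """
    a, b = mean_arthro.trim(region), mean_invitro.trim(region)
    if a.wavelengths.shape != b.wavelengths.shape or not np.allclose(
        a.wavelengths, b.wavelengths
    ):
        raise ValueError("spectra are not on a common channel grid in the region")
    x = a.intensity.mean(axis=0)
    y = b.intensity.mean(axis=0)
    mean = 0.5 * (x + y)
    sd = 0.5 * np.abs(x - y)
    ok = mean > 0
    if not np.all(ok):
        logger.warning("skipping %d channels with non-positive mean", int((~ok).sum()))
    if not np.any(ok):
        raise ValueError("no channels with positive mean in region")
    return float(100.0 * np.mean(sd[ok] / mean[ok]))


def paired_cv_by_location(
    arthro: ProcessedSpectra,
    invitro: ProcessedSpectra,
    region: tuple[float, float] = REGION_NIR,
) -> pd.Series:
    """Coefficient of variation between per-location mean arthroscopic and
    in vitro spectra, for every location present in both sets."""
    a = arthro.mean_by_location()
    b = invitro.mean_by_location()
    keys_b = {
        tuple(r): i
        for i, r in enumerate(b.meta[["pony", "joint", "location"]].to_numpy())
    }
    out = {}
    for i, r in enumerate(a.meta[["pony", "joint", "location"]].to_numpy()):
        key = tuple(r)
        if key not in keys_b:
            continue
        j = keys_b[key]
        out[key] = coefficient_of_variation(
            replace(a, intensity=a.intensity[[i]], meta=a.meta.iloc[[i]]),
            replace(b, intensity=b.intensity[[j]], meta=b.meta.iloc[[j]]),
            region,
        )
    return pd.Series(out, name="cv_percent")


# ---------------------------------------------------------------------------
# Arthroscopic QC over a whole study
# ---------------------------------------------------------------------------


@dataclass
class LocationQC:
    pony: int
    joint: int
    location: int
    median_area: float
    retained_repeats: tuple[int, ...]
    flagged: bool


def arthroscopic_qc(
    arthro: SpectraSet,
    invitro: SpectraSet,
    keep: int = 8,
    threshold: float | None = None,
) -> tuple[SpectraSet, pd.DataFrame]:
    """Apply the per-location repeat exclusion and contamination flagging.

    Returns the retained (best-``keep``, unflagged-location) arthroscopic
    spectra and a QC table with one row per location.
    """
    if threshold is None:
        inv_areas = np.array(
            [contact_area(invitro.spectrum(i)).area for i in range(len(invitro))]
        )
        threshold = contamination_threshold(inv_areas)
    scores = [contact_area(arthro.spectrum(i)) for i in range(len(arthro))]
    keys = arthro.meta[["pony", "joint", "location"]].itertuples(index=False, name=None)
    by_loc: dict[tuple, list[tuple[int, ContactQualityScore]]] = {}
    for i, (key, sc) in enumerate(zip(keys, scores)):
        by_loc.setdefault(key, []).append((i, sc))

    retained_idx: list[int] = []
    qc_rows = []
    for key in sorted(by_loc):
        pairs = by_loc[key]
        best = select_best_spectra([sc for _, sc in pairs], keep=keep)
        best_reps = {sc.repeat_index for sc in best}
        flagged = flag_contaminated_location(best, threshold)
        qc_rows.append(
            LocationQC(
                pony=key[0],
                joint=key[1],
                location=key[2],
                median_area=float(np.median([sc.area for sc in best])),
                retained_repeats=tuple(sorted(best_reps)),
                flagged=flagged,
            )
        )
        if not flagged:
            retained_idx.extend(i for i, sc in pairs if sc.repeat_index in best_reps)

    qc = pd.DataFrame(
        [
            {
                "pony": r.pony,
                "joint": r.joint,
                "location": r.location,
                "median_area": r.median_area,
                "retained_repeats": ";".join(map(str, r.retained_repeats)),
                "flagged": r.flagged,
            }
            for r in qc_rows
        ]
    )
    return arthro.subset(np.array(sorted(retained_idx), dtype=int)), qc
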