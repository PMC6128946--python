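"""Synthetic study generator: design hierarchy, latent tissue states, reference
properties, and two-arm NIR spectra with arthroscopic acquisition artefacts.

The generator emulates an equine cartilage-repair study: ponies carry either
surgically repaired chondral lesions (``repair`` group) or are healthy
(``control``), each pony contributes two femoropatellar joints, and twelve
measurement locations surround each (putative) lesion site. Locations fall in
four distance classes with degenerative effects decaying with distance from
the lesion. Spectra are recorded by two spectrometer arms (0.35--1.1 um at
0.6 nm; 1.0--2.5 um at 6.4 nm). Arthroscopic acquisitions suffer imperfect
probe contact and arthroscope-light contamination in the visible region;
in vitro acquisitions do not.

Every quantity is a pure function of the design, the effect configuration and
the seed, so downstream stages are testable against known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Spectrometer wavelength grids (um). Arm A: visible/short-NIR, arm B: NIR.
ARM_A_GRID = np.linspace(0.35, 1.10, 1251)
ARM_B_GRID = np.arange(0.0, 235) * 0.0064 + 1.0

#: Detector saturation region: channels at or above this wavelength carry no
#: usable tissue signal (water absorption saturates the NIR arm).
SATURATION_UM = 1.90
SATURATION_LEVEL = 0.95  # fraction of dynamic range
DYNAMIC_RANGE = 1.0

#: Visible-region support of the arthroscope light-source contamination (um).
LIGHT_REGION = (0.42, 0.75)

PROPERTY_NAMES = (
    "E_eq",
    "E_dyn",
    "plate_BV",
    "plate_BMD",
    "plate_thickness",
    "trab_BV",
    "trab_BMD",
    "trab_thickness",
    "SMI",
    "cartilage_thickness",
)

#: Cartilage-family targets (the rest are subchondral bone targets); the
#: preprocessing smoothing windows differ between the two families.
CARTILAGE_PARAMETERS = ("E_eq", "E_dyn")

# Healthy-population latent distribution: mean and SD of each latent driver.
_LATENT_DIST = {
    "water_fraction": (0.72, 0.03),
    "collagen_density": (1.0, 0.10),
    "proteoglycan_density": (1.0, 0.15),
    "mineral_density": (1.0, 0.12),
    "scattering_slope": (0.50, 0.05),
}

WATER_FRACTION_RANGE = (0.60, 0.85)


class InvalidDesignError(ValueError):
    """Raised when a study design violates its invariants."""


@dataclass(frozen=True)
class StudyDesign:
    """Hierarchical design: ponies -> joints -> locations.

    ``distance_class_per_location`` maps 0-based location index within a joint
    to a distance class 1--4 (1 = adjacent to the lesion). By default the 12
    locations split into 4 consecutive triplets of increasing distance.
    """

    n_repair_ponies: int = 7
    n_control_ponies: int = 3
    joints_per_pony: int = 2
    locations_per_joint: int = 12
    lesions_per_joint: int = 2
    n_unreachable: int = 4
    distance_class_per_location: dict[int, int] | None = None
    arthroscopically_unreachable: frozenset[tuple[int, int, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repair_ponies < 0 or self.n_control_ponies < 0:
            raise InvalidDesignError("pony counts must be non-negative")
        if self.joints_per_pony <= 0 or self.locations_per_joint <= 0:
            raise InvalidDesignError("joints/locations per pony must be positive")
        if self.n_unreachable < 0:
            raise InvalidDesignError("n_unreachable must be non-negative")
        for loc, cls in self.distance_classes.items():
            if cls not in (1, 2, 3, 4):
                raise InvalidDesignError(f"distance class {cls} for location {loc}")

    @property
    def distance_classes(self) -> dict[int, int]:
        if self.distance_class_per_location is not None:
            return self.distance_class_per_location
        per_class = max(1, self.locations_per_joint // 4)
        return {
            i: min(4, i // per_class + 1) for i in range(self.locations_per_joint)
        }

    @property
    def n_ponies(self) -> int:
        return self.n_repair_ponies + self.n_control_ponies

    @property
    def n_locations_total(self) -> int:
        return self.n_ponies * self.joints_per_pony * self.locations_per_joint

    @property
    def n_lesions(self) -> int:
        return self.n_repair_ponies * self.joints_per_pony * self.lesions_per_joint

    def pony_ids(self) -> list[tuple[int, str]]:
        """(pony_id, group) pairs; repair ponies first."""
        out = [(i, "repair") for i in range(self.n_repair_ponies)]
        out += [
            (self.n_repair_ponies + i, "control")
            for i in range(self.n_control_ponies)
        ]
        return out

    def resolve_unreachable(self) -> frozenset[tuple[int, int, int]]:
        """The set of (pony, joint, location) triples the arthroscope cannot
        reach. If not given explicitly, drawn deterministically from the design
        seed among *repair* ponies (controls were never arthroscoped)."""
        if self.arthroscopically_unreachable is not None:
            return self.arthroscopically_unreachable
        if self.n_unreachable == 0 or self.n_repair_ponies == 0:
            return frozenset()
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xA11]))
        triples = [
            (p, j, l)
            for p in range(self.n_repair_ponies)
            for j in range(self.joints_per_pony)
            for l in range(self.locations_per_joint)
        ]
        n = min(self.n_unreachable, len(triples))
        idx = rng.choice(len(triples), size=n, replace=False)
        return frozenset(triples[i] for i in sorted(idx))


@dataclass(frozen=True)
class LatentTissueState:
    """Latent drivers of both the reference properties and the spectra."""

    water_fraction: float
    collagen_density: float
    proteoglycan_density: float
    mineral_density: float
    scattering_slope: float

    def clamped(self) -> "LatentTissueState":
        lo, hi = WATER_FRACTION_RANGE
        w = self.water_fraction
        if not lo <= w <= hi:
            logger.warning("water_fraction %.3f clamped to [%.2f, %.2f]", w, lo, hi)
            w = float(np.clip(w, lo, hi))
        return replace(
            self,
            water_fraction=w,
            collagen_density=max(self.collagen_density, 0.0),
            proteoglycan_density=max(self.proteoglycan_density, 0.0),
            mineral_density=max(self.mineral_density, 0.0),
            scattering_slope=max(self.scattering_slope, 0.0),
        )


@dataclass(frozen=True)
class EffectConfig:
    """Repair-group latent shifts, in healthy-population SD units, at distance
    class 1. Shifts decay linearly with distance class: class ``k`` of ``K``
    receives a fraction ``(K - k + 1) / K`` of the full shift.

    Defaults emulate post-traumatic degeneration adjacent to a repair site:
    water up, proteoglycan and collagen down, mineralisation down.
    """

    scale: float = 1.0
    water_shift_sd: float = 1.3
    collagen_shift_sd: float = -1.5
    proteoglycan_shift_sd: float = -2.0
    mineral_shift_sd: float = -1.7
    n_classes: int = 4

    def decay(self, distance_class: int) -> float:
        if not 1 <= distance_class <= self.n_classes:
            raise ValueError(f"distance class {distance_class} out of 1..{self.n_classes}")
        return (self.n_classes - distance_class + 1) / self.n_classes


@dataclass(frozen=True)
class AcquisitionContext:
    modality: str  # "arthroscopic" | "in_vitro"
    contact_quality: float = 1.0
    arthroscope_light_level: float = 0.0
    n_repeats: int = 3
    noise_sd: float = 0.003

    def __post_init__(self) -> None:
        if self.modality not in ("arthroscopic", "in_vitro"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "in_vitro" and self.arthroscope_light_level != 0.0:
            raise ValueError("in_vitro acquisitions carry no arthroscope light")
        if not 0.0 <= self.contact_quality <= 1.0:
            raise ValueError("contact_quality must be in [0, 1]")


@dataclass
class RawSpectrum:
    """One acquisition: both spectrometer arms plus metadata."""

    arm_a_wavelengths: np.ndarray
    arm_a_intensity: np.ndarray
    arm_b_wavelengths: np.ndarray
    arm_b_intensity: np.ndarray
    metadata: dict

    def validate(self) -> None:
        for grid, vals in (
            (self.arm_a_wavelengths, self.arm_a_intensity),
            (self.arm_b_wavelengths, self.arm_b_intensity),
        ):
            if np.any(np.diff(grid) <= 0):
                raise ValueError("wavelength grid must be strictly increasing")
            if grid.shape != vals.shape:
                raise ValueError("grid/intensity shape mismatch")
            if not np.all(np.isfinite(vals)) or np.any(vals < 0):
                raise ValueError("intensities must be finite and non-negative")


# ---------------------------------------------------------------------------
# Latent -> reference-property maps
# ---------------------------------------------------------------------------

# Healthy-population means of the reference properties (units as labelled).
CONTROL_MEANS = {
    "E_eq": 579.0,            # kPa
    "E_dyn": 7.25,            # MPa
    "plate_BV": 98.4,         # %
    "plate_BMD": 1.00,        # g/cm^3
    "plate_thickness": 174.0,  # um
    "trab_BV": 30.5,          # %
    "trab_BMD": 0.247,        # g/cm^3
    "trab_thickness": 169.0,  # um
    "SMI": 0.367,             # dimensionless
    "cartilage_thickness": 1000.0,  # um
}

# Standardised latent weights per property: property = mean * g(sum w_i z_i)
# with g a mean-corrected softplus ratio (monotone in every driver).
_PROP_WEIGHTS: dict[str, dict[str, float]] = {
    "E_eq": {"proteoglycan_density": 0.45, "collagen_density": 0.08, "water_fraction": -0.15},
    "E_dyn": {"proteoglycan_density": 0.35, "collagen_density": 0.15, "water_fraction": -0.12},
    "plate_BMD": {"mineral_density": 0.35},
    "plate_thickness": {"mineral_density": 0.20, "collagen_density": 0.12},
    "trab_BV": {"mineral_density": 0.30},
    "trab_BMD": {"mineral_density": 0.35},
    "trab_thickness": {"mineral_density": 0.18, "collagen_density": 0.08},
    "cartilage_thickness": {"collagen_density": 0.08},
}
_PLATE_BV_WEIGHT = 0.50   # on mineral z-score, through the bounded map
_SMI_SLOPE = -0.35        # linear in mineral z-score (may go <= 0)

_LATENT_ORDER = tuple(_LATENT_DIST)


def _softplus(x):
    return np.logaddexp(0.0, x)


_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(64)


@lru_cache(maxsize=64)
def _softplus_ratio_mean(sigma_u: float) -> float:
    """E[softplus(1 + U) / softplus(1)] for U ~ N(0, sigma_u^2), by
    Gauss-Hermite quadrature. Used to mean-correct the monotone maps so the
    healthy population is centred on the nominal property means."""
    vals = _softplus(1.0 + sigma_u * _GH_X) / _softplus(1.0)
    return float(vals @ _GH_W / _GH_W.sum())


def _g(u: float) -> float:
    """Normalised monotone softplus link: g(0) = 1, strictly increasing."""
    return float(_softplus(1.0 + u) / _softplus(1.0))


def _zscores(state: LatentTissueState) -> dict[str, float]:
    return {
        name: (getattr(state, name) - mu) / sd
        for name, (mu, sd) in _LATENT_DIST.items()
    }


def latent_to_properties(state: LatentTissueState) -> dict[str, float]:
    """Deterministic monotone map from latent tissue state to the ten
    reference properties. Each property increases (or, where flagged,
    decreases) strictly in its latent drivers; the healthy-population mean of
    each property equals the documented nominal mean.
    """
    z = _zscores(state.clamped())
    props: dict[str, float] = {}
    for name, weights in _PROP_WEIGHTS.items():
        u = sum(w * z[latent] for latent, w in weights.items())
        sigma_u = float(np.hypot.reduce([abs(w) for w in weights.values()]))
        props[name] = CONTROL_MEANS[name] * _g(u) / _softplus_ratio_mean(sigma_u)
    # Plate BV is bounded above by 100%: map the deficit (100 - BV) instead.
    u = -_PLATE_BV_WEIGHT * z["mineral_density"]
    deficit = (100.0 - CONTROL_MEANS["plate_BV"]) * _g(u) / _softplus_ratio_mean(
        _PLATE_BV_WEIGHT
    )
    props["plate_BV"] = 100.0 - deficit
    # SMI: linear, decreasing in mineralisation; negative values allowed
    # (more plate-like than the reference ellipsoid).
    props["SMI"] = CONTROL_MEANS["SMI"] + _SMI_SLOPE * z["mineral_density"]
    props["trab_BV"] = min(props["trab_BV"], 100.0)
    return {name: props[name] for name in PROPERTY_NAMES}


def draw_latent_state(
    group: str,
    distance_class: int,
    rng: np.random.Generator,
    effect: EffectConfig | None = None,
) -> LatentTissueState:
    """Draw a latent tissue state for one location.

    Control locations draw from the healthy-population distribution; repair
    locations receive the configured degenerative shift, decaying with
    distance class.
    """
    if group not in ("repair", "control"):
        raise ValueError(f"unknown group {group!r}")
    effect = effect or EffectConfig()
    shift = {name: 0.0 for name in _LATENT_ORDER}
    if group == "repair" and effect.scale != 0.0:
        f = effect.scale * effect.decay(distance_class)
        shift["water_fraction"] = effect.water_shift_sd * f
        shift["collagen_density"] = effect.collagen_shift_sd * f
        shift["proteoglycan_density"] = effect.proteoglycan_shift_sd * f
        shift["mineral_density"] = effect.mineral_shift_sd * f
    values = {}
    for name in _LATENT_ORDER:
        mu, sd = _LATENT_DIST[name]
        values[name] = mu + sd * (shift[name] + rng.standard_normal())
    return LatentTissueState(**values).clamped()


def simulate_reference_properties(
    group: str,
    distance_class: int,
    rng: np.random.Generator,
    effect: EffectConfig | None = None,
) -> dict[str, float]:
    """One reference-property draw (latent draw followed by the monotone map)."""
    state = draw_latent_state(group, distance_class, rng, effect)
    return latent_to_properties(state)


# ---------------------------------------------------------------------------
# Spectral forward model
# ---------------------------------------------------------------------------

# Absorption bands: (centre um, sigma um, depth at nominal latent state).
# Gaussians are truncated at +/-3 sigma so each band has compact support.
_WATER_BANDS = ((0.97, 0.030, 0.06), (1.45, 0.050, 0.30), (1.93, 0.060, 0.80))
_CH_BANDS = ((0.90, 0.020, 0.03), (1.18, 0.040, 0.06), (1.73, 0.055, 0.12))
_NH_BANDS = ((1.00, 0.030, 0.04), (1.50, 0.045, 0.10))

_BASELINE_LEVEL = 0.90
_BASELINE_SLOPE = 0.12  # per (scattering_slope unit) per um


def _band(grid: np.ndarray, centre: float, sigma: float, depth: float) -> np.ndarray:
    mask = np.abs(grid - centre) <= 3.0 * sigma
    out = np.zeros_like(grid)
    out[mask] = depth * np.exp(-0.5 * ((grid[mask] - centre) / sigma) ** 2)
    return out


def _light_bump(grid: np.ndarray, level: float) -> np.ndarray:
    """Raised-cosine arthroscope-light contamination, exactly zero outside
    the visible interference region."""
    lo, hi = LIGHT_REGION
    centre, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    mask = np.abs(grid - centre) < half
    out = np.zeros_like(grid)
    out[mask] = level * 0.5 * (1.0 + np.cos(np.pi * (grid[mask] - centre) / half))
    return out


def _arm_intensity(
    grid: np.ndarray,
    state: LatentTissueState,
    context: AcquisitionContext,
    rng: np.random.Generator,
) -> np.ndarray:
    c = context.contact_quality
    water_scale = c * state.water_fraction / _LATENT_DIST["water_fraction"][0]
    slope = _BASELINE_SLOPE * state.scattering_slope * (
        1.0 + 0.4 * (state.mineral_density - 1.0)
    )
    intensity = _BASELINE_LEVEL - slope * (grid - grid[0])
    for centre, sigma, depth in _WATER_BANDS:
        intensity -= _band(grid, centre, sigma, depth * water_scale)
    for centre, sigma, depth in _CH_BANDS:
        intensity -= _band(grid, centre, sigma, depth * c * state.collagen_density)
    for centre, sigma, depth in _NH_BANDS:
        intensity -= _band(grid, centre, sigma, depth * c * state.proteoglycan_density)
    intensity += _light_bump(grid, context.arthroscope_light_level)
    noise_sd = context.noise_sd * (1.0 + 2.0 * (1.0 - c))
    noise = rng.standard_normal(grid.size) * noise_sd if noise_sd > 0 else 0.0
    intensity = intensity + noise
    # Detector saturation beyond 1.9 um: pinned near full scale, noisy.
    sat = grid >= SATURATION_UM
    if np.any(sat):
        sat_noise = (
            rng.standard_normal(int(sat.sum())) * 5.0 * noise_sd if noise_sd > 0 else 0.0
        )
        intensity[sat] = SATURATION_LEVEL * DYNAMIC_RANGE + sat_noise
    return np.clip(intensity, 0.0, DYNAMIC_RANGE)


def simulate_spectrum(
    state: LatentTissueState,
    context: AcquisitionContext,
    rng: np.random.Generator,
    metadata: dict | None = None,
) -> RawSpectrum:
    """Simulate one two-arm acquisition.

    The spectrum is a smooth scattering baseline minus truncated-Gaussian
    absorption bands (water/CH/NH overtones scaled by the latent state and
    probe-contact quality) plus arthroscope-light contamination confined to
    the visible region, additive noise, and detector saturation >= 1.9 um.
    """
    state = state.clamped()
    arm_a = _arm_intensity(ARM_A_GRID, state, context, rng)
    arm_b = _arm_intensity(ARM_B_GRID, state, context, rng)
    return RawSpectrum(
        arm_a_wavelengths=ARM_A_GRID.copy(),
        arm_a_intensity=arm_a,
        arm_b_wavelengths=ARM_B_GRID.copy(),
        arm_b_intensity=arm_b,
        metadata=dict(metadata or {}),
    )


# ---------------------------------------------------------------------------
# Full-study assembly
# ---------------------------------------------------------------------------

_META_COLUMNS = (
    "pony",
    "joint",
    "location",
    "group",
    "distance_class",
    "modality",
    "repeat_index",
)


@dataclass
class SpectraSet:
    """Stacked acquisitions of one modality: per-arm intensity matrices plus
    one metadata row per acquisition."""

    arm_a: np.ndarray  # (n, len(ARM_A_GRID))
    arm_b: np.ndarray  # (n, len(ARM_B_GRID))
    meta: pd.DataFrame

    def __len__(self) -> int:
        return len(self.meta)

    def spectrum(self, i: int) -> RawSpectrum:
        return RawSpectrum(
            arm_a_wavelengths=ARM_A_GRID.copy(),
            arm_a_intensity=self.arm_a[i].copy(),
            arm_b_wavelengths=ARM_B_GRID.copy(),
            arm_b_intensity=self.arm_b[i].copy(),
            metadata=self.meta.iloc[i].to_dict(),
        )

    def subset(self, mask) -> "SpectraSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectraSet(
            arm_a=self.arm_a[idx],
            arm_b=self.arm_b[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    @staticmethod
    def from_spectra(spectra: list[RawSpectrum]) -> "SpectraSet":
        if not spectra:
            return SpectraSet(
                arm_a=np.empty((0, ARM_A_GRID.size)),
                arm_b=np.empty((0, ARM_B_GRID.size)),
                meta=pd.DataFrame(columns=list(_META_COLUMNS)),
            )
        return SpectraSet(
            arm_a=np.stack([s.arm_a_intensity for s in spectra]),
            arm_b=np.stack([s.arm_b_intensity for s in spectra]),
            meta=pd.DataFrame([s.metadata for s in spectra]),
        )


@dataclass
class StudyData:
    """A complete synthetic study: reference table plus both spectra sets.

    ``references`` has one row per measured location (unreachable locations
    are excluded from both modalities, matching the study bookkeeping) with
    metadata, the ten reference properties, and the latent ground truth.
    """

    design: StudyDesign
    effect: EffectConfig
    seed: int
    references: pd.DataFrame
    invitro: SpectraSet
    arthro: SpectraSet

    @property
    def n_invitro_locations(self) -> int:
        return len(self.references)

    @property
    def n_arthro_locations(self) -> int:
        return int((self.references["group"] == "repair").sum())


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition noise/artefact settings for a generated study."""

    n_arthro_repeats: int = 15
    n_invitro_repeats: int = 3
    noise_sd: float = 0.003
    contact_mode: float = 0.85
    contact_concentration: float = 10.0
    light_level_mean: float = 2e-4
    #: poor contact admits more arthroscope light into the probe
    light_contact_coupling: float = 3.0
    contaminated_locations: frozenset = frozenset()
    contaminated_light_level: float = 1.0


def _beta_params(mode: float, concentration: float) -> tuple[float, float]:
    return 1.0 + mode * concentration, 1.0 + (1.0 - mode) * concentration


def generate_study(
    design: StudyDesign,
    effect: EffectConfig | None = None,
    rng_seed: int | None = None,
    acquisition: AcquisitionConfig | None = None,
) -> StudyData:
    """Generate a full synthetic study with known ground truth.

    Every reachable location carries ``n_invitro_repeats`` in vitro spectra;
    repair-group locations additionally carry ``n_arthro_repeats``
    arthroscopic spectra (controls are never arthroscoped). The dataset is a
    pure function of (design, effect, seed, acquisition).
    """
    effect = effect or EffectConfig()
    acq = acquisition or AcquisitionConfig()
    seed = design.seed if rng_seed is None else rng_seed
    unreachable = design.resolve_unreachable()
    classes = design.distance_classes

    ref_rows: list[dict] = []
    invitro_specs: list[RawSpectrum] = []
    arthro_specs: list[RawSpectrum] = []
    root = np.random.SeedSequence([int(seed), 0x57D])
    a_beta, b_beta = _beta_params(acq.contact_mode, acq.contact_concentration)

    for pony, group in design.pony_ids():
        for joint in range(design.joints_per_pony):
            for loc in range(design.locations_per_joint):
                key = (pony, joint, loc)
                child = np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(pony, joint, loc)
                )
                rng = np.random.default_rng(child)
                if key in unreachable:
                    continue
                dclass = classes[loc]
                state = draw_latent_state(group, dclass, rng, effect)
                props = latent_to_properties(state)
                meta = {
                    "pony": pony,
                    "joint": joint,
                    "location": loc,
                    "group": group,
                    "distance_class": dclass,
                }
                ref_rows.append(
                    {
                        **meta,
                        **props,
                        **{f"latent_{k}": getattr(state, k) for k in _LATENT_ORDER},
                    }
                )
                for rep in range(acq.n_invitro_repeats):
                    ctx = AcquisitionContext(
                        modality="in_vitro",
                        contact_quality=1.0,
                        arthroscope_light_level=0.0,
                        n_repeats=acq.n_invitro_repeats,
                        noise_sd=acq.noise_sd,
                    )
                    invitro_specs.append(
                        simulate_spectrum(
                            state, ctx, rng,
                            metadata={**meta, "modality": "in_vitro", "repeat_index": rep},
                        )
                    )
                if group != "repair":
                    continue
                if key in acq.contaminated_locations:
                    base_light = acq.contaminated_light_level
                else:
                    base_light = rng.exponential(acq.light_level_mean)
                for rep in range(acq.n_arthro_repeats):
                    contact = float(rng.beta(a_beta, b_beta))
                    light = base_light * (
                        1.0 + acq.light_contact_coupling * (1.0 - contact)
                    ) * rng.uniform(0.7, 1.3)
                    ctx = AcquisitionContext(
                        modality="arthroscopic",
                        contact_quality=contact,
                        arthroscope_light_level=light,
                        n_repeats=acq.n_arthro_repeats,
                        noise_sd=acq.noise_sd,
                    )
                    arthro_specs.append(
                        simulate_spectrum(
                            state, ctx, rng,
                            metadata={
                                **meta,
                                "modality": "arthroscopic",
                                "repeat_index": rep,
                                "contact_quality": contact,
                                "light_level": light,
                            },
                        )
                    )

    references = pd.DataFrame(ref_rows)
    return StudyData(
        design=design,
        effect=effect,
        seed=seed,
        references=references,
        invitro=SpectraSet.from_spectra(invitro_specs),
        arthro=SpectraSet.from_spectra(arthro_specs),
    )


def simulate_reference_table(
    design: StudyDesign,
    effect: EffectConfig | None = None,
    rng_seed: int | None = None,
) -> pd.DataFrame:
    """Reference-property table only (no spectra) — cheap path for
    statistical-calibration experiments over many replicate studies."""
    effect = effect or EffectConfig()
    seed = design.seed if rng_seed is None else rng_seed
    unreachable = design.resolve_unreachable()
    classes = design.distance_classes
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x2EF]))
    rows = []
    for pony, group in design.pony_ids():
        for joint in range(design.joints_per_pony):
            for loc in range(design.locations_per_joint):
                if (pony, joint, loc) in unreachable:
                    continue
                dclass = classes[loc]
                props = simulate_reference_properties(group, dclass, rng, effect)
                rows.append(
                    {
                        "pony": pony,
                        "joint": joint,
                        "location": loc,
                        "group": group,
                        "distance_class": dclass,
                        **props,
                    }
                )
    return pd.DataFrame(rows)
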