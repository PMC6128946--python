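"""Cartilage indentation mechanics: simulated stress-relaxation /
dynamic-loading records and the two reference moduli extracted from them.

The measurement protocol is four stress-relaxation steps of 5% strain at a
ramp velocity of 100%/s with 600 s holds, followed by 1 Hz sinusoidal
loading at 1% strain amplitude, applied with a plane-ended cylindrical
indenter (d = 0.53 mm). The equilibrium modulus E_eq comes from the slope of
the equilibrium stress-strain points over the most linear contiguous run of
steps (Poisson's ratio 0.1); the dynamic modulus E_dyn is the stress/strain
amplitude ratio of the sinusoid (Poisson's ratio 0.5). The
indentation-geometry correction enters as a pluggable scalar ``kappa``
(default 1); both the simulator and the analysis use the same convention,
``E = slope * (1 - nu^2) / kappa``, so recovery is exact by construction
when kappa matches.

The simulated material is a standard linear solid (SLS): relaxation modulus
``E(t) = E_inf + E1 * exp(-t / tau)``. Stress responses to the piecewise
ramp-and-hold strain history and to the sinusoid are evaluated from the
exact hereditary-integral solutions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

logger = logging.getLogger(__name__)

INDENTER_DIAMETER_UM = 530.0


@dataclass(frozen=True)
class IndentationProtocol:
    n_steps: int = 4
    step_strain: float = 0.05
    ramp_rate: float = 1.0       # strain/s (100 %/s)
    relax_time: float = 600.0    # s
    sine_freq: float = 1.0       # Hz
    sine_amplitude: float = 0.01  # strain
    sine_cycles: int = 10

    @property
    def ramp_duration(self) -> float:
        return self.step_strain / self.ramp_rate

    def step_start(self, k: int) -> float:
        return k * (self.ramp_duration + self.relax_time)

    @property
    def sine_start(self) -> float:
        return self.step_start(self.n_steps)

    @property
    def total_strain(self) -> float:
        return self.n_steps * self.step_strain


@dataclass
class IndentationRecord:
    time: np.ndarray          # s
    force: np.ndarray         # N
    displacement: np.ndarray  # um
    sample_thickness_um: float
    indenter_diameter_um: float = INDENTER_DIAMETER_UM
    protocol: IndentationProtocol = field(default_factory=IndentationProtocol)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def indenter_area_m2(self) -> float:
        r = self.indenter_diameter_um * 1e-6 / 2.0
        return float(np.pi * r**2)

    @property
    def strain(self) -> np.ndarray:
        return self.displacement / self.sample_thickness_um

    @property
    def stress_kpa(self) -> np.ndarray:
        return self.force / self.indenter_area_m2 / 1e3


@dataclass(frozen=True)
class ModulusPair:
    E_eq_kpa: float
    E_dyn_mpa: float
    eq_fit_r2: float
    dyn_fit_residual: float

    def __post_init__(self) -> None:
        if self.E_eq_kpa <= 0 or self.E_dyn_mpa <= 0:
            raise ValueError("moduli must be positive")


def _sls_ramp_stress(t, t0, t1, rate, e_inf, e1, tau):
    """Exact SLS stress contribution of a strain ramp of the given rate over
    [t0, t1], evaluated at times t >= t0 (zero before t0)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    during = (t >= t0) & (t < t1)
    after = t >= t1
    td = t[during] - t0
    out[during] = rate * (e_inf * td + e1 * tau * (1.0 - np.exp(-td / tau)))
    ta0 = t[after] - t0
    ta1 = t[after] - t1
    out[after] = rate * (
        e_inf * (t1 - t0) + e1 * tau * (np.exp(-ta1 / tau) - np.exp(-ta0 / tau))
    )
    return out


def _sls_sine_stress(tp, eps_a, omega, e_inf, e1, tau):
    """Exact SLS stress response to strain eps_a*sin(omega*t') switched on at
    t' = 0 (includes the start-up transient)."""
    wt = omega * tau
    k = e1 * wt / (1.0 + wt**2)
    return (
        eps_a * e_inf * np.sin(omega * tp)
        + eps_a * k * (np.cos(omega * tp) + wt * np.sin(omega * tp) - np.exp(-tp / tau))
    )


def _time_grid(protocol: IndentationProtocol) -> np.ndarray:
    """Sampling: dense over ramps and the sinusoid, sparse over holds."""
    pieces = []
    for k in range(protocol.n_steps):
        t0 = protocol.step_start(k)
        t1 = t0 + protocol.ramp_duration
        pieces.append(np.linspace(t0, t1, 25, endpoint=False))
        pieces.append(np.linspace(t1, t0 + protocol.ramp_duration + protocol.relax_time,
                                  400, endpoint=False))
    ts = protocol.sine_start
    dur = protocol.sine_cycles / protocol.sine_freq
    pieces.append(np.linspace(ts, ts + dur, int(200 * protocol.sine_cycles) + 1))
    return np.concatenate(pieces)


def simulate_indentation(
    e_eq_kpa: float,
    e_dyn_mpa: float | None = None,
    tau_s: float = 5.0,
    protocol: IndentationProtocol | None = None,
    sample_thickness_um: float = 1000.0,
    kappa: float = 1.0,
    noise_sd_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
) -> IndentationRecord:
    """Simulate one indentation record from SLS ground truth.

    ``e_eq_kpa`` is the target equilibrium modulus (nu = 0.1 convention) and
    ``e_dyn_mpa`` the target 1 Hz dynamic modulus (nu = 0.5 convention);
    omitting the latter defaults to an SLS with E1 = 10 * E_inf. Noise is
    additive Gaussian on the force channel, scaled by the peak force.
    """
    if e_eq_kpa <= 0:
        raise ValueError("equilibrium modulus must be positive")
    protocol = protocol or IndentationProtocol()
    # invert the analysis conventions so that extraction round-trips
    e_inf = e_eq_kpa * kappa / (1.0 - 0.1**2)
    omega = 2.0 * np.pi * protocol.sine_freq
    if e_dyn_mpa is None:
        e1 = 10.0 * e_inf
    else:
        target = e_dyn_mpa * 1e3 * kappa / (1.0 - 0.5**2)  # kPa, measured |E*|
        wt = omega * tau_s
        # |E*|^2 = (e_inf + e1 w^2/(1+w^2))^2 + (e1 w/(1+w^2))^2, w = omega*tau
        a = (wt**2 / (1 + wt**2)) ** 2 + (wt / (1 + wt**2)) ** 2
        b = 2.0 * e_inf * wt**2 / (1 + wt**2)
        c = e_inf**2 - target**2
        disc = b**2 - 4 * a * c
        if disc <= 0:
            raise ValueError("dynamic modulus target below equilibrium stiffness")
        e1 = (-b + np.sqrt(disc)) / (2 * a)

    t = _time_grid(protocol)
    stress = np.zeros_like(t)
    strain = np.zeros_like(t)
    for k in range(protocol.n_steps):
        t0 = protocol.step_start(k)
        t1 = t0 + protocol.ramp_duration
        stress += _sls_ramp_stress(t, t0, t1, protocol.ramp_rate, e_inf, e1, tau_s)
        strain += np.clip((t - t0) * protocol.ramp_rate, 0.0, protocol.step_strain)
    sine = t >= protocol.sine_start
    tp = t[sine] - protocol.sine_start
    stress[sine] += _sls_sine_stress(
        tp, protocol.sine_amplitude, omega, e_inf, e1, tau_s
    )
    strain[sine] += protocol.sine_amplitude * np.sin(omega * tp)

    r = INDENTER_DIAMETER_UM * 1e-6 / 2.0
    force = stress * 1e3 * np.pi * r**2  # kPa -> Pa -> N
    if noise_sd_fraction > 0:
        rng = rng or np.random.default_rng()
        force = force + rng.standard_normal(force.size) * noise_sd_fraction * np.abs(
            force
        ).max()
    return IndentationRecord(
        time=t,
        force=force,
        displacement=strain * sample_thickness_um,
        sample_thickness_um=sample_thickness_um,
        protocol=protocol,
    )


def equilibrium_modulus(
    record: IndentationRecord,
    kappa: float = 1.0,
    nu: float = 0.1,
    equilibrium_window: float = 0.1,
) -> tuple[float, float]:
    """Equilibrium modulus (kPa) and the R^2 of the linear-region fit.

    Equilibrium stress per step is the mean stress over the final
    ``equilibrium_window`` fraction of each hold; E_eq is the slope of
    equilibrium stress vs. applied strain over the contiguous run of >= 2
    steps maximising the fit R^2 (larger runs win ties), converted with
    ``E = slope * (1 - nu^2) / kappa``.
    """
    protocol = record.protocol
    if protocol.n_steps < 2:
        raise ValueError("need at least 2 relaxation steps")
    stress = record.stress_kpa
    eq_stress, eq_strain = [], []
    for k in range(protocol.n_steps):
        hold_start = protocol.step_start(k) + protocol.ramp_duration
        hold_end = protocol.step_start(k + 1) if k + 1 < protocol.n_steps else protocol.sine_start
        win_start = hold_end - equilibrium_window * (hold_end - hold_start)
        mask = (record.time >= win_start) & (record.time < hold_end)
        if not np.any(mask):
            raise ValueError(f"no samples in equilibrium window of step {k}")
        eq_stress.append(float(stress[mask].mean()))
        eq_strain.append((k + 1) * protocol.step_strain)
    eq_stress = np.array(eq_stress)
    eq_strain = np.array(eq_strain)
    if np.any(np.diff(eq_stress) < 0):
        warnings.warn("non-monotone equilibrium stresses; fit returned anyway")

    best = None
    for size in range(2, protocol.n_steps + 1):
        for start in range(protocol.n_steps - size + 1):
            sl = slice(start, start + size)
            slope, intercept = np.polyfit(eq_strain[sl], eq_stress[sl], 1)
            fitted = slope * eq_strain[sl] + intercept
            ss_res = float(np.sum((eq_stress[sl] - fitted) ** 2))
            ss_tot = float(np.sum((eq_stress[sl] - eq_stress[sl].mean()) ** 2))
            r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
            key = (round(r2, 6), size, -start)
            if best is None or key > best[0]:
                best = (key, slope, r2)
    _, slope, r2 = best
    return float(slope * (1.0 - nu**2) / kappa), float(r2)


def _fit_sinusoid(t, y, freq):
    """Least-squares fit y ~ A sin + B cos + C at a known frequency; returns
    (amplitude, rms residual)."""
    w = 2.0 * np.pi * freq
    M = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    amp = float(np.hypot(coef[0], coef[1]))
    resid = float(np.sqrt(np.mean((y - M @ coef) ** 2)))
    return amp, resid


def dynamic_modulus(
    record: IndentationRecord,
    kappa: float = 1.0,
    nu: float = 0.5,
    residual_threshold: float = 0.2,
    skip_cycles: int = 3,
) -> tuple[float, float]:
    """Dynamic modulus (MPa) and the relative stress-fit residual.

    Stress and strain amplitudes come from sinusoid fits at the protocol
    frequency over the sinusoidal segment (initial transient cycles
    skipped); E_dyn = (sigma_amp / eps_amp) * (1 - nu^2) / kappa. The
    amplitude ratio is phase-invariant by construction.
    """
    protocol = record.protocol
    if protocol.sine_cycles < 5:
        raise ValueError("need at least 5 sinusoid cycles")
    start = protocol.sine_start + skip_cycles / protocol.sine_freq
    mask = record.time >= start
    t = record.time[mask]
    stress_amp, resid = _fit_sinusoid(t, record.stress_kpa[mask], protocol.sine_freq)
    strain_amp, _ = _fit_sinusoid(t, record.strain[mask], protocol.sine_freq)
    if strain_amp == 0:
        raise ValueError("no sinusoidal strain present")
    rel_resid = resid / max(stress_amp, 1e-300)
    if rel_resid > residual_threshold:
        warnings.warn(f"sinusoid fit residual {rel_resid:.2g} above threshold")
    e_dyn_kpa = stress_amp / strain_amp * (1.0 - nu**2) / kappa
    return float(e_dyn_kpa / 1e3), float(rel_resid)


def modulus_pair(record: IndentationRecord, kappa: float = 1.0) -> ModulusPair:
    e_eq, r2 = equilibrium_modulus(record, kappa=kappa)
    e_dyn, resid = dynamic_modulus(record, kappa=kappa)
    return ModulusPair(E_eq_kpa=e_eq, E_dyn_mpa=e_dyn, eq_fit_r2=r2,
                       dyn_fit_residual=resid)
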