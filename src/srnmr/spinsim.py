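"""Indirect-dimension interferogram simulation under a scan schedule.

The accumulated complex signal at increment ``i`` for a set of spin
groups is

    values[i] = sum_k n_scans[i] * phase_sign[i] * amp_k
                * exp(2j*pi*offset_k*t1[i])
                * prod_J cos(pi*J*t_eff[i])
                * exp(-t1[i]/T2_k)   + noise

Chemical shift and relaxation evolve during ``t1`` only (the 2*delta
element refocuses the shift), while every passive scalar coupling is
active for the full effective time ``t_eff = t1 + 2*delta``.  Noise is
complex Gaussian; accumulating ``NS`` scans scales the deterministic part
by ``NS`` and the noise standard deviation by ``sqrt(NS)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedule import Schedule, ScheduleError

__all__ = [
    "SpinGroup",
    "Interferogram",
    "DirectDimParams",
    "simulate_interferogram",
    "simulate_windowed_reference",
    "simulate_strip",
]


@dataclass(frozen=True)
class SpinGroup:
    """One resonance in the indirect dimension.

    ``offset_hz`` is relative to the carrier; ``couplings_hz`` lists the
    passive scalar couplings (may be empty, e.g. a glycine Cα with no
    Cβ); ``t2_s`` is the transverse relaxation time.
    """

    label: str
    offset_hz: float
    couplings_hz: tuple[float, ...] = ()
    t2_s: float = 0.1
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.t2_s > 0:
            raise ValueError(f"T2 must be positive, got {self.t2_s}")
        object.__setattr__(self, "couplings_hz", tuple(self.couplings_hz))


@dataclass
class Interferogram:
    """Complex indirect-dimension vector plus its acquisition metadata."""

    values: np.ndarray
    schedule: Schedule
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if len(self.values) != len(self.schedule):
            raise ValueError(
                f"interferogram length {len(self.values)} != schedule rows "
                f"{len(self.schedule)}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame(
            {
                "index": np.arange(len(self)),
                "real": self.values.real,
                "imag": self.values.imag,
            }
        )
        frame.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path, schedule: Schedule) -> "Interferogram":
        frame = pd.read_csv(path, sep="\t")
        values = frame["real"].to_numpy() + 1j * frame["imag"].to_numpy()
        return cls(values=values, schedule=schedule)


def _coherent_signal(spins, schedule: Schedule) -> np.ndarray:
    t1 = schedule.t1_s
    t_eff = schedule.t_eff_s
    total = np.zeros(len(schedule), dtype=complex)
    for spin in spins:
        sig = spin.amplitude * np.exp(2j * np.pi * spin.offset_hz * t1 - t1 / spin.t2_s)
        for j in spin.couplings_hz:
            sig = sig * np.cos(np.pi * j * t_eff)
        total += sig
    return total


def simulate_interferogram(
    spins,
    schedule: Schedule,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    per_scan_noise: bool = False,
) -> Interferogram:
    """Accumulate the schedule's scans for a list of :class:`SpinGroup`.

    ``noise_sigma`` is the per-scan complex-Gaussian standard deviation
    (per real/imag component).  By default the accumulated noise is drawn
    once per increment with sd ``sigma*sqrt(n_scans)``; the statistically
    identical ``per_scan_noise=True`` mode literally sums n_scans draws.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    spins = list(spins)
    values = schedule.n_scans * schedule.phase_sign * _coherent_signal(spins, schedule)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        n = len(schedule)
        if per_scan_noise:
            noise = np.empty(n, dtype=complex)
            for i, ns in enumerate(schedule.n_scans):
                draws = rng.normal(0.0, noise_sigma, (int(ns), 2))
                noise[i] = draws[:, 0].sum() + 1j * draws[:, 1].sum()
        else:
            scale = noise_sigma * np.sqrt(schedule.n_scans)
            noise = scale * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
        values = values + noise
    return Interferogram(values=values, schedule=schedule, noise_sigma=noise_sigma, seed=seed)


def simulate_windowed_reference(
    spins,
    schedule: Schedule,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> Interferogram:
    """Constant-scan acquisition multiplied post hoc by the 1/cos window.

    The same pulse-sequence timing as ``schedule`` (delay switch and
    phase inversion) is acquired with a constant ``base_scans`` per
    increment; the stored ideal weight is then applied as a window
    function.  Noiseless, this equals the residual-corrected SR signal
    exactly — but the window multiplies the noise too, which is why SR
    wins sqrt(weight) in signal-to-noise.
    """
    if schedule.mode == "SR":
        # delay switch + phase flip are in the sequence; the capped ideal
        # weight is the (positive) window
        window = schedule.ideal_weight
    else:
        # no skip: window is the signed 1/cos and may blow up at the crossing
        c = np.cos(np.pi * schedule.params.j_hz * schedule.t_eff_s)
        if np.min(np.abs(c)) < 0.02:
            raise ScheduleError(
                "1/cos window is singular on this grid: a t_eff falls at the "
                "coupling zero crossing; build a skip-aware SR schedule "
                "(delta_A/delta_B switch) instead"
            )
        window = 1.0 / c
    base = schedule.params.base_scans
    signal = base * schedule.phase_sign * _coherent_signal(list(spins), schedule)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        n = len(schedule)
        scale = noise_sigma * np.sqrt(base)
        signal = signal + scale * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    values = signal * window
    return Interferogram(values=values, schedule=schedule, noise_sigma=noise_sigma, seed=seed)


@dataclass(frozen=True)
class DirectDimParams:
    """Conventional direct-dimension acquisition: ``n_points`` complex
    points spanning ``aq_s`` seconds with relaxation time ``t2_s``."""

    n_points: int = 128
    aq_s: float = 0.05
    t2_s: float = 0.03

    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.aq_s, self.n_points)


def simulate_strip(
    spins_with_direct_offsets,
    schedule: Schedule,
    direct_params: DirectDimParams = DirectDimParams(),
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """2D (indirect x direct) time-domain strip.

    ``spins_with_direct_offsets`` is an iterable of ``(SpinGroup,
    direct_offset_hz)`` pairs.  The direct dimension is always acquired
    conventionally: each spin contributes the outer product of its
    indirect interferogram with a decaying complex exponential at its
    direct offset.
    """
    t2d = direct_params.times()
    grid = np.zeros((len(schedule), direct_params.n_points), dtype=complex)
    pairs = list(spins_with_direct_offsets)
    for spin, f2 in pairs:
        indirect = simulate_interferogram([spin], schedule).values
        direct = np.exp(2j * np.pi * f2 * t2d - t2d / direct_params.t2_s)
        grid += np.outer(indirect, direct)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sigma * np.sqrt(schedule.n_scans)[:, None]
        grid = grid + scale * (
            rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape)
        )
    return grid
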