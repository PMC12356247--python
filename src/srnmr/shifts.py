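"""Synthetic backbone chemical shifts and triple-resonance peak lists.

The generator draws per-residue ¹⁵N/¹H(N)/¹³Cα/¹³Cβ shifts from
residue-type random-coil means plus Gaussian dispersion, emulating the
kind of shift tables one would obtain from a public repository for a
folded protein.  Peak lists for HSQC/HNCA/HNcoCA/CBCAcoNH and their
super-resolution (SR) variants follow the standard magnetization-transfer
topology: each observable amide (residues 2..L, non-proline) reports its
own and/or the preceding residue's Cα (and Cβ for CBCAcoNH).

SR changes two things only: the ¹³C dimension linewidth (long evolution
time) and the fine structure (the ¹J(Cα,Cβ) doublet collapses to a
singlet).  Peak coordinates are identical to the standard experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "RANDOM_COIL",
    "DISPERSION_SD",
    "ShiftTable",
    "Peak",
    "MultidomainSpec",
    "ExperimentParams",
    "EXPERIMENTS",
    "generate_shift_table",
    "simulate_peaklist",
    "ambiguity_metric",
    "build_multidomain",
]

# Random-coil backbone shifts (ppm): N, HN, CA, CB per residue type.
# Literature-typical random-coil values; a modelling choice for the
# synthetic generator, not measurements from any single dataset.
RANDOM_COIL: dict[str, tuple[float | None, float | None, float, float | None]] = {
    "A": (123.8, 8.24, 52.5, 19.1),
    "R": (120.5, 8.23, 56.0, 30.9),
    "N": (118.7, 8.40, 53.1, 38.9),
    "D": (120.4, 8.34, 54.2, 41.1),
    "C": (118.8, 8.32, 58.2, 28.0),
    "Q": (119.8, 8.32, 55.7, 29.4),
    "E": (120.2, 8.42, 56.6, 29.9),
    "G": (108.8, 8.33, 45.1, None),
    "H": (118.2, 8.42, 55.0, 29.0),
    "I": (119.9, 8.00, 61.1, 38.8),
    "L": (121.8, 8.16, 55.1, 42.4),
    "K": (120.4, 8.29, 56.2, 33.1),
    "M": (119.6, 8.28, 55.4, 32.9),
    "F": (120.3, 8.30, 57.7, 39.6),
    "P": (None, None, 63.3, 32.1),
    "S": (115.7, 8.31, 58.3, 63.8),
    "T": (113.6, 8.15, 61.8, 69.8),
    "W": (121.3, 8.25, 57.5, 29.6),
    "Y": (120.3, 8.28, 57.9, 38.8),
    "V": (119.2, 8.03, 62.2, 32.9),
}

#: structural-dispersion standard deviations (ppm) at dispersion_scale=1,
#: folded-protein-like: N, HN, CA, CB
DISPERSION_SD = {"N": 2.5, "H": 0.45, "CA": 1.5, "CB": 1.3}

#: ¹J(Cα,Cβ) coupling left active in standard (non-SR) C dimensions
J_CACB_HZ = 35.0

#: carbon Larmor frequency (MHz) at the default 700-MHz proton field
CARBON_MHZ = 176.05

ExperimentName = Literal[
    "HSQC15N", "HNCA", "SR-HNCA", "HNcoCA", "SR-HNcoCA", "CBCAcoNH"
]


@dataclass(frozen=True)
class ExperimentParams:
    """Per-experiment ¹³C-dimension acquisition model.

    The apparent C linewidth is ``0.66/t1_max`` (apodized-truncation
    width) plus the doublet splitting for peaks whose fine structure is
    an unresolved ¹J(Cα,Cβ) doublet.
    """

    name: str
    sr: bool
    c_t1_max_s: float | None  # None: no carbon dimension (HSQC15N)
    intra: bool
    sequential: bool
    cbeta: bool = False

    def c_fwhm_hz(self, doublet: bool) -> float | None:
        if self.c_t1_max_s is None:
            return None
        width = 0.66 / self.c_t1_max_s
        if doublet:
            width += J_CACB_HZ
        return width


EXPERIMENTS: dict[str, ExperimentParams] = {
    "HSQC15N": ExperimentParams("HSQC15N", False, None, False, False),
    "HNCA": ExperimentParams("HNCA", False, 8e-3, True, True),
    "SR-HNCA": ExperimentParams("SR-HNCA", True, 38e-3, True, True),
    "HNcoCA": ExperimentParams("HNcoCA", False, 8e-3, False, True),
    "SR-HNcoCA": ExperimentParams("SR-HNcoCA", True, 38e-3, False, True),
    "CBCAcoNH": ExperimentParams("CBCAcoNH", False, 8e-3, False, True, cbeta=True),
}


@dataclass
class ShiftTable:
    """Backbone shift table: one row per residue (1-based ``res_index``).

    ``frame`` columns: res_index, res_type, n_ppm, h_ppm, ca_ppm, cb_ppm;
    NaN marks absent atoms (glycine Cβ, proline amide).
    """

    frame: pd.DataFrame

    @property
    def sequence(self) -> str:
        return "".join(self.frame["res_type"])

    def __len__(self) -> int:
        return len(self.frame)

    def row(self, res_index: int) -> pd.Series:
        return self.frame.set_index("res_index").loc[res_index]


def generate_shift_table(
    sequence: str, dispersion_scale: float = 1.0, seed: int | None = None
) -> ShiftTable:
    """Draw a synthetic shift table for a one-letter sequence.

    Each atom shift is its residue-type random-coil mean plus a Gaussian
    deviate of sd ``dispersion_scale * DISPERSION_SD[atom]``.
    Deterministic under ``seed``.
    """
    sequence = sequence.strip().upper()
    bad = sorted(set(sequence) - set(RANDOM_COIL))
    if bad:
        raise ValueError(f"unknown residue letter(s): {''.join(bad)}")
    if dispersion_scale < 0:
        raise ValueError("dispersion_scale must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for i, aa in enumerate(sequence, start=1):
        n0, h0, ca0, cb0 = RANDOM_COIL[aa]

        def draw(mean, atom):
            if mean is None:
                return math.nan
            return mean + dispersion_scale * DISPERSION_SD[atom] * rng.standard_normal()

        records.append(
            {
                "res_index": i,
                "res_type": aa,
                "n_ppm": draw(n0, "N"),
                "h_ppm": draw(h0, "H"),
                "ca_ppm": draw(ca0, "CA"),
                "cb_ppm": draw(cb0, "CB"),
            }
        )
    return ShiftTable(pd.DataFrame.from_records(records))


@dataclass(frozen=True)
class Peak:
    """One simulated cross peak.

    ``truth`` is ``(strip_residue, carbon_residue)`` for 3D peaks and
    ``(strip_residue,)`` for the 2D HSQC; it is hidden from solvers and
    used only for scoring.
    """

    experiment: str
    h_ppm: float
    n_ppm: float
    c_ppm: float | None
    intensity: float
    c_fwhm_hz: float | None
    fine_structure: Literal["singlet", "doublet"]
    j_hz: float | None
    truth: tuple[int, ...]
    c_atom: str | None = None  # "CA" or "CB"


def _observable_amides(table: ShiftTable) -> list[int]:
    seq = table.sequence
    # residue 1 is lost to amide exchange; prolines have no amide proton
    return [i for i in range(2, len(seq) + 1) if seq[i - 1] != "P"]


def simulate_peaklist(
    table: ShiftTable,
    experiment: str,
    intra_ratio: float = 1.0,
    sequential_ratio: float = 0.5,
) -> list[Peak]:
    """Simulate the cross-peak list of one experiment from a shift table."""
    if experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {experiment!r}; choose from {sorted(EXPERIMENTS)}"
        )
    exp = EXPERIMENTS[experiment]
    frame = table.frame.set_index("res_index")
    seq = table.sequence
    peaks: list[Peak] = []
    for i in _observable_amides(table):
        amide = frame.loc[i]
        h, n = float(amide["h_ppm"]), float(amide["n_ppm"])
        if exp.c_t1_max_s is None:
            peaks.append(
                Peak(experiment, h, n, None, 1.0, None, "singlet", None, (i,))
            )
            continue

        def carbon_peak(j: int, atom: str, intensity: float) -> Peak | None:
            shift = float(frame.loc[j, "ca_ppm" if atom == "CA" else "cb_ppm"])
            if math.isnan(shift):
                return None
            # SR neglects the CA-CB coupling; without a CB partner
            # (glycine CA) there is no doublet either way
            has_partner = (
                not math.isnan(float(frame.loc[j, "cb_ppm"]))
                if atom == "CA"
                else True
            )
            doublet = (not exp.sr) and has_partner
            return Peak(
                experiment,
                h,
                n,
                shift,
                intensity,
                exp.c_fwhm_hz(doublet),
                "doublet" if doublet else "singlet",
                J_CACB_HZ if doublet else None,
                (i, j),
                c_atom=atom,
            )

        if exp.intra:
            pk = carbon_peak(i, "CA", intra_ratio)
            if pk:
                peaks.append(pk)
        if exp.sequential and i >= 2:
            pk = carbon_peak(i - 1, "CA", sequential_ratio)
            if pk:
                peaks.append(pk)
            if exp.cbeta:
                pk = carbon_peak(i - 1, "CB", sequential_ratio)
                if pk:
                    peaks.append(pk)
    return peaks


def ambiguity_metric(
    peaks: list[Peak], matching_tolerance_ppm: float | None = None
) -> float:
    """Mean number of intra-Cα candidates matching each sequential Cα peak.

    For every *linkable* sequential Cα peak (one whose carbon residue is
    also represented by an intra peak — the N-terminal residue's Cα never
    is), count the intra Cα peaks whose shift lies within the tolerance;
    1.0 means every sequential peak points to exactly one strip.  This is
    a truth-aware diagnostic of peak-list crowding, not a solver.
    Default tolerance: half the mean C-dimension FWHM, converted to ppm
    at the default carbon frequency.
    """
    intra_peaks = [p for p in peaks if p.c_ppm is not None and p.truth[1] == p.truth[0]]
    intra_residues = {p.truth[1] for p in intra_peaks}
    seq_peaks = [p for p in peaks if p.c_ppm is not None and p.truth[1] != p.truth[0]
                 and p.c_atom == "CA" and p.truth[1] in intra_residues]
    if not seq_peaks or not intra_peaks:
        raise ValueError("need both sequential and intra Cα peaks (e.g. an HNCA list)")
    if matching_tolerance_ppm is None:
        widths = [p.c_fwhm_hz for p in seq_peaks + intra_peaks]
        matching_tolerance_ppm = (float(np.mean(widths)) / 2.0) / CARBON_MHZ
    intra_vals = np.array([p.c_ppm for p in intra_peaks])
    counts = [
        int(np.sum(np.abs(intra_vals - p.c_ppm) <= matching_tolerance_ppm))
        for p in seq_peaks
    ]
    return float(np.mean(counts))


@dataclass(frozen=True)
class MultidomainSpec:
    """Sequences to concatenate with glycine linkers into one system."""

    sequences: tuple[str, ...]
    linker_length: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        if not self.sequences:
            raise ValueError("need at least one member sequence")
        if self.linker_length < 0:
            raise ValueError("linker_length must be >= 0")

    @property
    def total_length(self) -> int:
        m = len(self.sequences)
        return sum(len(s) for s in self.sequences) + self.linker_length * (m - 1)


def build_multidomain(
    spec: MultidomainSpec, dispersion_scale: float = 1.0, seed: int | None = None
) -> ShiftTable:
    """Concatenate member shift tables with fresh glycine-linker shifts."""
    rng = np.random.default_rng(seed)
    parts: list[pd.DataFrame] = []
    for k, seqpart in enumerate(spec.sequences):
        if k > 0 and spec.linker_length:
            linker = generate_shift_table(
                "G" * spec.linker_length,
                dispersion_scale,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            parts.append(linker.frame)
        member = generate_shift_table(
            seqpart, dispersion_scale, seed=int(rng.integers(0, 2**31 - 1))
        )
        parts.append(member.frame)
    frame = pd.concat(parts, ignore_index=True)
    frame["res_index"] = np.arange(1, len(frame) + 1)
    table = ShiftTable(frame)
    assert len(table) == spec.total_length
    return table
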