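"""Dynamic scan-number schedules for pseudo-homodecoupling.

A scalar ¹J_CC coupling modulates the indirect-dimension signal by
``cos(pi * J * t_eff)``, where the effective coupling-evolution time
``t_eff = t1 + 2*delta`` includes a fixed pulse-sequence delay ``delta``
during which the coupling — but not the chemical shift — evolves.  The
super-resolution (SR) trick is to acquire ``round(base * 1/|cos|)`` scans
at each increment so the accumulated signal is flat in the coupling and
decays only with T2, i.e. the coupling is *pseudo-decoupled*.

Two complications are handled here:

* near the cosine zero crossing at ``t_eff = 1/(2J)`` the required scan
  count diverges, so a window of ``+/- switch_margin`` around the crossing
  is jumped over by switching the sequence delay from a short ``delta_A``
  to a longer ``delta_B`` (the t1 grid itself stays uniform);
* past the crossing the cosine is negative, so the receiver/pulse phase is
  inverted (``phi_B = phi_A + pi``) to keep the accumulated signal
  positive; the stored ``phase_sign`` is the sign of the cosine.

Because only integer scan counts can be acquired, each row also stores the
multiplicative *residual* ``base * weight / n_scans`` that restores the
smooth exponential envelope in post-processing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "AcqParams",
    "Schedule",
    "ScheduleError",
    "first_zero_crossing",
    "switch_time",
    "ideal_weight",
    "build_schedule",
    "scan_budget",
    "ScanBudget",
    "residual_correction_vector",
]

RoundingMode = Literal["nearest-integer", "nearest-multiple-of-k"]
BoostCap = Literal["cap-after-1/J", "cap-after-zero-crossing", "no-cap"]

# numerical guard when classifying a grid point as before/after the switch
_T_ATOL = 1e-12


class ScheduleError(ValueError):
    """Raised for invalid acquisition parameters or impossible schedules."""


@dataclass(frozen=True)
class AcqParams:
    """Parameters defining one indirect-dimension acquisition.

    Parameters
    ----------
    j_hz
        Scalar coupling to be pseudo-decoupled (Hz), e.g. 35 for
        ¹J(Cα,Cβ) in HNCA or 38 for methyl ¹J_CC.
    delta_a_s, delta_b_s
        Short and long pulse-sequence delays (s).  ``2*delta`` adds to the
        coupling-evolution time of every increment; switching A -> B jumps
        ``t_eff`` over the cosine zero crossing.
    switch_margin_s
        Half-width of the skipped window around the zero crossing (s).
    t1_max_s
        Maximal evolution time (s).
    n_increments
        Number of complex points on the uniform t1 grid.
    base_scans
        Scans per increment in the conventional reference experiment.
    rounding_mode
        ``"nearest-integer"``: ``n = round(base * weight)``;
        ``"nearest-multiple-of-k"``: round to the nearest multiple of
        ``round_multiple`` (phase-cycle friendly).  Both floor at
        ``base_scans``.
    round_multiple
        k for the nearest-multiple-of-k mode.
    boost_cap
        ``"cap-after-1/J"`` (default): scans are not increased once
        ``t_eff > 1/J`` so the signal decays naturally toward zero;
        ``"cap-after-zero-crossing"``: no boost anywhere past the
        crossing (reproduces the published mean scan budget but leaves
        the cosine modulation live between 1/(2J) and 1/J);
        ``"no-cap"``: boost everywhere.
    """

    j_hz: float
    delta_a_s: float
    delta_b_s: float
    t1_max_s: float
    n_increments: int
    base_scans: int = 4
    switch_margin_s: float = 2e-3
    rounding_mode: RoundingMode = "nearest-integer"
    round_multiple: int = 2
    boost_cap: BoostCap = "cap-after-1/J"

    def __post_init__(self) -> None:
        if not self.j_hz > 0:
            raise ScheduleError(f"coupling must be positive, got J={self.j_hz} Hz")
        if not (0 <= self.delta_a_s < self.delta_b_s):
            raise ScheduleError(
                f"need 0 <= delta_A < delta_B, got {self.delta_a_s}, {self.delta_b_s}"
            )
        if not self.switch_margin_s > 0:
            raise ScheduleError("switch_margin_s must be positive")
        if not self.t1_max_s > 0:
            raise ScheduleError("t1_max_s must be positive")
        if self.n_increments < 2:
            raise ScheduleError("n_increments must be >= 2")
        if self.base_scans < 1:
            raise ScheduleError("base_scans must be >= 1")
        if self.rounding_mode not in ("nearest-integer", "nearest-multiple-of-k"):
            raise ScheduleError(f"unknown rounding_mode {self.rounding_mode!r}")
        if self.boost_cap not in ("cap-after-1/J", "cap-after-zero-crossing", "no-cap"):
            raise ScheduleError(f"unknown boost_cap {self.boost_cap!r}")
        if self.rounding_mode == "nearest-multiple-of-k" and self.round_multiple < 1:
            raise ScheduleError("round_multiple must be >= 1")


def first_zero_crossing(j_hz: float) -> float:
    """Effective time (s) of the first zero of ``cos(pi*J*t_eff)``: 1/(2J)."""
    if not j_hz > 0:
        raise ScheduleError(f"coupling must be positive, got J={j_hz} Hz")
    return 1.0 / (2.0 * j_hz)


def switch_time(params: AcqParams) -> float:
    """Smallest t1 (s) at which delta_B and the inverted phase are used.

    ``t_switch = 1/(2J) - 2*delta_A - switch_margin``: below it the short
    delay keeps ``t_eff`` at least one margin before the zero crossing;
    at and above it the long delay places ``t_eff`` on the far side.
    """
    t_sw = first_zero_crossing(params.j_hz) - 2.0 * params.delta_a_s - params.switch_margin_s
    if t_sw <= 0:
        raise ScheduleError(
            f"switch time {t_sw * 1e3:.3f} ms is not positive: J={params.j_hz} Hz is "
            "too large for delta_A/switch_margin"
        )
    return t_sw


def _reaches_switch(params: AcqParams) -> bool:
    """Whether the t1 grid extends to the delay switch at all."""
    try:
        return params.t1_max_s >= switch_time(params) - _T_ATOL
    except ScheduleError:
        raise


def ideal_weight(t1: float, params: AcqParams) -> tuple[float, int, str]:
    """Ideal scan-weight for one increment.

    Returns
    -------
    (weight, phase_sign, delta_used)
        ``weight = 1/|cos(pi*J*t_eff)|`` (set to 1 in the capped tail),
        ``phase_sign = sign(cos(pi*J*t_eff))`` and the delay branch
        ``"A"`` or ``"B"``.
    """
    if t1 < -_T_ATOL or t1 > params.t1_max_s + _T_ATOL:
        raise ScheduleError(f"t1={t1} s outside [0, t1_max={params.t1_max_s} s]")
    t_sw = switch_time(params)
    use_b = t1 >= t_sw - _T_ATOL
    delta = params.delta_b_s if use_b else params.delta_a_s
    t_eff = t1 + 2.0 * delta
    zc = first_zero_crossing(params.j_hz)
    if abs(t_eff - zc) < params.switch_margin_s - 1e-9:
        raise ScheduleError(
            f"t_eff={t_eff * 1e3:.3f} ms falls inside the skipped window around the "
            f"zero crossing at {zc * 1e3:.3f} ms; the delta_A/delta_B switch must "
            "prevent this"
        )
    c = math.cos(math.pi * params.j_hz * t_eff)
    sign = 1 if c >= 0 else -1
    weight = 1.0 / abs(c)
    if params.boost_cap == "cap-after-1/J" and t_eff > 1.0 / params.j_hz:
        weight = 1.0
    elif params.boost_cap == "cap-after-zero-crossing" and t_eff > zc:
        weight = 1.0
    return weight, sign, "B" if use_b else "A"


def _round_scans(weight: float, params: AcqParams) -> int:
    target = params.base_scans * weight
    if params.rounding_mode == "nearest-integer":
        n = int(round(target))
    else:
        k = params.round_multiple
        n = k * int(round(target / k))
    return max(params.base_scans, n)


@dataclass
class Schedule:
    """Per-increment acquisition table (uniform t1 grid).

    Columns are exposed as numpy arrays of length ``n_increments``:
    ``t1_s``, ``delta_used`` ('A'/'B'), ``t_eff_s``, ``phase_sign`` (+-1),
    ``ideal_weight`` (>= 1), ``n_scans`` (int >= base), ``residual``
    (``base*weight/n_scans``).
    """

    params: AcqParams
    mode: Literal["conventional", "SR"]
    t1_s: np.ndarray
    delta_used: np.ndarray
    t_eff_s: np.ndarray
    phase_sign: np.ndarray
    ideal_weight: np.ndarray
    n_scans: np.ndarray
    residual: np.ndarray
    phase_cycle: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t1_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(len(self)),
                "t1_s": self.t1_s,
                "delta_used": self.delta_used,
                "t_eff_s": self.t_eff_s,
                "phase_sign": self.phase_sign,
                "n_scans": self.n_scans,
                "residual": self.residual,
            }
        )

    def to_tsv(self, path) -> None:
        """Write the schedule as TSV with an AcqParams header comment."""
        header = "# " + json.dumps({"mode": self.mode, **asdict(self.params)})
        frame = self.to_frame().copy()
        frame["t1_s"] = frame["t1_s"].map(lambda v: f"{v:.9f}")
        frame["t_eff_s"] = frame["t_eff_s"].map(lambda v: f"{v:.9f}")
        frame["residual"] = frame["residual"].map(lambda v: f"{v:.9f}")
        with open(path, "w") as fh:
            fh.write(header + "\n")
            frame.to_csv(fh, sep="\t", index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "mode": self.mode,
            "params": asdict(self.params),
            "phase_cycle": self.phase_cycle,
            "rows": {
                "t1_s": self.t1_s.tolist(),
                "delta_used": self.delta_used.tolist(),
                "t_eff_s": self.t_eff_s.tolist(),
                "phase_sign": self.phase_sign.tolist(),
                "ideal_weight": self.ideal_weight.tolist(),
                "n_scans": self.n_scans.tolist(),
                "residual": self.residual.tolist(),
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "Schedule":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        rows = payload["rows"]
        return cls(
            params=AcqParams(**payload["params"]),
            mode=payload["mode"],
            t1_s=np.asarray(rows["t1_s"], dtype=float),
            delta_used=np.asarray(rows["delta_used"], dtype=object),
            t_eff_s=np.asarray(rows["t_eff_s"], dtype=float),
            phase_sign=np.asarray(rows["phase_sign"], dtype=int),
            ideal_weight=np.asarray(rows["ideal_weight"], dtype=float),
            n_scans=np.asarray(rows["n_scans"], dtype=int),
            residual=np.asarray(rows["residual"], dtype=float),
            phase_cycle=payload.get("phase_cycle", {}),
        )


# Hardware phase tables carried along as metadata only; the simulator models
# phase inversion through phase_sign.
_PHASE_CYCLE = {
    "phi_A": "x,-x",
    "phi_B": "-x,x",
    "phi_rec": "x,-x,-x,x",
}


def build_schedule(
    params: AcqParams, mode: Literal["conventional", "SR"] = "SR"
) -> Schedule:
    """Build the per-increment table for one acquisition.

    The t1 grid is ``linspace(0, t1_max, n_increments)``.  Conventional
    mode uses delta_A, weight 1 and phase +1 throughout; SR mode applies
    the delay switch, phase inversion, scan boost and residual
    bookkeeping.  Construction fails if any SR row lands inside the
    skipped window around the first zero crossing.
    """
    if mode not in ("conventional", "SR"):
        raise ScheduleError(f"unknown mode {mode!r}")
    t1 = np.linspace(0.0, params.t1_max_s, params.n_increments)
    n = params.n_increments
    if mode == "conventional":
        t_eff = t1 + 2.0 * params.delta_a_s
        return Schedule(
            params=params,
            mode=mode,
            t1_s=t1,
            delta_used=np.full(n, "A", dtype=object),
            t_eff_s=t_eff,
            phase_sign=np.ones(n, dtype=int),
            ideal_weight=np.ones(n),
            n_scans=np.full(n, params.base_scans, dtype=int),
            residual=np.ones(n),
            phase_cycle=dict(_PHASE_CYCLE),
        )

    zc = first_zero_crossing(params.j_hz)
    delta_used = np.empty(n, dtype=object)
    t_eff = np.empty(n)
    sign = np.empty(n, dtype=int)
    weight = np.empty(n)
    n_scans = np.empty(n, dtype=int)
    for i, t in enumerate(t1):
        w, s, branch = ideal_weight(float(t), params)
        if abs((t + 2 * (params.delta_b_s if branch == "B" else params.delta_a_s)) - zc) < (
            params.switch_margin_s - 1e-9
        ):
            raise ScheduleError(f"row {i}: t_eff inside the skipped zero-crossing window")
        weight[i] = w
        sign[i] = s
        delta_used[i] = branch
        t_eff[i] = t + 2 * (params.delta_b_s if branch == "B" else params.delta_a_s)
        n_scans[i] = _round_scans(w, params)
    residual = params.base_scans * weight / n_scans
    return Schedule(
        params=params,
        mode="SR",
        t1_s=t1,
        delta_used=delta_used,
        t_eff_s=t_eff,
        phase_sign=sign,
        ideal_weight=weight,
        n_scans=n_scans,
        residual=residual,
        phase_cycle=dict(_PHASE_CYCLE),
    )


@dataclass(frozen=True)
class ScanBudget:
    total_scans: int
    mean_scans: float
    time_ratio_vs_conventional: float


def scan_budget(schedule: Schedule) -> ScanBudget:
    """Total and mean scans per increment, and time cost vs conventional.

    The time ratio compares total scans against a conventional schedule
    with the same increment count at ``base_scans`` each.
    """
    if len(schedule) == 0:
        raise ScheduleError("empty schedule")
    total = int(schedule.n_scans.sum())
    conventional = schedule.params.base_scans * len(schedule)
    return ScanBudget(
        total_scans=total,
        mean_scans=total / len(schedule),
        time_ratio_vs_conventional=total / conventional,
    )


def residual_correction_vector(schedule: Schedule) -> np.ndarray:
    """Per-increment factors ``base*weight/n_scans`` restoring the smooth envelope.

    Multiplying the accumulated (noiseless, coupled) SR signal by this
    vector cancels the integer-rounding staircase, leaving a pure
    ``exp(-t1/T2)`` envelope wherever the boost is active (t_eff <= 1/J
    under the default cap).
    """
    return schedule.residual.copy()
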