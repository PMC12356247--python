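"""Experiment presets reproducing the published acquisition settings.

Increment counts follow the acquired/effective time-domain sizes: at a
700-MHz field the ¹³C sweep widths are 165 ppm (methyl HSQC, dwell
~34.4 µs) and 30 ppm (HNCA, dwell ~189 µs), so 8/33/38/42 ms of
evolution correspond to the complex point counts below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .schedule import AcqParams, build_schedule, switch_time
from .specproc import ProcessingParams

__all__ = ["Preset", "PRESETS", "get_preset", "validate_presets"]


@dataclass(frozen=True)
class Preset:
    name: str
    acq: AcqParams
    mode: str  # "SR" or "conventional"
    processing: ProcessingParams = ProcessingParams()
    metadata: dict = field(default_factory=dict)

    def build(self):
        return build_schedule(self.acq, self.mode)


_HSQC_META = {
    "tau_s": 1.7e-3,
    "tau1_s": 0.86e-3,
    "sw_c_ppm": 165.0,
    "sw_h_ppm": 13.0,
    "recycle_delay_s": 0.6,
}
_HNCA_META = {
    "tau_s": 2.3e-3,
    "tau1_s": 12e-3,
    "T_s": 24e-3,
    "sw_c_ppm": 30.0,
    "sw_n_ppm": 35.0,
    "sw_h_ppm": 17.9,
    "recycle_delay_s": 0.6,
}

PRESETS: dict[str, Preset] = {
    "hsqc-sr": Preset(
        "hsqc-sr",
        AcqParams(
            j_hz=38.0,
            delta_a_s=1e-3,
            delta_b_s=3e-3,
            t1_max_s=33e-3,
            n_increments=960,
            base_scans=4,
        ),
        "SR",
        metadata=_HSQC_META,
    ),
    "hsqc-conv-8ms": Preset(
        "hsqc-conv-8ms",
        AcqParams(
            j_hz=38.0,
            delta_a_s=1e-3,
            delta_b_s=3e-3,
            t1_max_s=8e-3,
            n_increments=232,
            base_scans=4,
        ),
        "conventional",
        metadata=_HSQC_META,
    ),
    "hsqc-conv-42ms": Preset(
        "hsqc-conv-42ms",
        AcqParams(
            j_hz=38.0,
            delta_a_s=1e-3,
            delta_b_s=3e-3,
            t1_max_s=42e-3,
            n_increments=1220,
            base_scans=4,
        ),
        "conventional",
        metadata=_HSQC_META,
    ),
    "hnca-sr": Preset(
        "hnca-sr",
        AcqParams(
            j_hz=35.0,
            delta_a_s=10e-6,
            delta_b_s=2e-3,
            t1_max_s=38e-3,
            n_increments=200,
            base_scans=4,
        ),
        "SR",
        metadata=_HNCA_META,
    ),
    "hnca-conv-8ms": Preset(
        "hnca-conv-8ms",
        AcqParams(
            j_hz=35.0,
            delta_a_s=10e-6,
            delta_b_s=2e-3,
            t1_max_s=8e-3,
            n_increments=42,
            base_scans=4,
        ),
        "conventional",
        metadata=_HNCA_META,
    ),
}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def validate_presets() -> None:
    """Assert the presets reproduce the published timing landmarks."""
    assert abs(switch_time(PRESETS["hsqc-sr"].acq) - 9.1e-3) < 0.1e-3
    assert abs(switch_time(PRESETS["hnca-sr"].acq) - 12.3e-3) < 0.1e-3
    assert PRESETS["hsqc-sr"].acq.delta_b_s - PRESETS["hsqc-sr"].acq.delta_a_s == 2e-3
    assert PRESETS["hnca-sr"].acq.t1_max_s == 38e-3
    assert PRESETS["hsqc-sr"].acq.t1_max_s == 33e-3
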