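"""Calibration multipliers shared across the engine and calibration workflow."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["CalibrationParams"]


@dataclass(frozen=True)
class CalibrationParams:
    """The model's three calibration multipliers.

    cs_cali scales clear-sky energy (atmospheric losses), tr_cali scales
    every object transmittance, gr_cali scales terrain shade.  All are
    nominally in (0, 1]; values above 1 can arise from peak calibration
    against an under-predicted observation and are warned about, not
    rejected.  An uncalibrated run uses cs=1, tr=1, gr=0.5.
    """

    cs_cali: float = 1.0
    tr_cali: float = 1.0
    gr_cali: float = 0.5

    def __post_init__(self) -> None:
        for name in ("cs_cali", "tr_cali", "gr_cali"):
            value = getattr(self, name)
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
            if value > 1 + 1e-9:
                warnings.warn(
                    f"{name} = {value} exceeds the nominal (0, 1] range",
                    stacklevel=3)
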