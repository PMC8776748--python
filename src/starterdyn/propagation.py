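"""Propagation-experiment statistics from colony counts (CFU/ml)."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional


@dataclass
class PropagationRecord:
    step_id: str
    cfu_t1: Optional[float] = None  # at inoculation
    cfu_t2: Optional[float] = None  # at harvest
    cfu_before_fd: Optional[float] = None  # around freeze-drying
    cfu_after_fd: Optional[float] = None

    def __post_init__(self):
        for name in ("cfu_t1", "cfu_t2", "cfu_before_fd", "cfu_after_fd"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")

    def generations(self) -> float:
        return generations_from_cfu(self.cfu_t1, self.cfu_t2)

    def survival(self) -> float:
        return survival_rate(self.cfu_before_fd, self.cfu_after_fd)


def generations_from_cfu(cfu_t1: float, cfu_t2: float) -> float:
    """Number of doublings between two counts: log2(CFU(t2)/CFU(t1)).

    Negative when the population shrank.
    """
    if cfu_t1 is None or cfu_t2 is None or cfu_t1 <= 0 or cfu_t2 <= 0:
        raise ValueError("CFU counts must be positive")
    return math.log(cfu_t2 / cfu_t1) / math.log(2)


def survival_rate(cfu_before_fd: float, cfu_after_fd: float) -> float:
    """Freeze-drying survival as a percentage: 100 * after / before."""
    if (
        cfu_before_fd is None
        or cfu_after_fd is None
        or cfu_before_fd <= 0
        or cfu_after_fd <= 0
    ):
        raise ValueError("CFU counts must be positive")
    return 100.0 * cfu_after_fd / cfu_before_fd
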