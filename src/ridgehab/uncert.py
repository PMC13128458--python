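"""Minimal first-order (delta-method) uncertainty bookkeeping.

Standing-stock tables report every quantity as mean ± standard error.
All propagation in this package assumes independent errors and exact
(error-free) geometric factors, so the algebra reduces to linear scaling
and addition in quadrature; ratios use the first-order delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable


@dataclass(frozen=True)
class Measurement:
    """A value with its standard error.

    ``degenerate`` marks estimates whose SE could not be computed from the
    data (single-sample compartments); it is reported as 0 but flagged.
    """

    value: float
    se: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError(f"standard error must be >= 0, got {self.se}")

    def scaled(self, k: float) -> "Measurement":
        """Multiply by an exact constant; SE scales linearly (|k|)."""
        return Measurement(self.value * k, self.se * abs(k), self.degenerate)

    def __format__(self, spec: str) -> str:
        return f"{self.value:{spec}} ± {self.se:{spec}}"


def combine_sum(terms: Iterable[Measurement]) -> Measurement:
    """Sum of independent measurements: values add, SEs add in quadrature."""
    terms = list(terms)
    value = sum(t.value for t in terms)
    se = math.sqrt(sum(t.se**2 for t in terms))
    return Measurement(value, se, any(t.degenerate for t in terms))


def share_percent(x: Measurement, others: Iterable[Measurement]) -> Measurement:
    """Percent share 100*x/(x + sum(others)) with delta-method SE.

    All inputs are treated as independent.  For p = 100*x_i/S with
    S = sum_j x_j, the gradient is (S - x_i)/S^2 w.r.t. x_i and
    -x_i/S^2 w.r.t. every other term.
    """
    rest = list(others)
    total = x.value + sum(o.value for o in rest)
    if total <= 0:
        raise ValueError("percent share undefined for non-positive total")
    var = ((total - x.value) / total**2 * x.se) ** 2
    var += sum((x.value / total**2 * o.se) ** 2 for o in rest)
    return Measurement(
        100.0 * x.value / total,
        100.0 * math.sqrt(var),
        x.degenerate or any(o.degenerate for o in rest),
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))
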