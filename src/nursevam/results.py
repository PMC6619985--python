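"""Lightweight result containers shared across modules."""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class TestResult:
    """A single hypothesis-test outcome.

    kind is one of {"wald_joint", "auc_delta", "ks", "chi2", "t"}; df is None
    for tests without a meaningful degrees-of-freedom count (e.g. bootstrap).
    """

    statistic: float
    p_value: float
    kind: str
    df: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        d = {
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "kind": self.kind,
            "df": None if self.df is None else float(self.df),
        }
        d.update({k: v for k, v in self.extra.items()})
        return d
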