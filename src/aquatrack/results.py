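"""Shared result container for treatment comparisons."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ComparisonResult:
    """Outcome of one statistical contrast between treatments.

    ``df`` is the test's degrees of freedom — a float for t-type tests, a
    ``(df1, df2)`` tuple for ANOVA, an integer for chi-square based tests,
    and ``None`` for rank tests whose null distribution is indexed by the
    group sizes instead (reported in ``n_per_group``).
    """

    metric: str
    test: str
    statistic: float
    df: object
    p_value: float
    transform: str | None = None
    n_per_group: dict = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "test": self.test,
            "statistic": self.statistic,
            "df": str(self.df) if self.df is not None else "",
            "p_value": self.p_value,
            "transform": self.transform or "",
            "notes": self.notes,
        }
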