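"""Shared result containers for statistical tests."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic : float
        Test statistic (F, G, chi-square, Mantel r, ...).
    df : float | tuple | None
        Degrees of freedom; a pair for F-type statistics.
    p : float
        P-value in [0, 1].
    q : float | None
        FDR-adjusted q-value, when a table-wide correction was applied.
    mc_se : float | None
        Monte-Carlo standard error of ``p`` for simulation-based tests.
    testable : bool
        False when the input did not permit the test (the remaining fields
        are then placeholders and should not be interpreted).
    meta : dict
        Method-specific extras (settings actually used, component estimates).
    """

    statistic: float
    df: object = None
    p: float = float("nan")
    q: float | None = None
    mc_se: float | None = None
    testable: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.testable and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of range: {self.p}")
        if self.q is not None and not (0.0 <= self.q <= 1.0):
            raise ValueError(f"q-value out of range: {self.q}")
        if self.mc_se is not None and self.mc_se < 0:
            raise ValueError("mc_se must be non-negative")
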