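"""Germplasm screening against a benchmark variety.

Once the bran-layer cellulose content of a candidate variety is known
(measured or NIR-predicted), it is compared with a benchmark — typically
the wild type the mutants derive from.  A sample whose content deviates
from the benchmark by strictly more than a threshold (0.43 % cellulose by
default) is flagged ``low`` or ``high``; a deviation of exactly the
threshold still counts as ``normal``.

:func:`load_screening_example` ships a nine-variety example table
(reference and NIR-predicted contents of mutants of the wild type W7)
used by the test suite.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CelluloseLevel",
    "ScreeningRule",
    "classify",
    "screen_table",
    "load_screening_example",
]


class CelluloseLevel(str, enum.Enum):
    LOW = "low"
    NORMAL = "normal"
    HIGH = "high"


@dataclass(frozen=True)
class ScreeningRule:
    """Benchmark content (%) and the deviation threshold (%)."""

    benchmark_value: float
    threshold: float = 0.43

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.benchmark_value <= 0:
            raise ValueError("benchmark content must be positive")

    @classmethod
    def from_table(
        cls, contents: pd.Series, benchmark_id: str, threshold: float = 0.43
    ) -> "ScreeningRule":
        """Build a rule from a named sample inside the screened table."""
        if benchmark_id not in contents.index:
            raise KeyError(f"benchmark sample {benchmark_id!r} not in table")
        return cls(float(contents.loc[benchmark_id]), threshold)


def classify(content: float, rule: ScreeningRule) -> CelluloseLevel:
    """Label one sample low/normal/high relative to the benchmark.

    The deviation must strictly exceed the threshold to leave ``normal``.
    """
    if content <= 0:
        raise ValueError("content must be positive")
    delta = content - rule.benchmark_value
    if delta > rule.threshold:
        return CelluloseLevel.HIGH
    if -delta > rule.threshold:
        return CelluloseLevel.LOW
    return CelluloseLevel.NORMAL


def screen_table(contents: pd.Series, rule: ScreeningRule) -> pd.DataFrame:
    """Classify every sample of an id -> content table.

    Returns a frame with the content, the deviation from the benchmark
    (rounded to 2 decimals for reporting) and the level label.
    """
    if len(contents) == 0:
        raise ValueError("empty screening table")
    contents = contents.astype(float)
    delta = contents - rule.benchmark_value
    labels = [classify(c, rule).value for c in contents]
    return pd.DataFrame(
        {
            "content": contents,
            "delta": delta.round(2),
            "level": labels,
        }
    )


def load_screening_example() -> pd.DataFrame:
    """Example screening table: reference and NIR-predicted bran-layer
    cellulose contents (%) of eight mutant lines and their wild type W7,
    with the published level labels."""
    rows = [
        ("O1", 3.15, 3.42, "low"),
        ("O2", 3.10, 3.28, "low"),
        ("O5", 3.19, 3.30, "low"),
        ("O9", 3.35, 3.51, "low"),
        ("O17", 3.22, 3.48, "low"),
        ("O7", 4.20, 4.13, "normal"),
        ("O13", 4.26, 4.37, "normal"),
        ("W7", 4.26, 4.14, "normal"),
        ("O19", 4.74, 4.58, "high"),
    ]
    return pd.DataFrame(
        rows, columns=["sample", "reference", "predicted", "level"]
    ).set_index("sample")
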