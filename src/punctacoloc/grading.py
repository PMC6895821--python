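"""Semiquantitative labelling grades and their aggregation.

Labelling intensity is scored on the ordinal scale
-- (negative), -/+ (some positive trials, some negative), + (faint),
++ (moderate), +++ (intense) -- by independent observers over repeated
experiments; the reported grade is the mean of the numeric encodings,
mapped back to the nearest symbol.  The numeric embedding
{0, 0.5, 1, 2, 3} is the minimal order-preserving one that puts -/+ at
the midpoint of - and +; no numeric scale is canonical for these grades,
so the embedding is a package convention.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Grade", "GradingRecord", "encode_grade", "aggregate_grades", "GRADE_SCALE"]

# symbol <-> numeric bijection (NA carries null)
GRADE_SCALE: dict[str, float | None] = {
    "-": 0.0,
    "-/+": 0.5,
    "+": 1.0,
    "++": 2.0,
    "+++": 3.0,
    "NA": None,
}

# tables in the wild mix ASCII hyphen, Unicode minus and the two orderings
# of the mixed grade; normalize all of them
_ALIASES = {
    "−": "-",
    "−/+": "-/+",
    "+/-": "-/+",
    "+/−": "-/+",
    "na": "NA",
    "n/a": "NA",
}

_ASSAYS = {"cAMP_binding", "RI_IF", "RII_IF", "CAT_IF"}


@dataclass(frozen=True)
class Grade:
    symbol: str
    numeric: float | None
    zone_note: str = ""  # e.g. "Only in some zones" — annotation, never scored


@dataclass(frozen=True)
class GradingRecord:
    """Scores for one case x assay from independent observers/repetitions."""

    case_id: str
    assay: str
    observer_scores: tuple[Grade, ...]

    def __post_init__(self) -> None:
        if self.assay not in _ASSAYS:
            raise ValueError(f"assay must be one of {sorted(_ASSAYS)}")
        if not self.observer_scores:
            raise ValueError("GradingRecord requires at least one score")


def _normalize(symbol: str) -> str:
    s = symbol.strip().replace("−", "-")
    return _ALIASES.get(s, _ALIASES.get(symbol.strip(), s))


def encode_grade(symbol: str, zone_note: str = "") -> Grade:
    """Map a grade symbol to its fixed numeric value.

    Unicode minus and the "+/-" spelling of the mixed grade are accepted.
    """
    key = _normalize(symbol)
    if key not in GRADE_SCALE:
        raise ValueError(
            f"unknown grade symbol {symbol!r}; valid symbols: "
            f"{', '.join(GRADE_SCALE)}"
        )
    return Grade(symbol=key, numeric=GRADE_SCALE[key], zone_note=zone_note)


def _back_map(value: float) -> str:
    """Nearest defined symbol; ties round toward the lower grade."""
    best = None
    for sym, num in GRADE_SCALE.items():
        if num is None:
            continue
        d = abs(value - num)
        if best is None or d < best[0] - 1e-12 or (abs(d - best[0]) <= 1e-12 and num < best[1]):
            best = (d, num, sym)
    return best[2]


def aggregate_grades(record: GradingRecord) -> Grade:
    """Mean of the numeric scores ignoring NA, back-mapped to a symbol.

    All-NA records aggregate to NA.  The mean is permutation-invariant and
    bounded by the extreme input grades; back-mapping ties round down
    (conservative reporting of labelling intensity).
    """
    nums = [g.numeric for g in record.observer_scores if g.numeric is not None]
    if not nums:
        return Grade(symbol="NA", numeric=None)
    mean = sum(nums) / len(nums)
    return Grade(symbol=_back_map(mean), numeric=mean)
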