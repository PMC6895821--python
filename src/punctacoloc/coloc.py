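"""Object-based colocalization of two channels of detected puncta.

Two maxima sets from images of identical shape are superimposed and maxima
are classified as *coincidental* (centres within a match radius, paired
one-to-one) or single-channel.  The headline outputs are the bidirectional
percentages: of all channel-A maxima, what fraction has a coincidental
channel-B partner, and vice versa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .detection import MaximaPoint, MaximaSet

__all__ = ["CoincidenceParams", "ColocResult", "match_maxima", "coloc_report"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoincidenceParams:
    """Rule deciding when two maxima count as superimposed.

    match_radius
        Maximum centre-to-centre distance (pixels) of a coincidental pair.
        Default 2.0 px, i.e. a punctum and its partner must land within a
        couple of pixels after channel overlay.
    matching_policy
        "greedy_nearest" (default): candidate pairs within the radius are
        accepted in order of increasing distance, each point used at most
        once.  "exact_pixel": only identical pixel coordinates match —
        the strict reading of superimposed pixels.
    """

    match_radius: float = 2.0
    matching_policy: str = "greedy_nearest"

    def __post_init__(self) -> None:
        if self.match_radius < 0:
            raise ValueError("match_radius must be >= 0")
        if self.matching_policy not in ("greedy_nearest", "exact_pixel"):
            raise ValueError(
                "matching_policy must be 'greedy_nearest' or 'exact_pixel'"
            )


@dataclass(frozen=True)
class ColocResult:
    """Counts and bidirectional percentages for one superimposed image pair.

    ``pct_a_coincident`` is 100 * n_coincident / (n_coincident + n_a_only)
    and NaN when channel A detected no maxima at all (never silently 0 or
    100); likewise for B.
    """

    n_a_only: int
    n_b_only: int
    n_coincident: int
    pct_a_coincident: float
    pct_b_coincident: float
    pairs: tuple[tuple[MaximaPoint, MaximaPoint, float], ...]

    @property
    def n_a_total(self) -> int:
        return self.n_a_only + self.n_coincident

    @property
    def n_b_total(self) -> int:
        return self.n_b_only + self.n_coincident


def _pct(n_coinc: int, n_only: int, which: str) -> float:
    denom = n_coinc + n_only
    if denom == 0:
        log.warning(
            "no maxima in channel %s: coincident percentage is undefined (NA)", which
        )
        return math.nan
    return 100.0 * n_coinc / denom


def match_maxima(
    set_a: MaximaSet, set_b: MaximaSet, params: CoincidenceParams | None = None
) -> ColocResult:
    """Superimpose two maxima sets and pair coincidental maxima one-to-one.

    Under ``greedy_nearest``, all (A, B) pairs with distance <= match_radius
    are sorted by distance — ties broken by the (row, col) of the A point,
    then of the B point, so output is deterministic — and accepted greedily,
    each maximum matched at most once.  Unmatched maxima are counted as
    single-channel.
    """
    if params is None:
        params = CoincidenceParams()
    if set_a.image_shape != set_b.image_shape:
        raise ValueError(
            f"maxima sets derive from images of different shapes: "
            f"{set_a.image_shape} vs {set_b.image_shape}"
        )

    pairs: list[tuple[MaximaPoint, MaximaPoint, float]] = []
    if len(set_a) and len(set_b):
        d = cdist(set_a.coords(), set_b.coords())
        radius = 0.0 if params.matching_policy == "exact_pixel" else params.match_radius
        ii, jj = np.nonzero(d <= radius)
        order = sorted(
            range(len(ii)),
            key=lambda k: (
                d[ii[k], jj[k]],
                set_a.points[ii[k]].row,
                set_a.points[ii[k]].col,
                set_b.points[jj[k]].row,
                set_b.points[jj[k]].col,
            ),
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        for k in order:
            i, j = int(ii[k]), int(jj[k])
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            pairs.append((set_a.points[i], set_b.points[j], float(d[i, j])))

    n_coinc = len(pairs)
    n_a_only = len(set_a) - n_coinc
    n_b_only = len(set_b) - n_coinc
    return ColocResult(
        n_a_only=n_a_only,
        n_b_only=n_b_only,
        n_coincident=n_coinc,
        pct_a_coincident=_pct(n_coinc, n_a_only, "A"),
        pct_b_coincident=_pct(n_coinc, n_b_only, "B"),
        pairs=tuple(pairs),
    )


def coloc_report(
    results: list[ColocResult], labels: list[str] | None = None
) -> pd.DataFrame:
    """Tabulate per-image counts/percentages plus a pooled summary row.

    The pooled percentages are computed from pooled counts, not by averaging
    the per-image percentages; empty denominators are reported as NA.
    """
    if not results:
        raise ValueError("coloc_report requires at least one ColocResult")
    if labels is None:
        labels = [f"image_{i + 1}" for i in range(len(results))]
    if len(labels) != len(results):
        raise ValueError("labels and results must have equal length")

    rows = []
    for lab, r in zip(labels, results):
        rows.append(
            {
                "label": lab,
                "n_coincident": r.n_coincident,
                "n_a_only": r.n_a_only,
                "n_b_only": r.n_b_only,
                "pct_a_coincident": r.pct_a_coincident,
                "pct_b_coincident": r.pct_b_coincident,
            }
        )
    pooled_c = sum(r.n_coincident for r in results)
    pooled_a = sum(r.n_a_only for r in results)
    pooled_b = sum(r.n_b_only for r in results)
    rows.append(
        {
            "label": "pooled",
            "n_coincident": pooled_c,
            "n_a_only": pooled_a,
            "n_b_only": pooled_b,
            "pct_a_coincident": _pct(pooled_c, pooled_a, "A (pooled)"),
            "pct_b_coincident": _pct(pooled_c, pooled_b, "B (pooled)"),
        }
    )
    return pd.DataFrame(rows)
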