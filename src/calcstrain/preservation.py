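"""Preservation screening via cumulative percent decay curves.

Archaeological dental calculus is screened for endogenous oral content by
ranking each sample's taxa by decreasing abundance and asking, at every rank
k, what percentage of the top-k taxa belong to a reference list of oral
taxa.  Well-preserved samples start high and stay high; contaminated or
degraded samples are dominated by environmental taxa and the curve sits low.
A sample passes when the curve stays at or above a cutoff (default 50%) at
every rank from a burn-in rank onward.

The adaptive burn-in skips the unstable head of the curve, where each
additional taxon swings the percentage by tens of points: the burn-in rank
is the first rank after the last rank-to-rank change larger than a
stability tolerance (default 5 percentage points).  This is a documented,
deterministic stand-in for the adaptive mode of the cuperdec R package,
whose exact criterion is not published; a fixed-rank burn-in is also
available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import TaxonTable

__all__ = ["DecayCurve", "decay_curve", "classify_preservation", "screen_samples", "TaxonTable"]

#: largest rank-to-rank change (percentage points) still considered stable
ADAPTIVE_STABILITY_TOL = 5.0


@dataclass
class DecayCurve:
    """Cumulative percentage of oral taxa among the top-k ranked taxa."""

    sample_id: str
    values: np.ndarray  # percentage at rank k, index 0 == rank 1
    taxa: list[str]  # taxa in rank order (nonzero only)

    def __len__(self) -> int:
        return len(self.values)


def decay_curve(sample_row: pd.Series, oral_reference: set[str]) -> DecayCurve:
    """Cumulative percent decay curve for one sample.

    Taxa with zero abundance are dropped; the remainder are ranked by
    decreasing abundance with ties broken lexicographically by taxon id so
    the curve is deterministic.  ``values[k-1] = 100 * |oral among top-k| / k``.
    """
    if (sample_row < 0).any():
        raise ValueError("negative abundances")
    nonzero = sample_row[sample_row > 0]
    if nonzero.empty:
        raise ValueError(f"sample {sample_row.name!r} has no nonzero taxa")
    ranked = nonzero.sort_index().sort_values(ascending=False, kind="stable")
    is_oral = np.asarray([t in oral_reference for t in ranked.index])
    k = np.arange(1, len(ranked) + 1)
    values = 100.0 * np.cumsum(is_oral) / k
    return DecayCurve(str(sample_row.name), values, list(ranked.index))


def _adaptive_burn_in(values: np.ndarray, tol: float = ADAPTIVE_STABILITY_TOL) -> int:
    """First rank (1-based) after the last rank-to-rank jump larger than ``tol``."""
    if len(values) < 2:
        return 1
    jumps = np.flatnonzero(np.abs(np.diff(values)) > tol)
    if jumps.size == 0:
        return 1
    # diff index j is the change from rank j+1 to rank j+2
    return int(jumps[-1]) + 2


def classify_preservation(
    curve: DecayCurve,
    cutoff_percent: float = 50.0,
    burn_in: str | int = "adaptive",
) -> tuple[bool, int]:
    """Pass/fail a sample's decay curve.

    Passes iff the curve is >= ``cutoff_percent`` at every rank from the
    burn-in rank onward.  ``burn_in`` is ``"adaptive"`` (default) or a fixed
    1-based rank.  Returns ``(passed, burn_in_rank)``.
    """
    if not 0.0 <= cutoff_percent <= 100.0:
        raise ValueError("cutoff must be in [0, 100]")
    if burn_in == "adaptive":
        rank = _adaptive_burn_in(curve.values)
    else:
        rank = int(burn_in)
        if rank < 1:
            raise ValueError("fixed burn-in rank must be >= 1")
    rank = min(rank, len(curve))
    passed = bool((curve.values[rank - 1:] >= cutoff_percent).all())
    return passed, rank


def screen_samples(
    table: TaxonTable,
    cutoff_percent: float = 50.0,
    burn_in: str | int = "adaptive",
) -> pd.DataFrame:
    """Classify every sample in a taxon table.

    Returns a DataFrame indexed by sample with columns ``passed`` and
    ``burn_in_rank``.
    """
    rows = {}
    for sample_id, row in table.abundances.iterrows():
        curve = decay_curve(row, table.oral_reference)
        passed, rank = classify_preservation(curve, cutoff_percent, burn_in)
        rows[sample_id] = {"passed": passed, "burn_in_rank": rank}
    return pd.DataFrame.from_dict(rows, orient="index")
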