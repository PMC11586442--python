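"""FAVA: an FST-based measure of variability across relative-abundance vectors.

Treating each sample's taxonomic profile as an allele-frequency vector, FAVA
applies Wright's FST to microbiome compositions: with Gini–Simpson
heterozygosity H(p) = 1 − Σ p_j², the statistic is

    FAVA = (H_T − H̄_S) / H_T

where H_T is the heterozygosity of the across-sample mean vector and H̄_S is
the mean within-sample heterozygosity.  FAVA is 0 exactly when all samples
share one composition and 1 exactly when every sample is concentrated on a
single (not necessarily distinct) taxon while the mean remains spread out.

This is the unweighted form: uniform sample weights and uniform taxon
treatment.  The statistic is undefined (not an error) for groups of fewer
than two samples and when H_T = 0; the result carries a reason code so a
single-sample group propagates as NA rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FavaResult", "fava", "fava_by_group"]


@dataclass
class FavaResult:
    """FAVA for one group of samples; ``value`` is None when undefined."""

    group: str
    n_samples: int
    h_t: float | None
    h_s_bar: float | None
    value: float | None
    reason: str | None = None  # set when value is None

    @property
    def defined(self) -> bool:
        return self.value is not None


def _normalize(matrix: np.ndarray) -> np.ndarray:
    if (matrix < 0).any():
        raise ValueError("negative abundances")
    sums = matrix.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise ValueError("zero-sum abundance row")
    return matrix / sums


def fava(abundance_matrix, group: str = "all") -> FavaResult:
    """FAVA over the rows of a samples × taxa abundance matrix.

    Rows are closed to relative abundances internally, so raw counts are
    accepted.  A single row yields an undefined result with reason ``"n<2"``;
    H_T = 0 (all mass on one shared taxon) yields reason ``"H_T=0"``.
    """
    m = np.asarray(abundance_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D samples x taxa matrix")
    n = m.shape[0]
    if n < 2:
        return FavaResult(group, n, None, None, None, reason="n<2")
    p = _normalize(m)
    h_s = 1.0 - (p ** 2).sum(axis=1)
    p_bar = p.mean(axis=0)
    h_t = 1.0 - (p_bar ** 2).sum()
    if h_t <= 0.0:
        return FavaResult(group, n, float(h_t), float(h_s.mean()), None, reason="H_T=0")
    value = (h_t - h_s.mean()) / h_t
    return FavaResult(group, n, float(h_t), float(h_s.mean()), float(value))


def fava_by_group(table: pd.DataFrame, grouping: pd.Series) -> tuple[list[FavaResult], FavaResult]:
    """Per-group FAVA plus the pooled all-samples statistic.

    ``grouping`` maps every sample (row of ``table``) to exactly one group
    label.  Singleton groups come back undefined while the others and the
    pooled value are computed normally.
    """
    missing = table.index.difference(grouping.index)
    if len(missing):
        raise ValueError(f"samples without a group: {list(missing)[:5]}")
    aligned = grouping.reindex(table.index)
    results = []
    for group in aligned.unique():
        sub = table.loc[aligned == group]
        if sub.shape[0] == 0:
            raise ValueError(f"empty group {group!r}")
        results.append(fava(sub.to_numpy(), group=str(group)))
    pooled = fava(table.to_numpy(), group="pooled")
    return results, pooled


def results_frame(results: list[FavaResult], pooled: FavaResult | None = None) -> pd.DataFrame:
    """Tabulate FAVA results (value NA when undefined) for TSV output."""
    rows = list(results) + ([pooled] if pooled is not None else [])
    return pd.DataFrame(
        {
            "group": [r.group for r in rows],
            "n_samples": [r.n_samples for r in rows],
            "fava": [r.value if r.defined else np.nan for r in rows],
            "reason": [r.reason or "" for r in rows],
        }
    )
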