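"""Homozygous-SNP alignments, TN93 distances, NJ trees, and tree concordance.

Multi-sample strain phylogenies from metagenomic pileups follow a
conservative recipe: call the majority allele at every position covered at
least ``min_cov`` deep, keep only effectively homozygous calls (major
allele frequency strictly greater than 0.9 — heterozygous-looking sites in
a metagenome usually mean strain mixtures or damage, not diploidy), and
assemble a samples × variant-positions matrix whose columns are the
positions where at least one sample carries a homozygous non-reference
allele.  A sample's state at a column is its homozygous allele when it has
a confident call there and ``N`` otherwise, so low-coverage samples abstain
rather than vote.

Distances are Tamura–Nei 1993 (distinct purine/pyrimidine transition rates,
empirical base frequencies) computed pairwise over columns where both
samples have a real base, with an optional gamma rate-heterogeneity
correction.  Trees are neighbour-joining (via scikit-bio) with midpoint
rooting, column-bootstrap support, and congruence among distance matrices
tested with Kendall's coefficient of concordance W under a permutation
test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from . import _seq
from .strain import Pileup

__all__ = [
    "SnpAlignment",
    "ConcordanceResult",
    "call_variants",
    "heterozygous_fraction",
    "filter_homozygous",
    "sample_qc",
    "build_snp_alignment",
    "tn93_distance",
    "nj_tree",
    "midpoint_root",
    "bootstrap_support",
    "concordance",
]


def call_variants(pileup: Pileup, reference_codes: np.ndarray, min_cov: int = 5) -> pd.DataFrame:
    """Majority-allele calls at every position covered >= ``min_cov``.

    Returns a DataFrame with columns ``position``, ``ref``, ``major``,
    ``major_freq`` and ``depth``; ties for the major allele break toward
    the alphabetically first base.
    """
    if len(pileup) != len(reference_codes):
        raise ValueError("pileup and reference lengths differ")
    depth = pileup.depth
    covered = np.flatnonzero(depth >= min_cov)
    counts = pileup.counts[covered]
    major = counts.argmax(axis=1)
    freq = counts[np.arange(len(covered)), major] / depth[covered]
    return pd.DataFrame({
        "position": covered,
        "ref": _seq.BASE_CHARS[reference_codes[covered]],
        "major": _seq.BASE_CHARS[major],
        "major_freq": freq,
        "depth": depth[covered],
    })


def heterozygous_fraction(calls: pd.DataFrame, threshold: float = 0.9) -> float:
    """Share of calls whose major allele frequency is <= ``threshold``."""
    if calls.empty:
        return 0.0
    return float((calls["major_freq"] <= threshold).mean())


def filter_homozygous(calls: pd.DataFrame, threshold: float = 0.9) -> pd.DataFrame:
    """Keep calls with major allele frequency strictly greater than ``threshold``."""
    return calls[calls["major_freq"] > threshold].reset_index(drop=True)


def sample_qc(
    stats: pd.DataFrame,
    min_snps: int = 1000,
    min_mean_cov: float = 5.0,
) -> pd.DataFrame:
    """Inclusion decisions per sample with the failing criterion named.

    ``stats`` is indexed by sample with columns ``n_snps`` (homozygous
    non-reference SNPs) and ``mean_coverage``.  Both thresholds are
    inclusive ("at least").
    """
    reasons = []
    for _, row in stats.iterrows():
        why = []
        if row["n_snps"] < min_snps:
            why.append(f"n_snps {int(row['n_snps'])} < {min_snps}")
        if row["mean_coverage"] < min_mean_cov:
            why.append(f"mean_coverage {row['mean_coverage']:.2f} < {min_mean_cov}")
        reasons.append("; ".join(why))
    return pd.DataFrame({
        "included": [r == "" for r in reasons],
        "reason": reasons,
    }, index=stats.index)


@dataclass
class SnpAlignment:
    """Samples × variant-positions character matrix over A,C,G,T,N."""

    sample_ids: list[str]
    positions: np.ndarray
    matrix: np.ndarray  # (n_samples, n_positions) of single characters

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.sample_ids), len(self.positions)):
            raise ValueError("matrix shape does not match samples x positions")

    @property
    def n_columns(self) -> int:
        return len(self.positions)

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for i, sid in enumerate(self.sample_ids):
                fh.write(f">{sid}\n{''.join(self.matrix[i])}\n")


def build_snp_alignment(
    calls_by_sample: dict[str, pd.DataFrame],
    reference_codes: np.ndarray,
) -> SnpAlignment:
    """Assemble the homozygous-SNP matrix across samples.

    ``calls_by_sample`` maps sample id to its homozygous-filtered calls.
    Columns are the union of positions where at least one sample's call
    differs from the reference.  A sample's state at a column is its
    homozygous allele when it has a call there (which covers confident
    reference as well) and ``N`` otherwise.
    """
    variant_positions: set[int] = set()
    for calls in calls_by_sample.values():
        alt = calls[calls["major"] != calls["ref"]]
        variant_positions.update(int(p) for p in alt["position"])
    positions = np.array(sorted(variant_positions), dtype=int)
    samples = list(calls_by_sample)
    matrix = np.full((len(samples), len(positions)), "N", dtype="U1")
    pos_index = {p: i for i, p in enumerate(positions)}
    for si, sid in enumerate(samples):
        calls = calls_by_sample[sid]
        hit = calls[calls["position"].isin(set(pos_index))]
        for p, b in zip(hit["position"], hit["major"]):
            matrix[si, pos_index[int(p)]] = b
    return SnpAlignment(samples, positions, matrix)


# ---------------------------------------------------------------------------
# TN93 distances
# ---------------------------------------------------------------------------

def _tn93_pair(x: np.ndarray, y: np.ndarray, gamma_alpha: float | None):
    """TN93 distance between two encoded sequences (255 = missing)."""
    valid = (x < 4) & (y < 4)
    n = int(valid.sum())
    if n < 2:
        return np.nan, "fewer than 2 shared non-N columns"
    xv, yv = x[valid].astype(int), y[valid].astype(int)
    freqs = np.bincount(np.concatenate([xv, yv]), minlength=4) / (2 * n)
    pi_a, pi_c, pi_g, pi_t = freqs
    pi_r, pi_y = pi_a + pi_g, pi_c + pi_t
    diff = xv != yv
    pair = np.sort(np.stack([xv, yv]), axis=0)
    p1 = float(np.mean(diff & (pair[0] == _seq.A) & (pair[1] == _seq.G)))  # purine ts
    p2 = float(np.mean(diff & (pair[0] == _seq.C) & (pair[1] == _seq.T)))  # pyrimidine ts
    q = float(np.mean(diff)) - p1 - p2  # transversions

    def xlog(k: float, w: float) -> float:
        # contribution k * f(w), where f = -ln for the ML distance and the
        # gamma-corrected transform alpha*(w**(-1/alpha)-1) otherwise
        if k == 0.0:
            return 0.0
        if w <= 0.0:
            raise FloatingPointError("saturated")
        if gamma_alpha is None:
            return -k * np.log(w)
        return k * gamma_alpha * (w ** (-1.0 / gamma_alpha) - 1.0)

    try:
        k1 = 2.0 * pi_a * pi_g / pi_r if pi_r else 0.0
        k2 = 2.0 * pi_c * pi_t / pi_y if pi_y else 0.0
        k3 = 2.0 * (pi_r * pi_y
                    - (pi_a * pi_g * pi_y / pi_r if pi_r else 0.0)
                    - (pi_c * pi_t * pi_r / pi_y if pi_y else 0.0))
        d = 0.0
        if k1:
            d += xlog(k1, 1.0 - p1 / k1 - q / (2.0 * pi_r))
        if k2:
            d += xlog(k2, 1.0 - p2 / k2 - q / (2.0 * pi_y))
        if k3:
            d += xlog(k3, 1.0 - q / (2.0 * pi_r * pi_y))
    except FloatingPointError:
        return np.nan, "saturated (log of non-positive argument)"
    return d, None


def tn93_distance(
    alignment: SnpAlignment,
    gamma_alpha: float | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], str]]:
    """Pairwise TN93 distance matrix from a SNP alignment.

    Pairs use only columns where both samples have a real base.  Undefined
    pairs (saturation, or fewer than two shared columns) come back as NaN
    with a reason keyed by the sample pair; trees refuse NaN inputs.
    ``gamma_alpha`` applies gamma rate-heterogeneity correction with the
    given shape.  Returned as a symmetric DataFrame indexed by sample id.
    """
    n = len(alignment.sample_ids)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    enc = np.full(alignment.matrix.shape, 255, dtype=np.uint8)
    for code, base in enumerate("ACGT"):
        enc[alignment.matrix == base] = code
    dm = np.zeros((n, n))
    reasons: dict[tuple[str, str], str] = {}
    for i, j in itertools.combinations(range(n), 2):
        d, why = _tn93_pair(enc[i], enc[j], gamma_alpha)
        dm[i, j] = dm[j, i] = d
        if why:
            reasons[(alignment.sample_ids[i], alignment.sample_ids[j])] = why
    return pd.DataFrame(dm, index=alignment.sample_ids, columns=alignment.sample_ids), reasons


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def nj_tree(distances: pd.DataFrame | DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbour joining; negative branch lengths clamp to zero."""
    if isinstance(distances, pd.DataFrame):
        if distances.isna().to_numpy().any():
            raise ValueError("distance matrix contains undefined entries")
        distances = DistanceMatrix(distances.to_numpy(), ids=list(distances.index))
    elif np.isnan(distances.data).any():
        raise ValueError("distance matrix contains undefined entries")
    return nj(distances)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest tip-to-tip path."""
    tips = list(tree.tips())
    if len(tips) == 2:
        # two-tip trees: place the root equidistant from both tips
        total = tips[0].distance(tips[1])
        a = TreeNode(name=tips[0].name, length=total / 2.0)
        b = TreeNode(name=tips[1].name, length=total / 2.0)
        return TreeNode(children=[a, b])
    return tree.root_at_midpoint()


def _bipartitions(tree: TreeNode, all_tips: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions, canonicalized to exclude a fixed reference tip."""
    ref = min(all_tips)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            parts.add(side)
    return parts


def bootstrap_support(
    alignment: SnpAlignment,
    replicates: int = 200,
    seed: int | None = None,
    gamma_alpha: float | None = None,
) -> tuple[TreeNode, int]:
    """Column-bootstrap support on the full-data NJ tree.

    Columns are resampled with replacement ``replicates`` times; each
    replicate is rebuilt with TN93 + NJ and its bipartitions recorded.
    Internal nodes of the full-data tree get ``support`` attributes (and
    names) in percent.  Replicates whose distances come out undefined are
    skipped; the number of effective replicates is returned alongside.
    """
    if seed is None:
        raise ValueError("bootstrap_support requires a seed")
    if alignment.n_columns == 0:
        raise ValueError("empty alignment")
    rng = np.random.default_rng(seed)
    dm, reasons = tn93_distance(alignment, gamma_alpha)
    if reasons:
        raise ValueError(f"undefined distances in full data: {reasons}")
    full_tree = nj_tree(dm)
    tips = frozenset(alignment.sample_ids)
    counts: dict[frozenset[str], int] = {}
    effective = 0
    for _ in range(replicates):
        cols = rng.integers(0, alignment.n_columns, size=alignment.n_columns)
        rep = SnpAlignment(alignment.sample_ids, alignment.positions[cols],
                           alignment.matrix[:, cols])
        rep_dm, rep_reasons = tn93_distance(rep, gamma_alpha)
        if rep_reasons:
            continue
        effective += 1
        for part in _bipartitions(nj_tree(rep_dm), tips):
            counts[part] = counts.get(part, 0) + 1
    for node in full_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = side if min(tips) not in side else tips - side
        if 2 <= len(canon) <= len(tips) - 2 and effective:
            node.support = 100.0 * counts.get(canon, 0) / effective
            node.name = f"{node.support:g}"
    return full_tree, effective


# ---------------------------------------------------------------------------
# Concordance (CADM / Kendall's W)
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    """Kendall's W over distance matrices and its permutation p-value."""

    w: float
    p_value: float
    n_matrices: int
    permutations: int


def _as_matrix(obj, ids: list[str]) -> np.ndarray:
    if isinstance(obj, TreeNode):
        dm = obj.tip_tip_distances()
        return dm.filter(ids).data
    if isinstance(obj, DistanceMatrix):
        return obj.filter(ids).data
    if isinstance(obj, pd.DataFrame):
        return obj.loc[ids, ids].to_numpy()
    return np.asarray(obj, dtype=float)


def _kendall_w(rank_rows: np.ndarray, ties: np.ndarray) -> float:
    m, n = rank_rows.shape
    totals = rank_rows.sum(axis=0)
    s = float(((totals - m * (n + 1) / 2.0) ** 2).sum())
    denom = m * m * (n ** 3 - n) - m * float(ties.sum())
    if denom <= 0:
        return np.nan
    return 12.0 * s / denom


def _tie_correction(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float((counts ** 3 - counts).sum())


def concordance(
    inputs,
    permutations: int = 99,
    seed: int | None = None,
) -> ConcordanceResult:
    """Congruence among distance matrices: Kendall's W + permutation test.

    ``inputs`` are two or more trees (converted to cophenetic, i.e.
    tip-to-tip path, distances) and/or distance matrices over the same tip
    set.  W is computed over the ranked unfolded upper triangles with tie
    correction; the permutation null permutes the tip labels of every
    matrix but the first, and ``p = (1 + #{W_perm >= W}) / (permutations+1)``,
    so the smallest attainable p is ``1/(permutations+1)``.
    """
    if len(inputs) < 2:
        raise ValueError("need at least 2 matrices or trees")
    if seed is None:
        raise ValueError("concordance requires a seed")
    first = inputs[0]
    if isinstance(first, TreeNode):
        ids = sorted(t.name for t in first.tips())
    elif isinstance(first, DistanceMatrix):
        ids = sorted(first.ids)
    elif isinstance(first, pd.DataFrame):
        ids = sorted(first.index)
    else:
        ids = list(range(np.asarray(first).shape[0]))  # type: ignore[arg-type]
    mats = [_as_matrix(obj, ids) for obj in inputs]
    n_tips = mats[0].shape[0]
    for m in mats:
        if m.shape != (n_tips, n_tips):
            raise ValueError("matrices have mismatched tip sets")
    iu = np.triu_indices(n_tips, k=1)

    def ranks_for(perm_each: list[np.ndarray] | None) -> tuple[np.ndarray, np.ndarray]:
        rows, ties = [], []
        for k, m in enumerate(mats):
            mm = m if perm_each is None or k == 0 else m[np.ix_(perm_each[k], perm_each[k])]
            r = rankdata(mm[iu])
            rows.append(r)
            ties.append(_tie_correction(r))
        return np.asarray(rows), np.asarray(ties)

    obs_rows, obs_ties = ranks_for(None)
    w_obs = _kendall_w(obs_rows, obs_ties)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perms = [np.arange(n_tips)] + [rng.permutation(n_tips) for _ in mats[1:]]
        rows, ties = ranks_for(perms)
        if _kendall_w(rows, ties) >= w_obs:
            hits += 1
    p = (1 + hits) / (permutations + 1)
    return ConcordanceResult(w_obs, p, len(mats), permutations)
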