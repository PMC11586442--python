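"""Polymorphic-rate dN/dS over coding genes, and the wrong-reference experiment.

A metagenomic sample containing a single strain of a species should show
almost no within-sample polymorphism: at every well-covered coding position
one allele dominates.  When two or more strains co-occur — or when reads
from one species are mapped to a related but incorrect reference genome —
many sites carry two alleles, and the ratio of nonsynonymous to synonymous
polymorphic sites (an ad-hoc "dN/dS" over polymorphic-site *counts*, not
rate-normalized by site opportunity) rises toward the value expected for
effectively random substitutions.

Site classification follows the polymut-style rules: a site needs coverage
>= ``min_cov`` to be evaluated, is polymorphic when its dominant allele
frequency is below ``dominant_freq`` (default 0.8), and its effect is found
by substituting the secondary allele into the codon formed from the
dominant alleles at the other two codon positions, translating with the
standard genetic code.  Base-quality filtering happens upstream, when the
pileup is built.

``cross_reference_experiment`` reproduces, at desk scale, the calibration
experiment that measures the dN/dS expected when a sample is mapped against
the wrong (closely related) reference.  In real genomes that signal comes
from reads of near-identical paralogous loci cross-mapping onto a single
reference locus and mixing their alleles.  The synthetic genomes therefore
carry a duplicated segment (two paralogs at a small internal divergence);
"mapping" places each read at its best-matching homologous candidate locus
(fewest mismatches, ties broken at random, reads above a mismatch cap
discarded) — a minimal stand-in for a short-read aligner that preserves
exactly the mechanism under study.  On the *correct* reference every read
matches its own locus perfectly and no mixing occurs; on an incorrect
reference the paralog copies are roughly equidistant, reads cross-map, and
polymorphic sites appear at paralog-divergent positions, independent of the
deamination level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import _seq
from .strain import Pileup, build_pileup
from .synthdata import (
    DAMAGE_NON_UDG,
    DAMAGE_NONE,
    DamageProfile,
    Genome,
    ReadAlignment,
    SimulationConfig,
    annotate_orfs,
    mutate_genome,
    simulate_reads,
)

__all__ = [
    "DnDsResult",
    "classify_sites",
    "dnds",
    "GenomeFamily",
    "paralog_genome_family",
    "map_reads_to_reference",
    "cross_reference_experiment",
    "CODON_AA",
]

#: low/high deamination intensities for the wrong-reference experiment
DAMAGE_LEVELS = {
    "none": DAMAGE_NONE,
    "low": DamageProfile(d0=0.10, decay=0.70, extent=15, udg_class="non_udg"),
    "high": DAMAGE_NON_UDG,
}


def _codon_aa_table() -> np.ndarray:
    """Amino acid (or ``*``) for each of the 64 codons, indexed c0*16+c1*4+c2."""
    table = CodonTable.unambiguous_dna_by_id[1]  # the standard code
    aa = np.empty(64, dtype="U1")
    bases = "ACGT"
    for i0, b0 in enumerate(bases):
        for i1, b1 in enumerate(bases):
            for i2, b2 in enumerate(bases):
                codon = b0 + b1 + b2
                idx = i0 * 16 + i1 * 4 + i2
                aa[idx] = "*" if codon in table.stop_codons else table.forward_table[codon]
    return aa


CODON_AA = _codon_aa_table()
_CODON_WEIGHTS = np.array([16, 4, 1])


@dataclass
class DnDsResult:
    """Counts of polymorphic coding sites by effect, and their ratio."""

    n_nonsynonymous: int
    n_synonymous: int
    n_considered: int
    ratio: float | None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def classify_sites(
    pileup: Pileup,
    genes: list[tuple[int, int, str]],
    min_cov: int = 5,
    dominant_freq: float = 0.8,
) -> pd.DataFrame:
    """Classify every in-gene position of a pileup.

    Returns a DataFrame with one row per coding position and columns
    ``position`` (genomic, 0-based), ``gene``, ``codon_index``,
    ``codon_pos`` (1-3), ``depth``, ``dominant``, ``dominant_freq``,
    ``secondary``, ``state`` (monomorphic/polymorphic/unevaluated) and
    ``effect`` (synonymous/nonsynonymous/not-applicable).  For
    reverse-strand genes, alleles are reported in coding orientation.  A
    polymorphic site in a codon whose other positions are not all covered
    gets effect ``not-applicable`` (the background codon cannot be formed).
    """
    frames = []
    for gene_idx, (start, end, strand) in enumerate(genes):
        if (end - start) % 3:
            raise ValueError(f"gene ({start},{end}) not in frame")
        counts = pileup.counts[start:end]
        if strand == "-":
            # complement counts into coding orientation
            counts = counts[::-1][:, _seq.COMPLEMENT]
        n = end - start
        depth = counts.sum(axis=1)
        covered = depth >= min_cov
        dom = counts.argmax(axis=1)
        rest = counts.copy()
        rest[np.arange(n), dom] = -1
        sec = rest.argmax(axis=1)
        sec_count = rest[np.arange(n), sec]
        with np.errstate(invalid="ignore", divide="ignore"):
            dom_freq = np.where(depth > 0, counts[np.arange(n), dom] / depth, 0.0)
        poly = covered & (dom_freq < dominant_freq)

        codon_of = np.arange(n) // 3
        codon_full = covered.reshape(-1, 3).all(axis=1)
        dom_codon_idx = (dom.reshape(-1, 3) * _CODON_WEIGHTS).sum(axis=1)

        state = np.where(~covered, "unevaluated",
                         np.where(poly, "polymorphic", "monomorphic"))
        effect = np.full(n, "not-applicable", dtype="U14")
        evaluable = poly & codon_full[codon_of]
        if evaluable.any():
            pos_in_codon = np.arange(n) % 3
            w = _CODON_WEIGHTS[pos_in_codon[evaluable]]
            base_idx = dom_codon_idx[codon_of[evaluable]]
            alt_idx = base_idx - dom[evaluable] * w + sec[evaluable] * w
            same = CODON_AA[base_idx] == CODON_AA[alt_idx]
            effect[evaluable] = np.where(same, "synonymous", "nonsynonymous")

        genome_pos = np.arange(start, end) if strand == "+" else np.arange(end - 1, start - 1, -1)
        frames.append(pd.DataFrame({
            "position": genome_pos,
            "gene": gene_idx,
            "codon_index": codon_of,
            "codon_pos": np.arange(n) % 3 + 1,
            "depth": depth,
            "dominant": _seq.BASE_CHARS[dom],
            "dominant_freq": dom_freq,
            "secondary": np.where(sec_count > 0, _seq.BASE_CHARS[sec], ""),
            "state": state,
            "effect": effect,
        }))
    if not frames:
        return pd.DataFrame(columns=["position", "gene", "codon_index", "codon_pos",
                                     "depth", "dominant", "dominant_freq", "secondary",
                                     "state", "effect"])
    return pd.concat(frames, ignore_index=True)


def dnds(
    pileup: Pileup,
    genes: list[tuple[int, int, str]],
    min_cov: int = 5,
    dominant_freq: float = 0.8,
) -> DnDsResult:
    """Aggregate site classifications into polymorphic-site dN/dS counts."""
    sites = classify_sites(pileup, genes, min_cov=min_cov, dominant_freq=dominant_freq)
    if sites.empty:
        return DnDsResult(0, 0, 0, None, reason="no coding sites")
    n_considered = int((sites["state"] != "unevaluated").sum())
    poly = sites[sites["state"] == "polymorphic"]
    n_nonsyn = int((poly["effect"] == "nonsynonymous").sum())
    n_syn = int((poly["effect"] == "synonymous").sum())
    if n_syn == 0:
        return DnDsResult(n_nonsyn, 0, n_considered, None,
                          reason="no synonymous polymorphic sites")
    return DnDsResult(n_nonsyn, n_syn, n_considered, n_nonsyn / n_syn)


# ---------------------------------------------------------------------------
# Wrong-reference experiment
# ---------------------------------------------------------------------------

@dataclass
class GenomeFamily:
    """Coordinate-compatible genomes sharing gene models and a paralog pair.

    All genomes descend from one annotated ancestor by substitutions only,
    so coordinates (and the two paralogous segments ``repeat_a`` /
    ``repeat_b``, each a half-open interval) are shared across the family.
    """

    genomes: list[Genome]
    repeat_a: tuple[int, int]
    repeat_b: tuple[int, int]


def paralog_genome_family(
    n_genomes: int = 2,
    length: int = 30000,
    repeat_length: int = 4500,
    paralog_divergence: float = 0.02,
    genome_divergence: float = 0.05,
    gc: float = 0.5,
    gene_length: int = 300,
    spacing: int = 60,
    seed: int | None = None,
) -> GenomeFamily:
    """Build an annotated genome family with an internal paralog pair.

    The ancestor carries two copies of a ``repeat_length`` segment at
    ``paralog_divergence`` from each other — the near-identical duplicated
    loci that let short reads cross-map.  Each family member then diverges
    from the ancestor at ``genome_divergence / 2``, so members sit at about
    ``genome_divergence`` from one another.  Gene tiling spans the whole
    genome; the copied segment may contain in-frame stops, which is harmless
    for site classification (a stop translates as ``*``).
    """
    if n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    if seed is None:
        raise ValueError("paralog_genome_family requires a seed")
    if 2 * repeat_length > length:
        raise ValueError("repeat pair does not fit in the genome")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    # paralog copy B = copy A at a small divergence, placed at the far end
    a_start, b_start = 0, length - repeat_length
    seg = codes[a_start:a_start + repeat_length].copy()
    hits = np.flatnonzero(rng.random(repeat_length) < paralog_divergence)
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size).astype(np.uint8)
        seg[hits] = (seg[hits] + shift) % 4
    codes[b_start:b_start + repeat_length] = seg
    ancestor = annotate_orfs(Genome("ancestor", _seq.decode(codes)), gene_length, spacing)
    genomes = []
    for i in range(n_genomes):
        g, _ = mutate_genome(ancestor, genome_divergence / 2.0,
                             int(rng.integers(2 ** 31)), f"fam_{i}")
        genomes.append(g)
    return GenomeFamily(genomes, (a_start, a_start + repeat_length),
                        (b_start, b_start + repeat_length))


def map_reads_to_reference(
    reads: list[ReadAlignment],
    reference: Genome,
    repeat_a: tuple[int, int],
    repeat_b: tuple[int, int],
    max_mismatch_frac: float = 0.08,
    seed: int | None = None,
) -> list[ReadAlignment]:
    """Place truth-coordinate reads on a coordinate-compatible reference.

    Each read is scored (Hamming mismatches) at its own locus and, when it
    lies fully inside one paralog copy, at the homologous locus in the other
    copy; it is placed at the best-scoring candidate (ties broken at
    random) and discarded when the best score exceeds
    ``ceil(max_mismatch_frac * read_length)`` — emulating an aligner's
    mismatch cap.  Mates are placed independently, as a real aligner places
    them when templates are short.
    """
    if seed is None:
        raise ValueError("map_reads_to_reference requires a seed")
    rng = np.random.default_rng(seed)
    ref = reference.codes
    (a0, a1), (b0, b1) = repeat_a, repeat_b
    out = []
    for r in reads:
        rl = len(r.seq)
        cand = [r.start]
        if a0 <= r.start and r.end <= a1:
            cand.append(r.start - a0 + b0)
        elif b0 <= r.start and r.end <= b1:
            cand.append(r.start - b0 + a0)
        scores = [int((r.seq != ref[c:c + rl]).sum()) for c in cand]
        best = min(scores)
        if best > int(np.ceil(max_mismatch_frac * rl)):
            continue
        winners = [c for c, s in zip(cand, scores) if s == best]
        pos = winners[0] if len(winners) == 1 else winners[int(rng.integers(len(winners)))]
        out.append(ReadAlignment(r.qname, reference.id, pos, r.is_reverse,
                                 r.seq, r.qual, r.tlen, r.is_read1, r.udg_class))
    return out


def cross_reference_experiment(
    family: GenomeFamily | None = None,
    read_lengths: tuple[int, ...] = (100, 75, 50),
    damage_levels: tuple[str, ...] = ("none", "low", "high"),
    depth: float = 20.0,
    seed: int | None = None,
    min_cov: int = 5,
    dominant_freq: float = 0.8,
) -> pd.DataFrame:
    """dN/dS grid over (source genome, reference genome, read length, damage).

    Simulates a read set from every source genome at each read length and
    deamination level, places it on every reference in the family with
    :func:`map_reads_to_reference`, and computes polymorphic-site dN/dS.
    Returns one row per cell with columns ``source``, ``reference``,
    ``read_length``, ``damage``, ``n_nonsynonymous``, ``n_synonymous``,
    ``n_considered``, ``n_polymorphic``, ``ratio`` (NaN when undefined).

    The mean ratio over incorrect-reference cells at the shortest read
    length — the summary the masking threshold is derived from — can be
    read off the returned frame; see :func:`incorrect_reference_mean`.
    """
    if seed is None:
        raise ValueError("cross_reference_experiment requires a seed")
    if family is None:
        family = paralog_genome_family(seed=seed)
    if len(family.genomes) < 2:
        raise ValueError("need at least 2 genomes")
    rng = np.random.default_rng(seed)
    rows = []
    for source in family.genomes:
        for rl in read_lengths:
            n_pairs = max(1, int(round(depth * len(source) / (2 * rl))))
            for level in damage_levels:
                cfg = SimulationConfig(seed=int(rng.integers(2 ** 31)), n_pairs=n_pairs,
                                       read_length=int(rl), damage=DAMAGE_LEVELS[level])
                reads = simulate_reads(source, cfg, sample_id=f"{source.id}_{rl}_{level}")
                for reference in family.genomes:
                    placed = map_reads_to_reference(
                        reads, reference, family.repeat_a, family.repeat_b,
                        seed=int(rng.integers(2 ** 31)))
                    pileup = build_pileup(placed, min_base_quality=30, min_insert=0,
                                          paired_only=False,
                                          reference_length=len(reference),
                                          sample_id=f"{source.id}->{reference.id}")
                    sites = classify_sites(pileup, reference.genes,
                                           min_cov=min_cov, dominant_freq=dominant_freq)
                    poly = sites[sites["state"] == "polymorphic"]
                    n_nonsyn = int((poly["effect"] == "nonsynonymous").sum())
                    n_syn = int((poly["effect"] == "synonymous").sum())
                    rows.append({
                        "source": source.id, "reference": reference.id,
                        "read_length": int(rl), "damage": level,
                        "n_nonsynonymous": n_nonsyn, "n_synonymous": n_syn,
                        "n_considered": int((sites["state"] != "unevaluated").sum()),
                        "n_polymorphic": int(len(poly)),
                        "ratio": n_nonsyn / n_syn if n_syn else np.nan,
                    })
    return pd.DataFrame(rows)


def incorrect_reference_mean(grid: pd.DataFrame, read_length: int | None = None) -> float:
    """Mean dN/dS over incorrect-reference cells, optionally at one read length.

    Defaults to the shortest read length in the grid, averaged across all
    deamination levels — the summary used as a multi-strain flagging
    threshold.
    """
    if read_length is None:
        read_length = int(grid["read_length"].min())
    sub = grid[(grid["source"] != grid["reference"]) & (grid["read_length"] == read_length)]
    return float(sub["ratio"].mean())
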