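"""Seeded synthetic data: genomes, damaged paired-end reads, abundance tables.

This module generates the inputs every downstream stage consumes, emulating
the statistical structure of shotgun-sequenced ancient dental calculus:

* pairs of bacterial genomes at a controlled nucleotide divergence
  (substitutions only, with the true substitution positions returned so
  tests can score results against a known truth);
* paired-end short reads carrying terminal cytosine-deamination damage
  (C→T from the 5′ end, G→A from the 3′ end of each read, in read
  orientation), parameterized by a geometric decay profile;
* sample-by-taxon abundance tables with a controlled oral/environmental
  split, for preservation screening and FAVA.

All randomness flows through a mandatory integer seed; identical
configuration and seed give byte-identical output, including SAM text.

The damage model is a two-parameter geometric decay ``rate(i) = d0·decay^i``
for read positions ``i < extent`` — a deliberate simplification of empirical
deamination profiles that reproduces the "high at the termini, decaying over
~10 bp" shape that read-end masking targets.  No indels and no sequencing
error other than deamination are simulated, which isolates the damage effect
that the masking calibration is designed to remove.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _seq
from ._seq import A, C, G, T

__all__ = [
    "Genome",
    "DamageProfile",
    "ReadAlignment",
    "SimulationConfig",
    "DAMAGE_NON_UDG",
    "DAMAGE_UDG_HALF",
    "DAMAGE_NONE",
    "generate_genome_pair",
    "annotate_orfs",
    "simulate_reads",
    "make_taxon_table",
    "sam_text",
    "write_sam",
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "read_sam",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class Genome:
    """A reference genome with optional protein-coding gene intervals.

    ``genes`` holds ``(start, end, strand)`` with 0-based half-open
    coordinates; gene intervals must lie within the sequence, not overlap,
    and have length divisible by 3.
    """

    id: str
    sequence: str
    genes: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")
        self._codes = _seq.encode(self.sequence)
        last_end = 0
        for start, end, strand in sorted(self.genes):
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"gene ({start},{end}) outside genome bounds")
            if (end - start) % 3:
                raise ValueError(f"gene ({start},{end}) length not divisible by 3")
            if start < last_end:
                raise ValueError("overlapping gene intervals")
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")
            last_end = end

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        """uint8 base codes (A=0, C=1, G=2, T=3)."""
        return self._codes


@dataclass(frozen=True)
class DamageProfile:
    """Geometric-decay deamination model.

    ``rate(i) = d0 * decay**i`` for read positions ``i < extent`` from the
    relevant read end (C→T from 5′, G→A from 3′, applied in read
    orientation), zero beyond ``extent``.
    """

    d0: float
    decay: float = 1.0
    extent: int = 0
    udg_class: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.d0 <= 1.0:
            raise ValueError("d0 must be in [0,1]")
        if not 0.0 < self.decay <= 1.0:
            raise ValueError("decay must be in (0,1]")
        if self.extent < 0:
            raise ValueError("extent must be >= 0")
        if self.udg_class not in ("none", "half", "non_udg"):
            raise ValueError(f"unknown udg_class {self.udg_class!r}")

    def rate(self, i: int | np.ndarray):
        """Per-base substitution probability at distance ``i`` from the end."""
        i = np.asarray(i)
        r = self.d0 * self.decay ** i
        return np.where(i < self.extent, r, 0.0)


#: Untreated library: strong terminal damage decaying over ~10-15 bases.
DAMAGE_NON_UDG = DamageProfile(d0=0.30, decay=0.70, extent=15, udg_class="non_udg")
#: Partial-UDG library: residual damage confined to the terminal 2 bases.
DAMAGE_UDG_HALF = DamageProfile(d0=0.05, decay=0.50, extent=2, udg_class="half")
#: Full UDG / modern DNA: no deamination.
DAMAGE_NONE = DamageProfile(d0=0.0, decay=1.0, extent=0, udg_class="none")

DAMAGE_BY_CLASS = {
    "non_udg": DAMAGE_NON_UDG,
    "half": DAMAGE_UDG_HALF,
    "none": DAMAGE_NONE,
}


@dataclass
class ReadAlignment:
    """One aligned read with its true coordinates (no aligner involved).

    ``seq``/``qual`` are stored in *reference* orientation, as a SAM record
    holds them.  ``tlen`` is the signed template length (positive for the
    leftmost mate).  ``mask`` marks how many aligned bases at each end are
    flagged non-contributing for pileup purposes; the read itself is never
    shortened and coordinates never change.
    """

    qname: str
    reference_id: str
    start: int
    is_reverse: bool
    seq: np.ndarray
    qual: np.ndarray
    tlen: int
    is_read1: bool = True
    udg_class: str = "none"
    mask: int = 0

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters for one simulated read set.  ``seed`` is mandatory.

    ``read_length`` is either a fixed length or a tuple of lengths sampled
    uniformly (an empirical length distribution).  ``insert_range`` is a
    closed interval for the template length, defaulting to
    ``[read_length, 2*read_length]`` so mates overlap about half the time,
    as is typical for short ancient-DNA fragments.
    """

    seed: int
    n_pairs: int = 1000
    read_length: int | tuple[int, ...] = 75
    insert_range: tuple[int, int] | None = None
    damage: DamageProfile = DAMAGE_NONE
    base_quality: int = 37

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("simulation requires an explicit seed")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


def generate_genome_pair(
    length: int,
    gc: float = 0.5,
    divergence: float = 0.0,
    seed: int | None = None,
    id_prefix: str = "genome",
) -> tuple[Genome, Genome, np.ndarray]:
    """Generate a genome and a substitution-only diverged copy.

    Each site of the copy is substituted independently with probability
    ``divergence`` (uniform choice among the three other bases), so the
    realized pairwise identity is exactly ``1 - n_subs/length``.  The true
    substitution positions are returned for oracle tests.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if seed is None:
        raise ValueError("generate_genome_pair requires a seed")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    positions = np.flatnonzero(rng.random(length) < divergence)
    codes2 = codes.copy()
    if positions.size:
        shift = rng.integers(1, 4, size=positions.size).astype(np.uint8)
        codes2[positions] = (codes2[positions] + shift) % 4
    g1 = Genome(f"{id_prefix}_a", _seq.decode(codes))
    g2 = Genome(f"{id_prefix}_b", _seq.decode(codes2))
    return g1, g2, positions


def mutate_genome(genome: Genome, divergence: float, seed: int, new_id: str) -> tuple[Genome, np.ndarray]:
    """Substitution-only mutated copy of ``genome`` (gene coordinates kept)."""
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    codes = genome.codes.copy()
    positions = np.flatnonzero(rng.random(len(codes)) < divergence)
    if positions.size:
        shift = rng.integers(1, 4, size=positions.size).astype(np.uint8)
        codes[positions] = (codes[positions] + shift) % 4
    return Genome(new_id, _seq.decode(codes), list(genome.genes)), positions


def annotate_orfs(genome: Genome, gene_length: int = 300, spacing: int = 100) -> Genome:
    """Tile the genome with non-overlapping forward-strand ORFs.

    Genes start every ``gene_length + spacing`` bases.  Each gene's sequence
    is rewritten in place so it begins with ATG and contains no in-frame
    stop codon (stops get their third base flipped to C, which never creates
    a new stop).  Returns a new :class:`Genome` carrying the edited sequence
    and the gene list.
    """
    if gene_length % 3:
        raise ValueError("gene_length must be divisible by 3")
    if gene_length > len(genome):
        raise ValueError("gene_length exceeds genome length")
    if spacing < 0:
        raise ValueError("spacing must be >= 0")
    codes = genome.codes.copy()
    genes = []
    start = 0
    while start + gene_length <= len(genome):
        end = start + gene_length
        codes[start:start + 3] = [A, T, G]
        for cstart in range(start, end, 3):
            codon = _seq.decode(codes[cstart:cstart + 3])
            if codon in STOP_CODONS:
                codes[cstart + 2] = C  # TAC=Tyr, TGC=Cys: no longer stops
        genes.append((start, end, "+"))
        start = end + spacing
    return Genome(genome.id, _seq.decode(codes), genes)


def simulate_reads(
    genome: Genome,
    config: SimulationConfig,
    sample_id: str = "sample",
) -> list[ReadAlignment]:
    """Simulate paired-end reads with terminal deamination damage.

    Fragments are placed uniformly over the genome.  The leftmost mate is
    sequenced on the forward strand, its mate on the reverse strand; damage
    is applied in read orientation (C→T from the 5′ end, G→A from the 3′
    end) and reverse reads are then stored back in reference orientation.
    True coordinates are recorded, so no aligner is involved.  Mates whose
    template is shorter than the read length are truncated to the template.
    """
    if len(genome) == 0:
        raise ValueError("empty genome")
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs
    L = len(genome)
    if isinstance(config.read_length, int):
        read_lens = np.full(n, config.read_length)
    else:
        read_lens = rng.choice(np.asarray(config.read_length), size=n)
    rl_max = int(read_lens.max())
    if rl_max > L:
        raise ValueError("read length exceeds genome length")
    lo, hi = config.insert_range if config.insert_range else (0, 0)
    if config.insert_range is None:
        inserts = np.minimum(read_lens * 2, L)
        inserts = rng.integers(read_lens, inserts + 1)
    else:
        inserts = rng.integers(lo, hi + 1, size=n)
        inserts = np.clip(inserts, read_lens, L)
    starts = rng.integers(0, L - inserts + 1)

    codes = genome.codes
    reads: list[ReadAlignment] = []
    # group by read length so damage can be applied on rectangular blocks
    for rl in np.unique(read_lens):
        idx = np.flatnonzero(read_lens == rl)
        rl = int(rl)
        s1 = starts[idx]
        s2 = starts[idx] + inserts[idx] - rl
        fwd = codes[s1[:, None] + np.arange(rl)]
        rev = codes[s2[:, None] + np.arange(rl)]
        # read orientation: reverse mate is the reverse complement
        rev = _seq.COMPLEMENT[rev[:, ::-1]]
        _apply_damage(fwd, config.damage, rng)
        _apply_damage(rev, config.damage, rng)
        rev = _seq.COMPLEMENT[rev[:, ::-1]]  # back to reference orientation
        qual = np.full(rl, config.base_quality, dtype=np.uint8)
        for k, i in enumerate(idx):
            qname = f"{sample_id}_p{i}"
            ins = int(inserts[i])
            reads.append(ReadAlignment(
                qname, genome.id, int(s1[k]), False, fwd[k], qual.copy(), ins,
                is_read1=True, udg_class=config.damage.udg_class))
            reads.append(ReadAlignment(
                qname, genome.id, int(s2[k]), True, rev[k], qual.copy(), -ins,
                is_read1=False, udg_class=config.damage.udg_class))
    reads.sort(key=lambda r: (r.start, r.qname, not r.is_read1))
    return reads


def _apply_damage(reads: np.ndarray, profile: DamageProfile, rng: np.random.Generator) -> None:
    """Apply terminal deamination in place; ``reads`` is (n, rl) in read orientation."""
    n, rl = reads.shape
    if profile.d0 == 0.0 or profile.extent == 0:
        return
    for i in range(min(profile.extent, rl)):
        p = profile.d0 * profile.decay ** i
        hit5 = (reads[:, i] == C) & (rng.random(n) < p)
        reads[hit5, i] = T
        j = rl - 1 - i
        hit3 = (reads[:, j] == G) & (rng.random(n) < p)
        reads[hit3, j] = A


@dataclass
class TaxonTable:
    """Samples × taxa abundance matrix plus the oral-taxon reference set."""

    abundances: pd.DataFrame
    oral_reference: set[str]

    def __post_init__(self) -> None:
        if (self.abundances.to_numpy() < 0).any():
            raise ValueError("negative abundances")


def make_taxon_table(
    n_samples: int,
    n_taxa: int = 40,
    oral_fraction_per_sample: float | list[float] = 0.8,
    seed: int | None = None,
    n_oral: int | None = None,
    total_counts: int = 10000,
    alpha: float = 0.5,
) -> TaxonTable:
    """Dirichlet-multinomial sample-by-taxon table with a controlled oral mass.

    By default 60% of the taxa form the oral reference set, mirroring how
    oral reference lists cover most taxa detectable in dental calculus.  For
    each sample a Dirichlet(alpha) composition is drawn separately over oral
    and environmental taxa, scaled to the requested expected oral fraction,
    and counts are drawn multinomially, so taxa on the minor side of a
    strongly skewed sample partly drop out at modest ``total_counts`` — the
    presence structure decay-curve screening relies on.  ``alpha=0.5``
    yields the skewed, few-taxa-dominate profiles typical of metagenomes.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if seed is None:
        raise ValueError("make_taxon_table requires a seed")
    fractions = np.broadcast_to(np.asarray(oral_fraction_per_sample, dtype=float), (n_samples,))
    if ((fractions < 0) | (fractions > 1)).any():
        raise ValueError("oral fractions must be in [0,1]")
    if n_oral is None:
        n_oral = int(round(0.6 * n_taxa))
    if not 0 < n_oral < n_taxa:
        raise ValueError("n_oral must leave both oral and environmental taxa")
    rng = np.random.default_rng(seed)
    oral_taxa = [f"Oral_taxon_{i:03d}" for i in range(n_oral)]
    env_taxa = [f"Env_taxon_{i:03d}" for i in range(n_taxa - n_oral)]
    rows = []
    for f in fractions:
        p_oral = rng.dirichlet(np.full(n_oral, alpha)) * f
        p_env = rng.dirichlet(np.full(n_taxa - n_oral, alpha)) * (1 - f)
        p = np.concatenate([p_oral, p_env])
        rows.append(rng.multinomial(total_counts, p / p.sum()))
    df = pd.DataFrame(rows, columns=oral_taxa + env_taxa,
                      index=[f"S{i:03d}" for i in range(n_samples)])
    return TaxonTable(df, set(oral_taxa))


# ---------------------------------------------------------------------------
# Format I/O: FASTA, GFF3, SAM, truth tables
# ---------------------------------------------------------------------------

def write_fasta(path: str, genomes: list[Genome]) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> list[Genome]:
    return [Genome(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_gff3(path: str, genome: Genome) -> None:
    """Write gene intervals as GFF3 CDS features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for i, (start, end, strand) in enumerate(genome.genes):
            attrs = f"ID=cds_{i:05d}"
            fh.write(f"{genome.id}\tcalcstrain\tCDS\t{start + 1}\t{end}\t.\t{strand}\t0\t{attrs}\n")


def read_gff3(path: str, genome: Genome) -> Genome:
    """Attach CDS intervals from a GFF3 file to ``genome``."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8 or parts[2] not in ("CDS", "gene"):
                continue
            if parts[0] != genome.id:
                continue
            genes.append((int(parts[3]) - 1, int(parts[4]), parts[6]))
    return Genome(genome.id, genome.sequence, genes)


def _sam_header(genome: Genome) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": genome.id, "LN": len(genome)}],
        "PG": [{"ID": "calcstrain", "PN": "calcstrain"}],
    }


def write_sam(path: str, genome: Genome, reads: list[ReadAlignment]) -> None:
    """Write reads as a valid SAM file (proper-pair flags, 1-based POS, TLEN)."""
    header = pysam.AlignmentHeader.from_dict(_sam_header(genome))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.qname
            a.query_sequence = _seq.decode(r.seq)
            a.reference_id = 0
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigarstring = f"{len(r.seq)}M"
            a.template_length = r.tlen
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.qual))
            flag = 0x1 | 0x2
            if r.is_reverse:
                flag |= 0x10
            else:
                flag |= 0x20
            flag |= 0x40 if r.is_read1 else 0x80
            a.flag = flag
            # mate coordinates from the signed template length
            if r.tlen >= 0:
                a.next_reference_start = r.start + r.tlen - len(r.seq)
            else:
                a.next_reference_start = r.start + r.tlen + len(r.seq)
            a.next_reference_id = 0
            out.write(a)


def sam_text(genome: Genome, reads: list[ReadAlignment]) -> str:
    """SAM output as text (deterministic for a fixed config and seed)."""
    with tempfile.NamedTemporaryFile("r", suffix=".sam") as tmp:
        write_sam(tmp.name, genome, reads)
        with open(tmp.name) as fh:
            return fh.read()


def read_sam(path: str, udg_class: str = "none") -> list[ReadAlignment]:
    """Load a SAM/BAM file into :class:`ReadAlignment` records.

    Only mapped reads with all-match CIGARs are supported (the pipeline
    consumes alignments, it does not produce them; indel-bearing records are
    rejected to keep coordinate bookkeeping exact).
    """
    reads = []
    with pysam.AlignmentFile(path) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            if a.cigartuples is None or any(op != 0 for op, _ in a.cigartuples):
                raise ValueError(f"read {a.query_name}: only all-match CIGARs supported")
            qual = np.asarray(a.query_qualities, dtype=np.uint8)
            reads.append(ReadAlignment(
                a.query_name, a.reference_name, a.reference_start, a.is_reverse,
                _seq.encode(a.query_sequence), qual, a.template_length,
                is_read1=not a.is_read2, udg_class=udg_class))
    return reads


def write_truth_positions(path: str, positions: np.ndarray, genome_id: str = "") -> None:
    """One substitution position (0-based) per line, TSV with a header."""
    pd.DataFrame({"genome": genome_id, "position": positions}).to_csv(path, sep="\t", index=False)
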