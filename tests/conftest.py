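"""Shared fixtures: hand-built reads/pileups and small seeded simulations."""

from __future__ import annotations

import numpy as np
import pytest

from calcstrain import synthdata as sd
from calcstrain._seq import encode
from calcstrain.strain import Pileup


def make_read(
    qname: str,
    start: int,
    seq: str,
    is_reverse: bool = False,
    tlen: int | None = None,
    qual: int | list[int] = 37,
    is_read1: bool = True,
    udg_class: str = "none",
    mask: int = 0,
    reference_id: str = "ref",
) -> sd.ReadAlignment:
    """Hand-construct a read with explicit coordinates and qualities."""
    codes = encode(seq)
    q = np.full(len(seq), qual, dtype=np.uint8) if isinstance(qual, int) else \
        np.asarray(qual, dtype=np.uint8)
    if tlen is None:
        tlen = len(seq)
    return sd.ReadAlignment(qname, reference_id, start, is_reverse, codes, q,
                            tlen, is_read1, udg_class, mask)


def make_pair(qname: str, start: int, seq1: str, seq2: str, insert: int, **kw):
    """A proper pair: forward mate at ``start``, reverse mate ending at start+insert."""
    r1 = make_read(qname, start, seq1, False, insert, is_read1=True, **kw)
    r2 = make_read(qname, start + insert - len(seq2), seq2, True, -insert,
                   is_read1=False, **kw)
    return [r1, r2]


def pileup_from_counts(counts: dict[int, dict[str, int]], length: int,
                       sample_id: str = "s", reference_id: str = "ref") -> Pileup:
    """Build a pileup directly from {position: {base: count}}."""
    arr = np.zeros((length, 4), dtype=np.int64)
    order = "ACGT"
    for pos, bases in counts.items():
        for b, c in bases.items():
            arr[pos, order.index(b)] = c
    return Pileup(reference_id, sample_id, arr)


@pytest.fixture(scope="session")
def coding_genome() -> sd.Genome:
    """A 6 kb genome tiled with ORFs, shared by polymorphism tests."""
    raw, _, _ = sd.generate_genome_pair(6000, 0.5, 0.0, seed=101)
    return sd.annotate_orfs(raw, gene_length=300, spacing=60)
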