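"""Per-family occurrence streams and ordered codon-pair co-occurrence counts.

The unit of analysis is the *occurrence stream*: the in-order subsequence of
a gene's codons belonging to one synonymous family.  Pairs are ordered
(C[i,j] counts codon i followed by codon j) and never cross gene boundaries
— tRNA reuse is a per-transcript hypothesis.

Three pairing strategies are provided because the exact historical counting
rule is under-specified (see README):

* ``consecutive`` — each adjacent ordered pair (occurrence t, t+1);
* ``all_pairs``   — every ordered pair (s, t) with s < t within a gene;
* ``windowed``    — ordered pairs whose codon-index distance is <= W.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from codonreuse.codon_model import SynonymousFamily
from codonreuse.genome_io import CDSRecord

STRATEGIES = ("consecutive", "all_pairs", "windowed")


@dataclass
class OccurrenceStream:
    """Ordered occurrences of one family's codons within one gene."""

    gene_id: str
    family: str
    occurrences: List[Tuple[str, int]]  # (codon, codon index within gene)

    def __len__(self) -> int:
        return len(self.occurrences)


@dataclass
class PairCountTable:
    family: str
    codons: Tuple[str, ...]
    counts: np.ndarray  # square int matrix, ordered pairs
    strategy: str
    window: Optional[int] = None

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        import pandas as pd

        rows = [
            (self.family, ci, cj, int(self.counts[i, j]))
            for i, ci in enumerate(self.codons)
            for j, cj in enumerate(self.codons)
        ]
        return pd.DataFrame(rows, columns=["family", "codon_i", "codon_j", "count"])


@dataclass
class ClassProfile:
    """Per-codon occurrence counts and frequencies for one family."""

    family: str
    codons: Tuple[str, ...]
    counts: np.ndarray  # per-codon occurrence counts
    empty: bool = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.empty = self.N == 0

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def f(self) -> np.ndarray:
        if self.empty:
            return np.zeros(len(self.codons))
        return self.counts / self.N


def family_stream(record: CDSRecord, family: SynonymousFamily) -> OccurrenceStream:
    """In-order extraction of the record's codons belonging to the family.

    Masked codons are excluded; the codon indices of the remaining
    occurrences are preserved (they are gene positions, not stream ranks).
    """
    members = set(family.codons)
    occ = [
        (c, i)
        for i, c in enumerate(record.codons)
        if i not in record.masked_positions and c in members
    ]
    return OccurrenceStream(gene_id=record.gene_id, family=family.name, occurrences=occ)


def count_pairs(
    streams: Iterable[OccurrenceStream],
    family: SynonymousFamily,
    strategy: str = "consecutive",
    window: Optional[int] = None,
) -> PairCountTable:
    """Count ordered codon-pair co-occurrences over per-gene streams.

    Gene boundaries are never crossed.  ``window`` is the maximum codon-index
    distance and is required (>= 1) for the ``windowed`` strategy.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if strategy == "windowed":
        if window is None or window < 1:
            raise ValueError("windowed strategy requires window >= 1")

    k = family.degeneracy
    idx = {c: i for i, c in enumerate(family.codons)}
    counts = np.zeros((k, k), dtype=np.int64)

    for stream in streams:
        if stream.family != family.name:
            raise ValueError(
                f"stream family {stream.family} does not match {family.name}"
            )
        occ = stream.occurrences
        n = len(occ)
        if n < 2:
            continue
        codes = [idx[c] for c, _ in occ]
        if strategy == "consecutive":
            for t in range(n - 1):
                counts[codes[t], codes[t + 1]] += 1
        elif strategy == "all_pairs":
            # suffix-count sweep: O(n*k) instead of O(n^2)
            suffix = np.zeros(k, dtype=np.int64)
            for s in range(n - 1, -1, -1):
                counts[codes[s]] += suffix
                suffix[codes[s]] += 1
        else:  # windowed
            positions = [p for _, p in occ]
            t0 = 0
            for s in range(n):
                for t in range(s + 1, n):
                    if positions[t] - positions[s] > window:
                        break
                    counts[codes[s], codes[t]] += 1

    return PairCountTable(
        family=family.name, codons=family.codons, counts=counts,
        strategy=strategy, window=window if strategy == "windowed" else None,
    )


def class_profile(records: Sequence[CDSRecord], family: SynonymousFamily) -> ClassProfile:
    """Occurrence counts of the family's codons over all (unmasked) codons.

    N is the class total — the number of times the amino-acid block occurs —
    and f the per-codon frequencies.  An all-zero profile is flagged empty;
    downstream statistics skip it.
    """
    idx = {c: i for i, c in enumerate(family.codons)}
    counts = np.zeros(family.degeneracy, dtype=np.int64)
    for rec in records:
        for i, c in enumerate(rec.codons):
            if i in rec.masked_positions:
                continue
            j = idx.get(c)
            if j is not None:
                counts[j] += 1
    return ClassProfile(family=family.name, codons=family.codons, counts=counts)
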