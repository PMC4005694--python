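"""Independent brute-force oracles, kept separate from the implementation.

The pair-counting oracle enumerates *all* ordered occurrence index pairs
(s, t), s < t, within each gene stream and filters by the strategy
predicate — O(n^2), no shared code with ``codonreuse.pair_counting``.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from codonreuse.codon_model import SynonymousFamily
from codonreuse.pair_counting import OccurrenceStream


def brute_force_pair_counts(
    streams: Iterable[OccurrenceStream],
    family: SynonymousFamily,
    strategy: str,
    window: Optional[int] = None,
) -> np.ndarray:
    idx = {c: i for i, c in enumerate(family.codons)}
    k = family.degeneracy
    counts = np.zeros((k, k), dtype=np.int64)
    for stream in streams:
        occ = stream.occurrences
        for s in range(len(occ)):
            for t in range(s + 1, len(occ)):
                if strategy == "consecutive":
                    keep = t == s + 1
                elif strategy == "all_pairs":
                    keep = True
                elif strategy == "windowed":
                    keep = occ[t][1] - occ[s][1] <= window
                else:
                    raise ValueError(strategy)
                if keep:
                    counts[idx[occ[s][0]], idx[occ[t][0]]] += 1
    return counts


def random_genome_records(rng: np.random.Generator, families, max_genes=20, max_codons=50):
    """Random small synthetic gene set over the analyzed codons."""
    from codonreuse.genome_io import CDSRecord

    all_codons = [c for f in families for c in f.codons]
    n_genes = int(rng.integers(1, max_genes + 1))
    records = []
    for g in range(n_genes):
        n = int(rng.integers(1, max_codons + 1))
        codons = [all_codons[i] for i in rng.integers(0, len(all_codons), n)]
        records.append(CDSRecord(gene_id=f"r{g}", strand="+", codons=codons))
    return records
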