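"""Expected-count model and the three deviation statistics.

Under positional independence the expected count of the ordered pair (i, j)
is E_ij = N * f_i * f_j, with f the per-codon frequencies of the family and
N a normalising total.  Two normalisations are supported:

* ``class_occurrences`` (default) — N is the family's occurrence total, the
  historical definition;
* ``pair_total`` — N is the number of counted pairs, so that sum(E) equals
  the number of observed pairs.  This is the properly normalised variant
  needed for calibration against a null.

Deviation statistics per ordered pair:

* percent deviation: 100 * (C - E) / E;
* binomial z: (C - E) / sqrt(N * p * (1 - p)) with p = f_i * f_j;
* log2 enrichment ("log2 norm"): log2 of the joint pair probability over the
  product of the marginals, with an optional pseudocount guarding zeros.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from codonreuse.pair_counting import ClassProfile, PairCountTable

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("class_occurrences", "pair_total")


@dataclass
class ExpectedTable:
    family: str
    codons: tuple
    expected: np.ndarray  # E_ij = N_used * f_i * f_j
    normalization: str
    n_used: float


@dataclass
class DeviationTable:
    """Per ordered pair: count, expected, pct, z, log2norm, quantile, flag.

    Backed by a long-format DataFrame with one row per ordered codon pair;
    metadata records the normalisation, totals and pairing strategy.
    """

    family: str
    codons: tuple
    data: pd.DataFrame
    normalization: str
    n_used: float
    n_pairs: int
    strategy: str
    pseudocount: float = 0.5

    def matrix(self, column: str) -> np.ndarray:
        k = len(self.codons)
        pos = {c: i for i, c in enumerate(self.codons)}
        m = np.full((k, k), np.nan)
        for _, row in self.data.iterrows():
            m[pos[row.codon_i], pos[row.codon_j]] = row[column]
        return m


def expected_counts(
    profile: ClassProfile,
    normalization: str = "class_occurrences",
    pairs: Optional[PairCountTable] = None,
) -> Optional[ExpectedTable]:
    """E_ij = N_used * f_i * f_j.

    ``pairs`` supplies the pair total and is required for the ``pair_total``
    normalisation.  Empty profiles are skipped with a warning (returns None).
    """
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {normalization!r}")
    if profile.empty:
        logger.warning("family %s has no occurrences; skipping", profile.family)
        return None
    if normalization == "class_occurrences":
        n_used = float(profile.N)
    else:
        if pairs is None:
            raise ValueError("pair_total normalization requires the pair count table")
        n_used = float(pairs.n_pairs)
    f = profile.f
    return ExpectedTable(
        family=profile.family,
        codons=tuple(profile.codons),
        expected=n_used * np.outer(f, f),
        normalization=normalization,
        n_used=n_used,
    )


def percent_deviation(count: float, expected: float) -> float:
    """100 * (C - E) / E; NaN (logged) when E is zero with C > 0."""
    if expected > 0:
        return 100.0 * (count - expected) / expected
    if count > 0:
        logger.warning("percent deviation undefined: C=%s with E=0", count)
    return math.nan


def binomial_z(count: float, expected: float, n_used: float, f_i: float, f_j: float) -> float:
    """(C - E) / sqrt(N p (1-p)), p = f_i * f_j, binomial-model deviation."""
    p = f_i * f_j
    if not 0.0 < p < 1.0 or n_used <= 0:
        return math.nan
    return (count - expected) / math.sqrt(n_used * p * (1.0 - p))


def log2_norm(
    count: float,
    n_pairs: int,
    f_i: float,
    f_j: float,
    k: int,
    pseudocount: float = 0.5,
) -> float:
    """log2 of joint pair probability over the product of the marginals.

    log2( ((C + a) / (n_pairs + a*k^2)) / (f_i * f_j) ) with pseudocount a
    (default 0.5; set 0 for the bare definition, valid when C > 0) and k the
    family size.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    denom = f_i * f_j
    if denom <= 0:
        return math.nan
    p_joint = (count + pseudocount) / (n_pairs + pseudocount * k * k)
    if p_joint <= 0:
        return -math.inf
    return math.log2(p_joint / denom)


def assemble_deviation_table(
    pairs: PairCountTable,
    expected: ExpectedTable,
    profile: ClassProfile,
    null=None,
    pseudocount: float = 0.5,
    threshold: float = 0.95,
) -> DeviationTable:
    """Combine counts, expected model and statistics into one long table.

    Quantile and significance columns are populated only when a null
    distribution is supplied (see :mod:`codonreuse.empirical_null`).
    """
    if not (pairs.family == expected.family == profile.family):
        raise ValueError("family mismatch between counts, expected and profile")
    if pairs.codons != expected.codons or tuple(profile.codons) != pairs.codons:
        raise ValueError("codon order mismatch between inputs")

    k = len(pairs.codons)
    f = profile.f
    n_pairs = pairs.n_pairs
    rows = []
    for i, ci in enumerate(pairs.codons):
        for j, cj in enumerate(pairs.codons):
            c = float(pairs.counts[i, j])
            e = float(expected.expected[i, j])
            rows.append(
                {
                    "family": pairs.family,
                    "codon_i": ci,
                    "codon_j": cj,
                    "count": int(c),
                    "expected": e,
                    "pct_dev": percent_deviation(c, e),
                    "z": binomial_z(c, e, expected.n_used, f[i], f[j]),
                    "log2norm": (
                        log2_norm(c, n_pairs, f[i], f[j], k, pseudocount)
                        if n_pairs > 0
                        else math.nan
                    ),
                    "quantile": math.nan,
                    "significant": False,
                }
            )
    table = DeviationTable(
        family=pairs.family,
        codons=pairs.codons,
        data=pd.DataFrame(rows),
        normalization=expected.normalization,
        n_used=expected.n_used,
        n_pairs=n_pairs,
        strategy=pairs.strategy,
        pseudocount=pseudocount,
    )
    if null is not None:
        from codonreuse.empirical_null import flag_significant, observed_quantile

        table = observed_quantile(null, table)
        table = flag_significant(table, threshold)
    return table
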