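"""Monte-Carlo empirical null for the per-pair log2 enrichment.

For each family, B random codon sequences of L residues are drawn iid from
the family's observed codon frequencies; on each sequence the log2
enrichment of every ordered adjacent pair is computed (n_pairs = L - 1),
yielding an empirical distribution of B values per pair.  An observed value
is then located as its quantile (weak inequality, ties counted in, B in the
denominator) inside that distribution, and positive deviations above a
quantile threshold are flagged significant.

The null is built from freshly generated iid sequences — not resampled
genes — so it captures what pair enrichments look like when successive
synonymous choices are independent at the genome's codon frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from codonreuse.pair_counting import ClassProfile
from codonreuse.pair_stats import DeviationTable

logger = logging.getLogger(__name__)


@dataclass
class NullConfig:
    """B replicates of L residues; 5000 x 1000 is the analysis default."""

    B: int = 5000
    L: int = 1000
    seed: int = 0
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.L < 2:
            raise ValueError("L must be >= 2")


@dataclass
class NullDistribution:
    family: str
    codons: tuple
    values: np.ndarray  # shape (k, k, B), sorted ascending along the last axis
    config: NullConfig = field(repr=False, default=None)

    @property
    def B(self) -> int:
        return self.values.shape[-1]


def _pair_log2norm_batch(
    codes: np.ndarray, k: int, f: np.ndarray, pseudocount: float
) -> np.ndarray:
    """log2 enrichment of all ordered pairs for each row of iid codon codes.

    codes: (B, L) integer array; returns (B, k, k).
    """
    B, L = codes.shape
    n_pairs = L - 1
    pair_codes = codes[:, :-1] * k + codes[:, 1:]
    offsets = (np.arange(B) * k * k)[:, None]
    flat = (pair_codes + offsets).ravel()
    counts = np.bincount(flat, minlength=B * k * k).reshape(B, k, k)
    denom = np.outer(f, f)[None, :, :]
    p_joint = (counts + pseudocount) / (n_pairs + pseudocount * k * k)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log2(p_joint / denom)
    vals[:, denom[0] <= 0] = np.nan
    return vals


def pair_log2norm_replicates(
    profile: ClassProfile,
    B: int,
    L: int,
    rng: np.random.Generator,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """B iid replicate sequences of L codons; per-replicate per-pair log2
    enrichment, shape (B, k, k).  Building block of the null, also used to
    draw probe replicates for calibration checks."""
    k = len(profile.codons)
    codes = rng.choice(k, size=(B, L), p=profile.f)
    return _pair_log2norm_batch(codes, k, profile.f, pseudocount)


def simulate_null(
    profile: ClassProfile,
    config: NullConfig,
    rng: Optional[np.random.Generator] = None,
) -> Optional[NullDistribution]:
    """Simulate the per-pair null distribution for one family.

    Each replicate draws L codons independently from the profile's
    frequencies; adjacent ordered pairs within the replicate are counted.
    Returns None (with a warning) for degenerate profiles in which fewer
    than two codons occur.
    """
    if profile.empty or int(np.count_nonzero(profile.counts)) < 2:
        logger.warning("family %s: degenerate frequency profile, null skipped", profile.family)
        return None
    if rng is None:
        rng = np.random.default_rng(config.seed)
    vals = pair_log2norm_replicates(
        profile, config.B, config.L, rng, config.pseudocount
    )  # (B,k,k)
    vals = np.sort(np.moveaxis(vals, 0, -1), axis=-1)  # (k,k,B)
    return NullDistribution(family=profile.family, codons=tuple(profile.codons),
                            values=vals, config=config)


def observed_quantile(null: NullDistribution, observed: DeviationTable) -> DeviationTable:
    """Locate each observed log2 enrichment inside its empirical null.

    quantile_ij = (# null values <= observed_ij) / B, in [0, 1].  Pairs
    absent from the null get NaN with a log message.
    """
    if null.family != observed.family:
        raise ValueError(f"null family {null.family} != table family {observed.family}")
    pos = {c: i for i, c in enumerate(null.codons)}
    B = null.B
    quantiles = []
    for _, row in observed.data.iterrows():
        i, j = pos.get(row.codon_i), pos.get(row.codon_j)
        if i is None or j is None:
            logger.warning("pair %s-%s missing from null", row.codon_i, row.codon_j)
            quantiles.append(np.nan)
            continue
        vec = null.values[i, j]
        if np.isnan(vec).all() or np.isnan(row.log2norm):
            quantiles.append(np.nan)
            continue
        quantiles.append(np.searchsorted(vec, row.log2norm, side="right") / B)
    observed.data["quantile"] = quantiles
    return observed


def flag_significant(table: DeviationTable, threshold: float = 0.95) -> DeviationTable:
    """Flag positive deviations at or above the quantile threshold.

    significant = (quantile >= threshold) AND (pct_dev > 0): only the
    reuse (positive) direction is flagged.
    """
    q = table.data["quantile"]
    table.data["significant"] = (q >= threshold) & (table.data["pct_dev"] > 0)
    return table
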