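"""Synthetic coding-sequence genomes with a controllable tRNA-reuse bias.

Each gene is a sequence of amino-acid (family) draws; within a gene, the
first occurrence of a family draws its codon from the family's frequency
vector f, and every subsequent occurrence *reuses* with probability rho:

* ``identical`` mode — the previous codon is repeated verbatim;
* ``cotrna`` mode — a codon is drawn uniformly from the previous codon's
  co-tRNA group (codons decoded by the same isoacceptor).

With probability 1 - rho the codon is a fresh draw from f.  In identical
mode the per-family codon chain has transition P(i -> i) = rho + (1-rho)f_i
and stationary distribution f, giving the closed-form diagonal enrichment

    pct_ii = 100 * rho * (1 - f_i) / f_i

under consecutive pairing with the pair-total normalisation — the ground
truth used by the calibration and recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from codonreuse.codon_model import (
    SynonymousFamily,
    cotrna_groups,
    default_isoacceptor_map,
    partition_families,
    standard_code,
)
from codonreuse.genome_io import CDSRecord, write_fasta_cds

REUSE_MODES = ("identical", "cotrna")


def default_families() -> List[SynonymousFamily]:
    return partition_families(standard_code(11))


def default_background(families: List[SynonymousFamily]) -> Dict[str, float]:
    """Uniform over the analyzed amino acids, split equally across blocks.

    Every amino acid with degeneracy >= 2 (18 of the 20) gets equal weight;
    six-fold amino acids split theirs equally between quartet and doublet.
    """
    by_aa: Dict[str, List[str]] = {}
    for fam in families:
        by_aa.setdefault(fam.amino_acid, []).append(fam.name)
    n_aa = len(by_aa)
    bg: Dict[str, float] = {}
    for aa, names in by_aa.items():
        for name in names:
            bg[name] = 1.0 / (n_aa * len(names))
    return bg


@dataclass
class SyntheticConfig:
    """Generator parameters; (config, seed) fully determines the genome."""

    n_genes: int = 200
    gene_length: Union[int, Tuple[int, int]] = 300  # analyzed codons per gene
    rho: float = 0.0
    reuse_mode: str = "identical"
    seed: int = 0
    family_freqs: Optional[Dict[str, np.ndarray]] = None  # default: uniform per family
    background: Optional[Dict[str, float]] = None  # family name -> probability

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.reuse_mode not in REUSE_MODES:
            raise ValueError(f"reuse_mode must be one of {REUSE_MODES}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth for recovery tests: config echo, analytic diagonal
    enrichments, and the realized per-codon counts."""

    config: SyntheticConfig
    expected_diagonal_pct: Dict[str, np.ndarray]  # family -> per-codon pct
    realized_counts: Dict[str, np.ndarray] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["# synthetic genome ground truth"]
        cfg = self.config
        lines += [
            f"n_genes={cfg.n_genes}",
            f"gene_length={cfg.gene_length}",
            f"rho={cfg.rho}",
            f"reuse_mode={cfg.reuse_mode}",
            f"seed={cfg.seed}",
        ]
        for fam in sorted(self.expected_diagonal_pct):
            vals = ",".join(f"{v:.6f}" for v in self.expected_diagonal_pct[fam])
            lines.append(f"expected_diagonal_pct.{fam}={vals}")
        for fam in sorted(self.realized_counts):
            vals = ",".join(str(int(v)) for v in self.realized_counts[fam])
            lines.append(f"realized_counts.{fam}={vals}")
        return "\n".join(lines) + "\n"


def analytic_diagonal_pct(rho: float, f_i: float) -> float:
    """Expected diagonal percent deviation, identical mode, consecutive
    pairing, pair-total normalisation: 100 * rho * (1 - f_i) / f_i.

    Derivation: P(i -> i) = rho + (1 - rho) f_i, stationary distribution f,
    so E[C_ii]/n_pairs = f_i (rho + (1-rho) f_i) while the independence
    model gives f_i^2.
    """
    if not 0.0 < f_i < 1.0:
        raise ValueError(f"f_i must be in (0, 1), got {f_i}")
    return 100.0 * rho * (1.0 - f_i) / f_i


def estimate_rho(pct: float, f_i: float) -> float:
    """Invert the diagonal closed form: rho_hat = (pct/100) * f_i / (1 - f_i)."""
    if not 0.0 < f_i < 1.0:
        raise ValueError(f"f_i must be in (0, 1), got {f_i}")
    return (pct / 100.0) * f_i / (1.0 - f_i)


def _resolve_freqs(
    families: List[SynonymousFamily], config: SyntheticConfig
) -> Dict[str, np.ndarray]:
    freqs: Dict[str, np.ndarray] = {}
    for fam in families:
        if config.family_freqs and fam.name in config.family_freqs:
            f = np.asarray(config.family_freqs[fam.name], dtype=float)
            if len(f) != fam.degeneracy:
                raise ValueError(
                    f"{fam.name}: frequency vector length {len(f)} != degeneracy {fam.degeneracy}"
                )
            if abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
                raise ValueError(f"{fam.name}: frequencies must be non-negative and sum to 1")
        else:
            f = np.full(fam.degeneracy, 1.0 / fam.degeneracy)
        freqs[fam.name] = f
    return freqs


def generate_genome(
    config: SyntheticConfig,
    families: Optional[List[SynonymousFamily]] = None,
    out_fasta: Optional[str | Path] = None,
) -> Tuple[List[CDSRecord], TruthRecord]:
    """Generate a synthetic genome under the first-order reuse process.

    Returns the CDS records (ATG prepended, TAA appended, valid input for
    :mod:`codonreuse.genome_io`) and the ground-truth record; optionally
    writes the genome as FASTA.  Byte-identical output for identical
    (config, seed).
    """
    if families is None:
        families = default_families()
    fam_by_name = {f.name: f for f in families}
    freqs = _resolve_freqs(families, config)
    background = config.background or default_background(families)
    unknown = set(background) - set(fam_by_name)
    if unknown:
        raise ValueError(f"background names unknown families: {sorted(unknown)}")

    bg_names = sorted(background)
    bg_p = np.array([background[n] for n in bg_names], dtype=float)
    if (bg_p < 0).any() or bg_p.sum() <= 0:
        raise ValueError("background weights must be non-negative with positive sum")
    bg_p = bg_p / bg_p.sum()
    bg_cdf = np.cumsum(bg_p)

    fam_cdfs = {n: np.cumsum(freqs[n]) for n in bg_names}
    fam_codons = {n: fam_by_name[n].codons for n in bg_names}

    groups_of: Dict[str, Dict[str, Tuple[str, ...]]] = {}
    if config.reuse_mode == "cotrna":
        iso = default_isoacceptor_map()
        for n in bg_names:
            fam = fam_by_name[n]
            codon_group: Dict[str, Tuple[str, ...]] = {}
            for grp in cotrna_groups(fam, iso):
                for c in grp:
                    codon_group[c] = grp
            groups_of[n] = codon_group

    rng = np.random.default_rng(config.seed)
    records: List[CDSRecord] = []
    realized: Dict[str, np.ndarray] = {
        n: np.zeros(len(fam_codons[n]), dtype=np.int64) for n in bg_names
    }
    codon_index = {n: {c: i for i, c in enumerate(fam_codons[n])} for n in bg_names}

    for g in range(config.n_genes):
        if isinstance(config.gene_length, tuple):
            lo, hi = config.gene_length
            L = int(rng.integers(lo, hi + 1))
        else:
            L = int(config.gene_length)
        fam_idx = np.searchsorted(bg_cdf, rng.random(L), side="right")
        u_reuse = rng.random(L)
        u_codon = rng.random(L)
        last: Dict[str, str] = {}
        codons = ["ATG"]
        for t in range(L):
            name = bg_names[fam_idx[t]]
            prev = last.get(name)
            if prev is not None and u_reuse[t] < config.rho:
                if config.reuse_mode == "identical":
                    codon = prev
                else:
                    grp = groups_of[name][prev]
                    codon = grp[int(u_codon[t] * len(grp)) % len(grp)]
            else:
                j = int(np.searchsorted(fam_cdfs[name], u_codon[t], side="right"))
                codon = fam_codons[name][min(j, len(fam_codons[name]) - 1)]
            codons.append(codon)
            last[name] = codon
            realized[name][codon_index[name][codon]] += 1
        codons.append("TAA")
        records.append(
            CDSRecord(gene_id=f"synth{g:05d}", strand="+", codons=codons,
                      source_coords=f"synthetic:{g}")
        )

    expected_diag = {
        n: np.array(
            [
                analytic_diagonal_pct(config.rho, fi) if 0 < fi < 1 else np.nan
                for fi in freqs[n]
            ]
        )
        for n in bg_names
    }
    truth = TruthRecord(config=config, expected_diagonal_pct=expected_diag,
                        realized_counts=realized)
    if out_fasta is not None:
        write_fasta_cds(records, out_fasta)
    return records, truth
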