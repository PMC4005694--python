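"""End-to-end orchestration: records -> per-family deviation tables.

This is the library core behind the ``codonreuse analyze`` command; tests
and scripts call :func:`run_analysis` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from codonreuse.codon_model import (
    SynonymousFamily,
    partition_families,
    standard_code,
)
from codonreuse.empirical_null import NullConfig, simulate_null
from codonreuse.genome_io import CDSRecord, validate_and_trim
from codonreuse.pair_counting import (
    ClassProfile,
    PairCountTable,
    class_profile,
    count_pairs,
    family_stream,
)
from codonreuse.pair_stats import (
    DeviationTable,
    assemble_deviation_table,
    expected_counts,
)

SCOPES = ("block", "amino-acid")


@dataclass
class RunConfig:
    """Everything a run needs; echoed verbatim into every output header."""

    scope: str = "block"
    strategy: str = "consecutive"
    window: Optional[int] = None
    normalization: str = "class_occurrences"
    null_B: int = 5000
    null_L: int = 1000
    seed: int = 0
    sig_threshold: float = 0.95
    pseudocount: float = 0.5
    table_id: int = 11

    def header_lines(self) -> List[str]:
        return [
            f"# scope={self.scope}",
            f"# strategy={self.strategy}",
            f"# window={self.window if self.window is not None else 'NA'}",
            f"# normalization={self.normalization}",
            f"# null_B={self.null_B}",
            f"# null_L={self.null_L}",
            f"# seed={self.seed}",
            f"# sig_threshold={self.sig_threshold}",
            f"# pseudocount={self.pseudocount}",
            f"# table_id={self.table_id}",
        ]


@dataclass
class AnalysisResult:
    config: RunConfig
    tables: Dict[str, DeviationTable]
    profiles: Dict[str, ClassProfile]
    pair_tables: Dict[str, PairCountTable]
    n_records_in: int = 0
    n_records_valid: int = 0
    skipped: List[str] = field(default_factory=list)

    def combined(self) -> pd.DataFrame:
        frames = [t.data for _, t in sorted(self.tables.items())]
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)


def _aa_scope_counts(
    records: Sequence[CDSRecord],
    family: SynonymousFamily,
    siblings: List[SynonymousFamily],
    strategy: str,
    window: Optional[int],
) -> PairCountTable:
    """Amino-acid scope: one stream per amino acid, within-block tabulation.

    The merged stream runs over every codon of the amino acid (all blocks);
    pairs whose two members both fall in the target block are tabulated.
    """
    merged_codons = tuple(sorted(c for f in siblings for c in f.codons))
    merged = SynonymousFamily(
        name=f"{family.amino_acid}_all", amino_acid=family.amino_acid,
        codons=merged_codons, degeneracy=len(merged_codons),
    )
    streams = [family_stream(r, merged) for r in records]
    big = count_pairs(streams, merged, strategy=strategy, window=window)
    idx = [merged_codons.index(c) for c in family.codons]
    sub = big.counts[np.ix_(idx, idx)].copy()
    return PairCountTable(family=family.name, codons=family.codons, counts=sub,
                          strategy=strategy, window=big.window)


def run_analysis(
    records: Sequence[CDSRecord],
    config: RunConfig,
    families: Optional[List[SynonymousFamily]] = None,
    with_null: bool = True,
) -> AnalysisResult:
    """Validate records, count pairs, compute statistics and (optionally)
    the Monte-Carlo null, for every synonymous family.

    Records are stop-trimmed and internally-stopped records dropped before
    counting.  Null replicate streams are seeded deterministically per
    family from ``config.seed``.
    """
    if config.scope not in SCOPES:
        raise ValueError(f"unknown scope {config.scope!r}")
    code = standard_code(config.table_id)
    if families is None:
        families = partition_families(code)
    by_aa: Dict[str, List[SynonymousFamily]] = {}
    for fam in families:
        by_aa.setdefault(fam.amino_acid, []).append(fam)

    result = AnalysisResult(config=config, tables={}, profiles={}, pair_tables={},
                            n_records_in=len(records))
    clean: List[CDSRecord] = []
    for rec in records:
        v = validate_and_trim(rec, code)
        if v.valid:
            clean.append(v)
        else:
            result.skipped.append(f"{rec.gene_id}\t{v.reason}")
    result.n_records_valid = len(clean)
    if not clean:
        raise ValueError("no valid coding sequences after validation")

    fam_names = sorted(f.name for f in families)
    seed_seq = np.random.SeedSequence(config.seed)
    children = {name: ss for name, ss in zip(fam_names, seed_seq.spawn(len(fam_names)))}

    for fam in sorted(families, key=lambda f: f.name):
        profile = class_profile(clean, fam)
        result.profiles[fam.name] = profile
        if config.scope == "amino-acid":
            pairs = _aa_scope_counts(clean, fam, by_aa[fam.amino_acid],
                                     config.strategy, config.window)
        else:
            streams = [family_stream(r, fam) for r in clean]
            pairs = count_pairs(streams, fam, strategy=config.strategy,
                                window=config.window)
        result.pair_tables[fam.name] = pairs
        expected = expected_counts(profile, config.normalization, pairs)
        if expected is None or pairs.n_pairs == 0:
            continue
        null = None
        if with_null and config.null_B > 0:
            rng = np.random.default_rng(children[fam.name])
            null = simulate_null(
                profile,
                NullConfig(B=config.null_B, L=config.null_L, seed=config.seed,
                           pseudocount=config.pseudocount),
                rng=rng,
            )
        result.tables[fam.name] = assemble_deviation_table(
            pairs, expected, profile, null=null,
            pseudocount=config.pseudocount, threshold=config.sig_threshold,
        )
    return result


def strategy_block_totals(
    records: Sequence[CDSRecord],
    families: Optional[List[SynonymousFamily]] = None,
    window: Optional[int] = None,
    table_id: int = 11,
) -> pd.DataFrame:
    """Per-family pair totals under every implemented pairing strategy.

    Reported alongside the statistics because the historical counting rule
    behind published genome tables is under-specified: raw block totals are
    interpretation-dependent, while the percent-deviation arithmetic is not.
    Columns: family, class_total_N, consecutive, all_pairs, windowed (NaN
    when no window is given).
    """
    code = standard_code(table_id)
    if families is None:
        families = partition_families(code)
    clean = [v for v in (validate_and_trim(r, code) for r in records) if v.valid]
    rows = []
    for fam in sorted(families, key=lambda f: f.name):
        streams = [family_stream(r, fam) for r in clean]
        profile = class_profile(clean, fam)
        row = {"family": fam.name, "class_total_N": profile.N}
        for strat in ("consecutive", "all_pairs"):
            row[strat] = count_pairs(streams, fam, strategy=strat).n_pairs
        row["windowed"] = (
            count_pairs(streams, fam, strategy="windowed", window=window).n_pairs
            if window is not None
            else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def render_family_blocks(table: DeviationTable) -> str:
    """Render one family as four aligned blocks: co-occurrence counts,
    expected counts (rounded for display), percent deviation (3 decimals),
    and empirical quantiles."""
    k = len(table.codons)
    lines = [f"## {table.family}  (strategy={table.strategy}, "
             f"normalization={table.normalization}, N_used={table.n_used:.0f}, "
             f"n_pairs={table.n_pairs})"]

    def block(title: str, fmt, matrix: np.ndarray) -> List[str]:
        out = [f"# {title}", "codon\t" + "\t".join(table.codons)]
        for i, ci in enumerate(table.codons):
            cells = [fmt(matrix[i, j]) for j in range(k)]
            out.append(ci + "\t" + "\t".join(cells))
        return out

    def f_int(v):
        return "NA" if np.isnan(v) else str(int(round(v)))

    def f_3(v):
        return "NA" if np.isnan(v) else f"{v:.3f}"

    lines += block("co-occurrence counts", f_int, table.matrix("count"))
    lines += block("expected counts", f_int, table.matrix("expected"))
    lines += block("percent deviation from expected", f_3, table.matrix("pct_dev"))
    lines += block("empirical quantile (aa.norm.sim)", f_3, table.matrix("quantile"))
    return "\n".join(lines) + "\n"


def write_outputs(result: AnalysisResult, out_dir: str | Path) -> None:
    """Write per-family block files, the combined long table, per-strategy
    block totals and the run log under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = "\n".join(result.config.header_lines()) + "\n"

    combined = result.combined()
    with open(out / "pairs_long.tsv", "w") as fh:
        fh.write(header)
        combined.to_csv(fh, sep="\t", index=False, float_format="%.6g", na_rep="NA")

    for name, table in sorted(result.tables.items()):
        with open(out / f"{name}_blocks.tsv", "w") as fh:
            fh.write(header)
            fh.write(render_family_blocks(table))

    totals = pd.DataFrame(
        [
            {
                "family": name,
                "class_total_N": result.profiles[name].N,
                "strategy": pt.strategy,
                "n_pairs": pt.n_pairs,
            }
            for name, pt in sorted(result.pair_tables.items())
        ]
    )
    with open(out / "block_totals.tsv", "w") as fh:
        fh.write(header)
        totals.to_csv(fh, sep="\t", index=False)

    with open(out / "run_log.txt", "w") as fh:
        fh.write(header)
        fh.write(f"records_in={result.n_records_in}\n")
        fh.write(f"records_valid={result.n_records_valid}\n")
        fh.write(f"records_skipped={len(result.skipped)}\n")
        for line in result.skipped:
            fh.write(f"skipped\t{line}\n")
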