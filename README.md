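# codonreuse

Genome-scale analysis of **consecutive synonymous-codon pairing bias** — the
tendency, within a gene, for a codon to be followed by a synonymous codon
that can be decoded by the same tRNA isoacceptor ("co-tRNA codon pairing").
A positive diagonal bias in the ordered codon-pair matrix of a synonymous
family is the genomic signature expected if deacylated tRNAs are recharged
near the ribosome and reused at the next occurrence of the same amino acid,
rather than diffusing back into the cytoplasmic pool.

The package is written for sequence analysts studying translational
efficiency in archaea and bacteria. It takes an annotated genome (GenBank
flat file) or a CDS FASTA, and for every synonymous family (six-fold
families split by degeneracy rules into quartet + doublet blocks, e.g.
Ser4 = UCN and Ser2 = AGY) computes:

- **co-occurrence counts** `C_ij`: ordered pairs in which codon *i* is
  followed by codon *j* of the same block within one gene, under a
  configurable pairing rule (consecutive / all pairs / windowed);
- **expected counts** `E_ij = N·f_i·f_j` under positional independence,
  with `f` the block's codon frequencies and `N` either the block's
  occurrence total (the historical definition) or the pair total
  (properly normalised for calibration);
- three deviation statistics per pair:
  - percent deviation `100·(C−E)/E` (positive on the diagonal ⇒ reuse),
  - binomial z `(C−E)/√(N·p·(1−p))` with `p = f_i·f_j`,
  - log2 enrichment `log2(P(pair)/(f_i·f_j))` ("aa.log2.norm");
- a **Monte-Carlo empirical null** for the log2 enrichment: B random codon
  sequences of L residues (default 5000 × 1000) drawn iid at the block's
  frequencies; each observed value is reported as its quantile in the null
  ("aa.norm.sim"), and positive deviations above a quantile threshold
  (default 0.95) are flagged.

A synthetic-genome generator with a tunable tRNA-reuse probability ρ
(first-order reuse process over each family's occurrence stream) provides
ground truth: in identical-reuse mode the diagonal enrichment has the
closed form `pct_ii = 100·ρ·(1−f_i)/f_i`, which the pipeline recovers.

A reference table of published Ser/Arg codon-pair counts for the
*Methanothermobacter thermautotrophicus* deltaH genome (NC_000916.1) ships
with the package (`codonreuse.reference`) so the statistics can be
exercised without downloading the genome.

## A known limitation: raw block totals are pairing-rule dependent

The published *M. thermautotrophicus* Ser/Arg table cannot be used to pin
down the counting rule that produced it: its Ser2 counts block sums to
**3057** tabulated pairs while its expected block sums to the class total
of **2729** codon occurrences — more pairs than occurrences is impossible
under consecutive next-occurrence pairing, so the original pairing rule is
under-specified. Raw co-occurrence counts are therefore **not** a
reproduction surface. The pipeline instead (a) implements all three
pairing strategies explicitly, (b) reports each strategy's block totals
side by side (`strategy_block_totals.tsv`) for any genome the user
supplies, and (c) guarantees the *percent-deviation arithmetic*, which is
independent of the counting rule: feeding the published counts and
expected counts through `percent_deviation` reproduces the published
percentages to three decimals.

## Worked example

Simulate a genome with 20 % tRNA reuse, then analyze it:

```bash
codonreuse simulate --n-genes 200 --gene-length 300 --rho 0.2 --seed 7 --out sim/
codonreuse analyze sim/genome.fasta --normalization pairs --null-reps 200 --seed 3 --out results/
```

`results/Val4_blocks.tsv` then contains four aligned blocks (counts,
expected, percent deviation, quantiles). For the valine family the percent
deviation block reads (one analysis of the command above):

```
codon   GTA      GTC      GTG      GTT
GTA     56.888   -20.608  -15.673  -22.812
GTC     -12.083  61.238   -26.605  -18.372
GTG     -19.485  -20.314  52.811   -14.192
GTT     -24.816  -16.718  -17.644  58.759
```

The diagonal sits near the analytic value `100·0.2·0.75/0.25 = 60`:
identical codon pairs occur ~60 % more often than expected under
independence, while every off-diagonal pair is depleted by ~20 %
(`= −100·ρ`). All four diagonal cells carry empirical quantile 1.000 and
are flagged significant; estimating `ρ̂ = (pct/100)·f/(1−f)` per codon
recovers the simulated reuse probability. On a real genome the same
diagonal structure in, e.g., the Ser4 and Arg4 blocks is the co-tRNA
pairing signal.

`pairs_long.tsv` holds the same information in long format
(family, codon_i, codon_j, count, expected, pct_dev, z, log2norm,
quantile, significant), and every output file echoes the full run
configuration and seed in its header.

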