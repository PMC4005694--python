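# Methods

## The statistic and its model

For one synonymous family (degeneracy block) with codons `1..k`, codon
frequencies `f_i = n_i / N` (N = class occurrence total over all valid
coding sequences), the pipeline tabulates ordered pair counts `C_ij` over
per-gene occurrence streams and compares them with the independence model

    E_ij = N_used · f_i · f_j .

Positional independence is the null: successive synonymous choices within
a gene carry no memory. tRNA reuse predicts an excess of pairs decodable
by the same isoacceptor — on the diagonal, and between co-tRNA codons.

Three per-pair statistics quantify the deviation:

1. **percent deviation** `100·(C_ij − E_ij)/E_ij` — scale-free, sign gives
   the direction; undefined cells (E = 0) render as NA, never 0.
2. **binomial z** `(C_ij − E_ij)/√(N_used·p·(1−p))`, `p = f_i f_j` —
   deviation in SD units if each of `N_used` trials produced pair (i,j)
   with probability p. Because √(Np(1−p))/Np → 0 as N grows, z magnifies
   small relative deviations at genome scale; it is reported, not used for
   flagging.
3. **log2 enrichment** `log2( ((C+a)/(n_pairs+a·k²)) / (f_i f_j) )` with
   pseudocount `a` (default 0.5; a = 0 gives the bare joint/marginal
   ratio, and then equals `log2(1 + pct/100)` exactly under the pair-total
   normalisation — a tested identity).

### Normalisation: class total vs pair total

`N_used` defaults to the class occurrence total N (the historical
definition of the expected table). That choice does not make sum(E) equal
the number of counted pairs, so a `pair_total` mode (`N_used = n_pairs`)
is provided and used wherever calibration matters (the reuse-recovery
closed form, the z sanity checks). Both are recorded in output metadata.

### Pairing strategies

Occurrence streams are per gene and per block; gene boundaries are never
crossed (reuse is a per-transcript hypothesis). Strategies:

- `consecutive` (default): occurrence t with t+1 — the minimal reading of
  "next occurrence of the same amino acid";
- `all_pairs`: every ordered (s, t), s < t, within a gene;
- `windowed`: ordered pairs with codon-index distance ≤ W.

All three exist because published genome tables of this kind do not
uniquely determine the rule (see README): the Ser2 counts block of the
shipped reference table sums to 3057 pairs against a class total of 2729.
Percent-deviation arithmetic is unaffected by the choice; raw totals are
reported per strategy.

The default pairing **scope** is the degeneracy block (Ser4 and Ser2
streams are independent), matching how the reference table normalises each
block by its own class total. A sensitivity mode (`--scope amino-acid`)
builds one stream per amino acid — intervening codons of the sibling block
then break/extend adjacency — and tabulates within-block pairs from it.

## Empirical null and significance

For each family, B replicate sequences of L codon draws (iid at the
family's frequencies) are generated; adjacent ordered pairs within a
replicate (n_pairs = L − 1) give one log2-enrichment value per pair per
replicate. Defaults B = 5000, L = 1000 for analysis; tests use B = 500.
The observed quantile is `(# null ≤ observed)/B` (weak inequality, ties
counted); `significant = (quantile ≥ q) AND (pct > 0)` with q default
0.95 — only the reuse direction is flagged, and no multiple-testing
correction is applied (significance is the empirical-quantile flag only).

Two deliberate properties of this construction:

- The null is built from *generated sequences at fixed L*, not from
  resampled genes, so its dispersion reflects L — typically wider than the
  genome's (which has more pairs). Observed quantiles on a large genome
  are therefore under-dispersed relative to Uniform(0,1) and the
  threshold-q flagging is conservative: the type-I check is an upper
  bound (flagged fraction ≤ (1−q) + 3·binomial SE), not an equality.
- Calibration proper is checked by a probability-integral-transform test:
  probe replicates drawn from the same iid process, located in the null,
  must give quantiles uniform on [0,1] (KS < 0.05, 200 probe replicates
  pooled over a 4-codon family's 16 pair cells; pooling is needed because
  a 200-value KS has sampling noise ≈ 0.06 on its own).

## Synthetic-genome generator

Each gene is a sequence of family draws from a background composition
(default: uniform over the 18 amino acids with degeneracy ≥ 2, split
equally between the quartet and doublet blocks of six-fold amino acids).
Within a gene, a family's first occurrence draws its codon from f; each
later occurrence *reuses* with probability ρ — the previous codon
verbatim (`identical`) or a uniform draw from the previous codon's
co-tRNA group (`cotrna`) — else draws fresh from f. ATG is prepended and
TAA appended, so the output is valid pipeline input.

In identical mode the per-family codon chain has transition
`P(i→i) = ρ + (1−ρ)f_i` and stationary distribution f, giving

    pct_ii = 100·ρ·(1−f_i)/f_i      (consecutive pairing, pair_total),

the test oracle (`analytic_diagonal_pct`), invertible as
`ρ̂ = (pct/100)·f_i/(1−f_i)`. The chain's lag-m autocorrelation ρ^m
inflates the sampling variance of realized codon frequencies by
(1+ρ)/(1−ρ); the marginal-preservation test uses that corrected SE.

What the generator does **not** emulate: GC-content and expression-level
gradients across genes, amino-acid composition of real proteomes (unless
configured), codon-context effects spanning families, and length/abundance
correlations. Passing calibration and recovery tests therefore shows the
statistics are correct under the stated reuse model, not that a real
genome's bias must arise from tRNA reuse — on real data the empirical
null is what guards against frequency-composition artifacts.

## Genome parsing and hygiene

GenBank CDS features are resolved to mRNA sense (reverse-complement,
join-splicing) before codon splitting; partial and pseudo features are
excluded by default (toggles exist; the convention for the source study
is unrecorded, so both default to "exclude"). Records whose length is not
a multiple of 3 are skipped with a warning, never fatal. A codon with any
non-ACGT base is masked in place — excluded from counts but preserving the
occurrence order of its neighbours. Terminal stops are trimmed; an
internal stop invalidates the record (`reason=internal_stop`). The
genetic code is NCBI table 11 (identical partition to table 1).

## Isoacceptor configuration

Co-tRNA groups partition each block by decoding anticodon. Wobble
decoding depends on base modifications that cannot be inferred from
sequence, so the inventory is a plain-text config
(`anticodon TAB copies TAB codons`). The shipped default for
*M. thermautotrophicus* uses the annotated Ser/Arg anticodons (GGA ×2,
TGA, GCT; GCG, TCG, CCT, TCT) and a generic archaeal layout elsewhere
(G34 reads NNC/NNU, T34 reads NNA/NNG, C34 reads NNG, a dedicated
one-codon reader for Ile AUA). Where a codon has several decoders, its
primary is the exact Watson–Crick wobble match (hence Arg2 splits into
{AGG} and {AGA} when both CCT and TCT exist). For four-fold blocks with
two isoacceptors the default assigns NNC/NNU to the G34 reader and
NNA/NNG to the T34 reader (e.g. Arg4: CGC/CGU → GCG, CGA/CGG → TCG);
this is configuration, not an assertion about modified-base decoding.

## Numerical choices and problem sizes

- Expected counts are kept real-valued internally; block renderings round
  to integers for display, percent deviations print to 3 decimals.
- Pseudocount 0.5 guards zero counts in the log2 enrichment on both the
  observed and null sides (same value on both, keeping them comparable).
- All randomness flows from one seed, split per family via
  `numpy.random.SeedSequence.spawn`, so runs are byte-reproducible.
- Test problem sizes: counting oracles use 200 random genomes of ≤ 20
  genes × ≤ 50 codons; null calibration a ρ=0 genome of 2000 × 300 codons
  at B = 500; reuse recovery 2000 genes × 60 codons of a single uniform
  4-codon family (1.2 × 10⁵ class occurrences), recovering ρ within
  ±0.03. These sizes make every check a few seconds while keeping Monte
  Carlo standard errors well inside the asserted tolerances.

## Known limitations

- The binomial z treats pairs as independent trials; overlapping adjacent
  pairs make its variance deviate mildly from 1 (measured ≈ 0.95 under
  the no-reuse model), and estimating f from the same data shrinks it
  further — which is why flagging uses the empirical quantile, not z.
- Separation-distance profiles (autocorrelation vs codon distance) and
  cross-gene pairing are out of scope by design.
- The shipped reference table transcribes its source verbatim, including
  one internally inconsistent Arg2 cell (AGA–AGA count 1346 vs expected
  1092 does not match the published 2.326 %); tests assert only
  arithmetically consistent cells.
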