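# Methods

This note documents the model implemented by `createscan`, the defaults it
ships with, and the numerical and design choices behind them. Every number
quoted here is computed by the test suite or by `scripts/acceptance.py`;
nothing is an empirical claim about real experiments.

## Cassette design

A design targets one codon of one gene and is realized as a 230-nt cassette:

```
[18 nt subpool primer][12 nt variant primer][118 nt homology arm]
[35 nt J23119 promoter][ATC][20 nt spacer][24 nt scaffold 5' fragment]
```

The homology arm covers 58 nt upstream of the edited codon, the 3-nt codon
itself, and 57 nt downstream, so the arm both templates the edit and serves
as the mapping anchor for barcode quantification.

**Site saturation.** Each selected residue yields exactly 20 designs: the 19
missense substitutions, each using a curated preferred codon per amino acid,
plus one synonymous design that swaps the wild-type codon for its
highest-ranked synonymous alternative. Methionine and tryptophan sites are
rejected (single-codon amino acids admit no synonymous control); the
simulator never selects them. The canonical library size is therefore
`20 × n_sites` (e.g. 815 sites → 16,300 designs).

**Spacer choice.** The protospacer is the 20-mer adjacent to the NGG PAM
nearest the edited codon, searched on both strands (a minus-strand PAM is a
`CC` on the plus strand). Distance is the gap between the codon interval and
the PAM interval; ties prefer the plus strand, then the smaller coordinate.

**PAM disruption.** The repair template must not be re-cut, so the arm
carries a second, silent change: preferably a synonymous substitution that
destroys an essential PAM guanine (third codon positions tried first),
otherwise a synonymous change inside the 10-nt seed region. Both tiers are
constrained to fall inside the homology arm and outside the edited codon;
if neither tier succeeds the design fails loudly rather than silently
emitting a re-cuttable cassette.

## Barcode quantification

Reads are aligned to the cassette database with infix (semi-global)
edit-distance alignment (edlib, `HW` mode), so truncated reads can still be
recognized. Two thresholds apply:

- **Reported** hit: ≥95% identity over ≥150 alignment columns (identity =
  match columns / all alignment columns, from the extended CIGAR). Up to 40
  candidate hits are retained per read.
- **Counted** hit: the alignment must additionally span the full 230-nt
  cassette and exceed 99% identity (strict), i.e. at most two errors.

Exact matches short-circuit through a hash lookup. Identity ties are broken
lexicographically by design id so counting is deterministic. The distinction
between reported and counted hits is kept because diagnostic mapping rates
and quantitative counts have different tolerance for partial or noisy reads.

## Enrichment statistics

For design *i* in replicate *r*,

```
W_ir = log2( (c_post / T_post) / (c_pre / T_pre) )
```

with totals taken over the whole sample. A zero post-selection count is
floored at 0.5 (a score is still informative as an upper bound on depletion);
a pre-selection count below 10 masks that replicate (the ratio is too noisy),
with exactly 10 retained. Replicates are combined by a count-weighted
average, weighting by pre-selection counts by default (the pre counts set
the sampling noise of the ratio).

The null distribution is estimated from the synonymous designs of the same
condition: `mu` and `sigma` (ddof = 1) of their weighted scores, with a
B = 20,000 nonparametric bootstrap for the 95% CI of `mu`. A design is
**enriched** iff `W ≥ mu + 2 sigma` (inclusive) and **depleted**
symmetrically; the reported p-value is the normal upper tail. An empirical
alternative for condition-level p-values uses `(1 + #{scores > w}) / (n + 1)`,
which is strictly positive and attains `1/(n+1)` at the maximum.

## Genomic validation

Editing is confirmed independently of the barcodes by amplicon sequencing of
a genomic window. The expected-variant database holds the wild-type window
plus, per design, the window with the codon edit and its PAM-disrupting
change applied. Matching is exact (100% identity over the full window);
wrong-length reads are skipped with a warning. Reported quantities:

- `fraction covered = round(100 × variants observed / designs in window, 1)`
- `Eff = 100 × (edited reads / total reads) / (w / library size)`, the
  per-cell editing efficiency under uniform cassette representation, where
  `w` is the number of designs in the window.

## Generative model

The simulator is the ground truth the statistics are tested against. Its
defaults are the study conditions, not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| `epsilon` (editing efficiency) | 0.03 | realistic single-step recombineering efficiency |
| `escaper_fitness` | 0.0 | unedited cells that survive cutting grow like wild type |
| `generations` | 10 | a typical overnight selection |
| `n_replicates` | 2 | minimal replication used throughout |
| `depth_pre` / `depth_post` | 200,000 | comfortable counts for a 1,000-design library |
| `error_rate` | 0.0 | sequencing errors off unless studied explicitly |

Growth is deterministic and exponential: a cassette's cell pool splits into
an edited fraction `epsilon` growing as `(1+s)^g` and an escaper fraction
`1 − epsilon` growing as `(1+s_esc)^g`. Synonymous designs always have
`s = 0` unless explicitly overridden. Stochasticity enters only at
sequencing, as a multinomial draw over expected relative abundances; genomic
window reads are drawn pre-selection, where each variant has probability
`epsilon / N`. Sequencing errors, when enabled, are substitution-only. All
randomness flows through `numpy.random.default_rng([seed, stream])` with a
distinct stream per consumer, so runs are byte-reproducible and replicates
are independent.

**What the generator does not emulate:** growth-phase stochasticity
(drift/bottlenecks), cassette-specific editing efficiency, recombination
between cassettes, indel sequencing errors, PCR jackpotting, and
double-edits. These are deliberate: a deterministic growth phase makes
closed-form expectations exact, which is what lets the test suite verify the
statistics analytically.

**Calibrated winners.** `required_growth(target, n, epsilon, e)` inverts the
model: it returns the edited-pool growth `x` such that a single beneficial
design reaches `target` log2 enrichment relative to `n − 1` neutral designs,
accounting for the escaper background `e`. This gives the recovery tests an
exact target instead of a tuned threshold.

**Escaper masking.** Because every cassette carries a `(1 − epsilon)`
escaper background growing at wild-type rate, barcode enrichment is bounded:
as `epsilon → 0` the signal of a beneficial edit collapses toward the
escaper baseline, and depletion can never fall below the escaper floor
`(1 − epsilon) · x_esc` — at `epsilon = 0.03`, even a lethal edit depletes
its barcode by only ~4%. The suite checks this masking is monotone in
`epsilon`, and tests of sign recovery for deleterious designs use a fully
edited (`epsilon = 1`) regime where the bound is absent. This is a real
property of escaper-contaminated selections, not a simulator artifact.

## Numerical choices

- Alignment identity is computed from extended-CIGAR match columns, not from
  edit distance, so the reported/counted thresholds are exact column ratios.
- The bootstrap is vectorized (one `B × n` index matrix) — 20,000 resamples
  on a few hundred synonymous scores cost milliseconds.
- Derived seeds are kept below 2^31.
- The test suite checks enrichment arithmetic to 1e-9 and simulator
  neutrality to relative 1e-12; alignment assignments are checked exactly
  against an independent dynamic-programming oracle, identities to 1e-3
  (equal-cost alignment paths can shift column counts by one).

## Scope and layout

The repository is an analysis project: the library lives in
`src/createscan/`, and the numbered scripts under `analysis/` are the
narrative interface — design, simulate, score, validate, calibrate — each a
thin driver writing tables to `results/`. There is no CLI entry point; the
scripts are the intended command-line surface, and the Python API is the
programmatic one. Problem sizes used throughout: a 1,000-design, 5-gene
preset for the full pipeline; a 120-design neutral preset (200 runs) for
calibration; a 100-design two-gene library for worked examples.

## Limitations

- The synonymous null assumes synonymous edits are phenotypically silent;
  codon-usage fitness effects would bias `mu`.
- The normal-tail p-value is a convenience; with few synonymous designs the
  empirical variant is safer.
- Exact-match genomic validation undercounts edits in noisy reads; it is
  meant for high-accuracy amplicon data.
- Enrichment magnitudes are only interpretable relative to the synonymous
  null, and under low editing efficiency they compress toward the escaper
  baseline (see escaper masking above).
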