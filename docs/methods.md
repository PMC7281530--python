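# Methods

`poolscreen` implements the desk side of a pooled shRNA drop-out
(viability) screen together with the dose–response and drug-combination
analyses such a screen feeds into. This note documents the models, the
defaults and why they were chosen, the numerical details, and what the
synthetic-data generator does and does not emulate.

## The screen model

A pooled screen starts from a library of hairpins (here modelled on a
boutique library of 4020 hairpins targeting 1677 genes, ~2.4 hairpins per
gene), each a unique fixed-length nucleotide sequence silencing one gene.
Cells carrying the library are grown for weeks with or without drug at a
sub-lethal dose (EC10); hairpins whose knockdown removes drug resistance
("rescuer" genes) lose representation under treatment. Representation is
read out by amplicon sequencing: each read spans one PCR amplicon of
constant structure — 53 nt forward primer, 513 nt vector insert carrying
the hairpin, 68 nt reverse segment whose 3' end holds a 30 nt adaptor and
a 9 nt sample barcode — 634 nt in total. Because the structure is
constant, the hairpin and barcode occupy fixed windows in every read, and
counting reduces to window extraction plus exact/Hamming matching. No
alignment is performed; ties at the best Hamming distance are reported as
ambiguous rather than assigned, and every read lands in exactly one fate
category (assigned, no-barcode, no-hairpin, ambiguous), so counts are
conservative and auditable.

Defaults: barcode matching tolerates 1 mismatch (barcodes are required to
be pairwise more than 2 mismatches apart, so assignment is unambiguous),
hairpin matching tolerates 2. These are package decisions — the counting
procedure of the original screen is not public — chosen so that an
Ion-Torrent-like per-base substitution rate of ~0.3–1% rarely costs a
read while random 22-mers essentially never collide within distance 2.

## Representation sampling simulation

Passaging samples a finite number of cells from the pool. One passage is
modelled as a multinomial draw of `n_draws` cells (default 10^6) from the
abundance profile; replicated draws give a per-hairpin mean, SD, and
coefficient of variation. For a hairpin at probability `p` the binomial
closed form is `CV = sqrt((1-p)/(n p))`: at uniform abundance
(p = 1/4020, n = 10^6, mean ≈ 249) this is ≈ 0.063, and the per-hairpin
probability of missing a replicate entirely is ~exp(-249) — the
quantitative basis for treating 10^6 cells as preserving representation.
Sampling is with replacement (the pool is much larger than the sample);
a hypergeometric refinement would change nothing at these ratios. The
relative-error metric is the CV of counts across replicates.

## Hit calling

Counts are normalised to reads per million (CPM). Hairpins whose mean raw
count across untreated control replicates is not above 100 are excluded
before testing (`filtered`) — strict inequality on the control mean, the
least brittle reading of a ">100 in controls" rule. Hairpins passing the
filter whose raw treated counts are all zero are `lost` (complete
drop-out), detected before any ratio so they are never diluted into the
fold-change rule. Remaining hairpins get:

- a two-sided two-sample t-test, treated vs control replicates, on
  `log2(CPM + pseudocount)` (pseudocount 0.5). Testing on the log scale is
  the standard treatment for count data whose replicate noise is
  multiplicative; it keeps the null calibrated at the nominal 1% with
  triplicates and gives near-complete power at 8-fold effects, where a
  raw-scale t-test loses both calibration margin and ~6–8% power to
  skew. Classical equal-variance Student's t is the default (`equal_var`
  exposes Welch); `log_scale=False` exposes the raw-CPM test.
- `log2_ratio = log2((mean_t + 0.5)/(mean_c + 0.5))` on CPM means.

`depleted`/`enriched` calls require |log2 ratio| ≥ 1 (two-fold) **and**
raw p < 0.01, applied symmetrically. Benjamini–Hochberg adjusted p-values
are reported for all kept hairpins but do not gate the primary-hit call.
Classification is a partition: every library hairpin receives exactly one
of {depleted, enriched, lost, unchanged, filtered}. Degenerate rows with
zero variance in both arms resolve to p = 1 when means agree (no evidence
of change) and p → 0 when they differ exactly.

Cross-drug overlap intersects hit sets of one class across contrasts at
two levels: hairpin IDs, and gene symbols (a gene counts for a contrast
as soon as one of its hairpins is a hit there, so a gene can be shared
across drugs through different hairpins — the relevant notion for
rescuer-gene overlap).

## Dose–response and EC_x

Monotherapy curves use the four-parameter Hill model
`y(d) = emin + (emax - emin) d^h / (ec50^h + d^h)` with inhibition
fractions in [0, 1], fitted by bounded least squares with `ec50`
parameterised in log space (tolerances 1e-12, so noiseless curves are
recovered to ~1e-7). Responses spanning less than 2 percentage points are
flagged flat rather than fitted. EC_x is the closed-form inversion
`ec_x = ec50 ((f/(1-f))^(1/h)`, `f = (x/100 - emin)/(emax - emin)`,
defined only for emin < x/100 < emax.

## ZIP synergy scoring

The zero-interaction-potency null for two drugs is probabilistic
independence, `y_AB = y_A + y_B - y_A y_B`, evaluated on the monotherapy
Hill fits from the zero-dose margins. The observed combination response
at each dose pair is smoothed by conditional potency-shifted curves: for
each fixed dose of drug B, the response along drug A's doses is fitted
with a log-logistic family `(b + E t)/(1 + t)`, `t = (d/m)^h`,
initialised at the ZIP potency shift (baseline b at drug B's monotherapy
effect, E at 1) but with both ends estimated. Fitting the ends matters: a
family with pinned asymptotes cannot represent a uniform departure from
independence, so a genuine constant synergy offset would be partially
absorbed by the smoothing instead of reported (a planted 10-point offset
scores ~8 with pinned ends and 10.0 with estimated ends, and the
invariance "adding c points to every combination cell shifts the overall
score by c" only holds with estimated ends). The ZIP delta in each cell
is `100 × (mean of the two conditional fits − independence expectation)`,
in percentage points; a failed conditional fit falls back to the raw
observed value (logged).

Summary scores: **overall** = mean delta over all combination cells;
**MSA** (most synergistic area) = maximum mean delta over all contiguous
dose windows with both sides ≥ 3 cells, the full surface included. A
fixed 3×3 window is the usual convention and is the maximiser on typical
hot-spot surfaces, but a fixed window does not guarantee MSA ≥ overall on
arbitrary surfaces (window averages under-weight corner cells); including
all ≥3×3 windows restores that guarantee exactly.

Inhibition is defined as `1 - viability/vehicle`; raw fluorescence
imports convert as `(value - blank)/(vehicle - blank)`, and values
outside [0, 1] are clipped with a logged count.

## Synthetic data: what it emulates, and what it does not

The generator produces every pipeline input with known ground truth:

- **Library**: unique random ACGT sequences (default 22 nt), one or more
  hairpins per gene with extra hairpins spread multinomially (defaults
  4020 hairpins / 1677 genes).
- **Abundance**: log-normal skew (log-sd `dispersion`, default 1.0;
  0 = uniform). The real library's abundance distribution is not public;
  log-normal is a one-parameter heavy-tailed stand-in, not measured data.
- **Reads**: full-length 634-nt single-end amplicons, hairpin at a fixed
  insert offset, barcode at the 3' end, i.i.d. substitution errors only,
  constant quality strings. The exact per-hairpin multinomial tally is
  returned with the FASTQ, so counting is tested against ground truth
  rather than re-inferred. Not modelled: indels (the dominant Ion Torrent
  error mode), PCR amplification bias, duplicates, quality variation.
- **Screen counts**: per replicate, expected count = depth × abundance,
  modulated by a per-hairpin log-normal factor with CV `replicate_cv`
  (default 0.2 — a realistic biological+technical replicate CV for a
  6-week pooled culture) and observed as Poisson. Planted effects
  multiply abundance (depletion/enrichment) or zero it (lost).
- **Dose matrices**: independence surface of two Hill curves plus a
  constant interaction offset `delta` on combination cells, plus optional
  Gaussian noise, clipped to [0, 1]. `delta=0` is an exact ZIP-null.

Passing recovery tests on these data therefore demonstrates correctness
of the computations under multiplicative-noise, substitution-error,
constant-offset-interaction conditions; it does not demonstrate
robustness to indels, PCR jackpotting, growth competition between clones,
or dose-dependent interaction shapes, none of which the generator
produces.

## Problem sizes in tests and the acceptance script

Recovery runs use a 2000-hairpin/1000-gene library at depth 10^6 with
triplicate arms (50 replicate screens for calibration numbers), the
counting oracle uses 10^5 reads on a 500-hairpin library, and the
representation simulation uses the full 4020-hairpin pool at 10^6 draws ×
100 replicates — sizes at which every Monte-Carlo quantity reported is
stable to well within the tolerances checked.

## Known limitations

- The counting step assumes structurally intact reads; reads shorter than
  the amplicon are reported unassigned rather than rescued by partial
  matching.
- Equal-variance Student's t with n = 3 per arm is calibrated under the
  generator's noise; strongly heteroscedastic real data would warrant the
  Welch option.
- Gene-level inference is by set intersection only; no gene-level
  aggregation statistic (rank aggregation etc.) is provided.
- ZIP scores depend on adequate monotherapy margins; matrices without a
  zero-dose row/column are rejected rather than imputed.
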