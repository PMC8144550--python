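# Methods

## Setting and model

`ampedit` analyzes comparative genome-editing experiments: a treatment
sample (Tx, nuclease delivered) and a mock sample (M, no nuclease) are
amplified with the same multiplex PCR panel — one primer pair per
interrogated locus — and sequenced identically. Because sequencing and
process errors (polymerase slippage, base damage, mis-assignment,
ambiguous alignment) affect both samples the same way, the mock sample is
a matched noise control, and editing can be separated from noise
statistically rather than by background subtraction.

For each locus, reads are assigned by primer matching, globally aligned to
the reference amplicon, and every indel is binned into a cell
(τ, i) — indel type τ (deletion/insertion × length class) at reference
position i. Only a window around the expected cut-site is classified
(default: cut ± 10, i.e. a 20-bp window); a blunt SpCas9 break is assumed
3 bp 5′ of the NGG PAM.

With n_Tx and n_M the Tx/M read counts in a cell and N_Tx, N_M the
per-locus totals, each cell is labeled by a MAP comparison of two
generative models:

* **no edit**: indels arise identically in both samples, so
  n_Tx | no-edit ~ Hypergeometric(N = N_Tx + N_M, B = n_Tx + n_M, n = N_Tx);
* **edit**: events at an edited cell come almost surely from treatment,
  n_Tx | edit ~ Binomial(n_Tx + n_M, q) with q near 1.

The cell is an edit when
P(edit)·P(n_Tx, n_M | edit) > P(no edit)·P(n_Tx, n_M | no edit).
All likelihoods are evaluated in log space through scipy's log-gamma-based
pmfs; exact posterior ties resolve to noise (conservative), and cells with
n_Tx = 0 short-circuit to noise.

**Prior ladder.** P(edit) = 0.5 at the cut-site; at distance d ≥ 1 it
decays log-linearly from 10⁻¹ (d = 1) to 10⁻⁴ (window edge). The
interpolation between those endpoints was an open choice; log-linear was
chosen so every step multiplies the prior odds by a constant factor. The
non-zero off-cut priors are what allow alternative cut-sites (alternative
PAM, shifted alignment) to be detected. A per-position override vector is
accepted and validated against the window length.

**q estimation.** q is the pooled fraction Σn_Tx / Σ(n_Tx + n_M) over
well-supported cells (n_Tx + n_M ≥ 50) within ±2 of the on-target
cut-sites, clamped to [0.90, 0.999]; with no qualifying cell the default
0.95 is used. The ±2 tolerance exists because deletions longer than 1 bp
legitimately start 1–2 bp 5′ of the break. The clamp keeps the edit model
strictly informative and the likelihoods finite; results are insensitive
to q within the clamp range because the two models differ by orders of
magnitude wherever the decision matters.

**Quantification.** A Tx read is edited when it carries ≥ 1 event in an
edit-labeled cell; mock counts are never subtracted. Activity is
edited / N_Tx with a Wald interval
p̂ ± z_{1−α/2}·√(p̂(1−p̂)/N_Tx), clamped to [0, 1], no continuity
correction (α = 0.05 default). A site is *active* at activity ≥ 0.1%
(configurable). The concordance test takes (weaker, stronger) activity
pairs across experimental conditions and computes the exact upper tail of
Binomial(n, 0.5) on the number of monotone pairs; ties count as
concordant (a tie is not evidence against monotonicity).

**Translocations.** Reads whose two ends match primers of different loci
are fusion candidates. Four end configurations exist (F–R in either role
order, F–F head-to-head, R–R tail-to-tail); all four and their
reverse-complements are recognized. For each candidate the putative
fusion amplicon is built by joining the two loci bluntly at their expected
cut indices (segments reverse-complemented as the configuration requires),
and the candidate is retained when it aligns to it semi-globally with
identity ≥ 0.85 and length ≥ 0.8 of the fusion amplicon — tolerances that
absorb junctional resection. Retained counts per unordered pair, C_Tx and
C_M, feed an upper-tail hypergeometric test with b = C_Tx,
B = C_Tx + C_M, n = round(√(N_Tx(λ₁)·N_Tx(λ₂))) and
N = n + round(√(N_M(λ₁)·N_M(λ₂))) (geometric means make the test
symmetric in the pair; rounding to integers and clamping B ≤ N handle
degenerate small depths). p-values over all tested pairs are
Benjamini–Hochberg corrected (threshold 0.05). By default only pairs of
*active* sites are tested; `all_pairs` overrides this for spike-in-style
analyses. Candidate types are collapsed to unordered pairs for testing;
per-type reporting is out of scope.

## Alignment

Needleman–Wunsch with affine gaps (match +5, mismatch −4, gap open −20,
extend −1; Gotoh recurrences, row-vectorized in numpy). The strong open
penalty consolidates nearby gap columns into single events, matching the
per-event typing. Exact scoring values are a package choice; they are
configurable.

Indel placement is often ambiguous (any repeat context spanning the cut
admits several co-optimal alignments). Since the biological prior is a
break at the cut-site, each gap run is slid among its score-neutral
placements to the position nearest the cut index, ties leftmost. Sliding
moves the flanking aligned base across the run only when the substitution
score is unchanged, so the reported alignment always attains the optimal
DP score (property-tested against an independent plain implementation,
and against exhaustive enumeration of co-optimal paths on homopolymer
instances).

Event typing uses exact lengths 1–29 plus a pooled ≥ 30 class.
Substitution columns are never editing evidence; they are counted for
diagnostics only. A read may contribute to several cells (one complex
event = one deletion + one insertion call) but at most once per cell.

## Demultiplexing and preprocessing

Primer matching is Levenshtein distance (edlib, prefix mode) of each
primer against the read's 5′ end and against the 5′ end of its
reverse-complement; the distance cap defaults to ⌊primer length / 4⌋
(tolerates 1–2 sequencing errors on a 20–30-nt primer, with a 4-nt window
slack). Same-site F/R pair within the cap ⇒ assigned (and
reverse-complement reads are flipped to forward orientation); cross-site
or same-end pair ⇒ translocation candidate; anything else, including tied
best matches, is discarded — a conservative policy, since a mis-assigned
read would only enter the noise model. Assignment depends on the sequence
alone and is cached per unique sequence.

The built-in preprocessor merges read pairs by best ungapped overlap
(≥ 10 nt, mismatch fraction ≤ 0.2, quality-weighted consensus) and drops
reads with mean Phred < 30. Adapter trimming is not performed; amplicon
reads are primer-delimited and externally preprocessed input can skip this
stage entirely. Read accounting (emitted + dropped + unmergeable = input;
assigned + candidates + discarded = input) is asserted on every run.

## Synthetic data generator

`ampedit.simulate` emulates the comparative design: per-site Tx/M depths;
per-read editing with a spectrum over (kind, length, offset) whose default
mass sits at offset 0 — the event's 5′-most affected base is the base
immediately 5′ of the break — with deletion lengths 1–10 and insertion
lengths 1–3 under geometric decay; substitution and 1-bp-indel noise drawn
from the same distribution in both samples (a `tx_noise_bias` knob exists
to stress the classifier); spiked fusion reads built by the package's own
fusion-amplicon constructor; and an optional symmetric chimera-noise rate
for null studies. Reads are emitted merged by default; a paired-end mode
splits them to exercise the merger. Everything is deterministic given the
seed, and unmodified reads share one string so per-sequence caches stay
small at deep coverage.

What the generator does *not* model: PCR duplicate structure and
amplification bias (each read is an independent molecule), position- or
motif-dependent error hotspots, quality-score degradation along the read,
microhomology-driven deletion spectra, large structural events beyond
blunt two-locus fusions, and reads from loci outside the panel. Passing
tests on simulated data therefore demonstrate the statistical machinery
under the model's own assumptions, not performance on any particular real
dataset.

## Evaluation studies and problem sizes

`ampedit.benchmarks` (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs:

* exact-arithmetic checks of the hypergeometric pmf/tail and binomial
  likelihood against integer/rational enumeration over the grid N ≤ 60
  (complete for the pmf; tails complete to N ≤ 30 and strided above, to
  keep the sweep seconds-scale);
* classifier monotonicity over randomized count grids, and a label-swap
  study (20 simulated experiments, depth 1500, rate 2%, shared noise) in
  which swapping Tx and M must collapse edit calls to ≤ 5% of the
  correctly-oriented count;
* rate recovery at depths of 5×10⁴ reads per sample for true rates
  0.1%/1%/10% with shared indel noise at half the rate, 20 seeds per rate,
  mean relative error ≤ 30%;
* a 200-experiment translocation null (3 sites, depth 800, symmetric
  chimera rate 0.2%) in which ≤ 7% of experiments may show any significant
  pair at FDR 0.05;
* a fusion spike-in dilution series (0.16%, 1.6%, 16% of a 5×10⁴-read
  site, plus an un-spiked control) that must be detected down to 0.16%
  with a clean control;
* a noise-free round trip that must recover edited-read counts and the
  injected fusion pair exactly.

These sizes were chosen as the smallest at which the statistical claims
are meaningful (e.g. ≥ 50 expected edited reads at the lowest rate).

## Numerical and degenerate-input choices

* Integral alignment scores make DP traceback equality tests exact; float
  scores are accepted but tie detection then relies on exact float
  equality.
* Hypergeometric tails are accumulated with `logsumexp`, never by naive
  summation of pmf values.
* N_Tx = 0 yields activity 0 with an explicit warning flag rather than an
  error; edited = 0 yields the degenerate interval [0, 0] (a Wald
  limitation, documented rather than patched).
* Tx/M depth imbalance > 3× per site logs a warning (comparative
  inference quality degrades) but does not fail the run.
* Sequences are handled case-insensitively; `N` bases are kept and count
  as mismatches in edit-distance matching.

## Known limitations

* The Wald interval undercovers at very low activity with small N_Tx;
  exact intervals are out of scope by design.
* UMIs are not supported, so amplification multiplicity is
  indistinguishable from molecule multiplicity.
* Fusions with loci outside the panel are invisible by construction.
* The q estimator is a documented package choice (pooled on-target
  cut-site ratio with clamping), not a fitted model.
* Adapter trimming is delegated to upstream tools.
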