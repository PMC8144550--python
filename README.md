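# ampedit

Comparative (treatment vs mock) analysis of multiplex-amplicon CRISPR
editing experiments: Bayesian classification of NHEJ indels against
sequencing/process noise, editing-activity quantification with confidence
intervals, and detection of adverse translocation events between panel
loci.

## Who this is for

Groups validating CRISPR on-/off-target activity with multiplex amplicon
sequencing (e.g. rhAmpSeq-style panels): a nuclease-treated sample (Tx)
and a mock sample (M) are amplified with the same primer panel — one pair
per candidate locus — and sequenced identically. At off-target sites,
true editing rates near 0.1% sit at or below the sequencing noise floor,
where background subtraction either buries real signal under mock noise or
reports noise as signal. `ampedit` instead models the noise explicitly
using the mock sample, and additionally mines the multiplex design for
fusion amplicons: reads carrying primers of two *different* loci, the
signature of a translocation between two cut sites.

## The model

For each locus, reads are assigned by primer edit-distance matching,
globally aligned to the reference amplicon (affine-gap Needleman–Wunsch
with cut-site-proximal placement of ambiguous gaps), and indels are
tabulated per cell (τ, i) — indel type τ by length class, reference
position i — inside a 20-bp window around the expected cut-site. With
n_Tx, n_M the cell counts and N_Tx, N_M the per-locus totals, a MAP
classifier compares

* no edit: n_Tx ~ HG(N = N_Tx + N_M, B = n_Tx + n_M, n = N_Tx) — indels
  equally likely in either sample;
* edit: n_Tx ~ Binom(n_Tx + n_M, q), q ≈ 1 estimated from the on-target
  data;

and labels the cell an edit when
P(edit)·P(n_Tx, n_M | edit) > P(no edit)·P(n_Tx, n_M | no edit), with a
position prior of 0.5 at the cut-site decaying to 10⁻⁴ at the window edge
(non-zero off-cut priors make alternative cut-sites detectable). A Tx
read carrying any edit-labeled event is an edited read; activity is
edited/N_Tx with a Wald interval p̂ ± z·√(p̂(1−p̂)/N_Tx), and a site is
"active" at ≥ 0.1%.

Mixed-primer reads are typed into the four possible fusion-end
configurations, validated by alignment against the putative fusion
amplicon (the two loci joined bluntly at their cut-sites), and each site
pair is tested with the hypergeometric upper tail
HGT(b = C_Tx; N, B = C_Tx + C_M, n), where n and N − n are geometric
means of the two sites' Tx and M read totals; p-values are
Benjamini–Hochberg corrected. See `docs/methods.md` for the full account.

## Worked example

Simulate a 3-locus experiment (4 000 reads per site per sample, 1% true
editing, shared noise, a fusion between site0 and site1 spiked into
treatment at 0.4%) and analyze it:

```sh
ampedit simulate --n-sites 3 --depth 4000 --editing-rate 0.01 \
    --sub-rate 0.001 --indel-noise-rate 0.00001 \
    --fusion site0,site1,1,0.004 --seed 7 -o sim
ampedit run --tx-r1 sim/tx.fastq --m-r1 sim/mock.fastq \
    --panel sim/panel.csv -o out
```

`out/site_results.tsv`:

```text
site_id  n_tx  n_m   edited_reads  activity_pct  ci_low_pct  ci_high_pct  active
site0    4000  4000  40            1             0.692       1.308        True
site1    4000  4000  30            0.75          0.483       1.017        True
site2    4000  4000  42            1.05          0.734       1.366        True
```

The simulator's truth record lists exactly 40/30/42 edited reads at the
three sites, so every edited read was recovered and nothing was invented;
`activity_pct` is the edited fraction of treatment reads with its 95%
Wald interval. `out/translocations.tsv`:

```text
site_a  site_b  c_tx  c_m  n     N     p_value      q_value      significant
site0   site1   16    0    4000  8000  1.50312e-05  1.50312e-05  True
```

All 16 spiked fusion reads reached treatment only (c_m = 0), so the
hypergeometric tail against the pooled background is tiny and the pair is
significant after FDR correction. `out/classifier_dump.tsv` shows the
per-cell decisions (e.g. five 1-bp deletions at the cut-site in Tx with
zero in M → edit; a lone deletion 7 bp away under a 10⁻⁴-scale prior →
noise), and `out/run_summary.json` carries the exact read accounting and
parameters.

The library mirrors the CLI: `ampedit.parse_panel`,
`ampedit.simulate_experiment`, `ampedit.analyze_reads`, and the per-stage
functions (`needleman_wunsch`, `classify_cell`, `hypergeometric_tail`,
…) are all importable for notebook use.

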