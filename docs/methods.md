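# Methods

## Scope and model

`bruwave` analyses bromouridine pulse-labeling (Bru-Seq) read data around
an acute topoisomerase-I (Top1) poisoning experiment: 45 min of
camptothecin with the final 15 min labeled, followed by washout and two
15-min recovery labelings.  Camptothecin traps Top1 covalently on DNA;
an elongating RNA polymerase II that reaches such a lesion arrests and
does not resume after drug removal, so recovery of synthesis proceeds
exclusively through newly initiated polymerases that repopulate genes
5'→3' as a wave.  The package quantifies four consequences of that
mechanism:

1. **Size-dependent inhibition.**  With lesions at density λ per bp, a
   polymerase clears a gene of length L with probability exp(−λL), so
   long genes lose nascent signal while short genes — which still attract
   their share of a fixed sequencing library — gain relative signal.
   Gene-level synthesis is summarized as RPKM, reads per kb of genomic
   (intron-inclusive) gene length per million library reads, and
   2-fold classes of the pseudocount-stabilized treated/control ratio.
2. **5'-restricted coverage under drug.**  The TSS-aligned metagene of
   long expressed genes decays approximately as exp(−λx) with distance x
   from the TSS, because coverage at x requires no lesion in [0, x].
3. **A recovery wave.**  After washout, new initiations elongate at a
   reduced rate v; the farthest labeled position ("front") at effective
   time t (washout → end of labeling) is v·t.  The front is detected on
   the recovery/control metagene ratio and the rate fitted through the
   origin: v = Σ fᵢtᵢ / Σ tᵢ² (kb/min).
4. **Termination and upstream effects.**  Readthrough past the poly(A)
   site (short unblocked genes), divergent upstream PROMPT signal, and
   enhancer-RNA output are scored as window-density indices.

## Coordinates and quantification

All intervals are 0-based half-open on the forward genomic axis (BED
native); strand enters only through TSS/TES derivation and the
distance-from-TSS transform.  A read is assigned to a gene iff it shares
the strand and its midpoint lies inside the gene span — midpoint
assignment avoids double counting at gene boundaries; overlapping
same-strand genes each count a shared read.  The library size is the
total read count of the condition file, matching the "per million reads"
normalization; no per-gene rescaling is applied anywhere, so
cross-condition bin ratios remain meaningful.

## The simulator

The generator is mechanistic, not phenomenological: per gene, trap
positions form a homogeneous spatial Poisson process (default
λ = 0.25/kb) on [0, L + readthrough extent), fixed per gene per
condition — lesions live on the DNA and are shared by all of a gene's
polymerases.  Polymerases initiate at `k_init` (default 1/min),
elongate at `v_elong` (default 2000 bp/min; ~2 kb/min is the accepted
unperturbed Pol II rate) and arrest permanently at the first trap.
Labeled spans are the sub-intervals transcribed during the labeling
window; reads (default 50 bp) are Poisson-thinned uniformly along the
labeled spans to the configured per-condition depth and emitted fully
inside their span, in genomic coordinates on the transcript strand.

Condition timelines (label window on each condition's clock):

| condition | traps | elongation | label window |
|---|---|---|---|
| control | none | v_elong | [0, 30] min, steady-state initiation history |
| cpt0    | active 45 min | v_elong until first trap | final [30, 45] min of drug |
| rec15   | cleared at washout | v_recovery (default 1200 bp/min) | [0, 15] min |
| rec30   | cleared at washout | v_recovery | [15, 30] min |

Model choices worth knowing:

* **Pre-washout polymerases never label again.**  In the recovery
  conditions every polymerase engaged during treatment — stalled at a
  trap or still moving at washout — is retained in the truth table with
  an empty labeled span.  Nearly all treatment-phase polymerases are
  trap-limited anyway (mean free path 1/λ = 4 kb), and observed data
  show no body recovery at all, so arrest is applied uniformly.
* **Trap density default.**  λ = 0.25/kb makes a 100-kb gene almost
  surely internally blocked while a 5-kb gene escapes with probability
  exp(−1.25) ≈ 0.29, reproducing the long/short dichotomy.
* **Readthrough** is modeled only for genes short enough to escape
  internal blockage (≤ 20 kb): an escaping polymerase continues past the
  TES with probability 0.5 for an exponential extension (nominal mean
  5 kb) truncated at 5 kb, so every read respects the declared
  gene-span + extent envelope.  The truncation lowers the realized mean
  extension below the nominal parameter.
* **PROMPTs** are fixed 1-kb antisense transcripts upstream of the TSS,
  emitted at `prompt_basal_frac · k_init` (default 0.1/min-equivalent)
  and multiplied by `prompt_rate_fold` (default 5) under drug.  The
  extent is fixed, not mechanistic.
* **Labeling** is instantaneous and uniform; there is no uptake
  kinetics, no sequence content, no error model, no replication or
  pharmacokinetics.  `init_boost` (default 1) optionally scales drug-arm
  initiation; no value is assumed for promoter hyper-initiation.
* One RNG stream per condition (`seed + condition index`), so each
  condition is independently reproducible; fixtures are byte-identical
  across re-runs of the same seed.

Because the generator draws reads from the exact labeled spans, passing
tests demonstrate internal consistency of the estimators with the
mechanistic model — they do not validate mapping artifacts, coverage
biases, expression heterogeneity, annotation errors or overlapping
transcription found in real libraries.

## Analysis parameters

| parameter | default | role |
|---|---|---|
| epsilon | 0.25 RPKM | pseudocount in fold-change and profile ratios |
| fc_threshold | 2.0 | up/down classification cut-off |
| expr_min_rpkm | 1.0 | expression floor for the metagene cohort |
| metagene_min_length | 100 kb | length floor for the cohort |
| bin_width / max_extent | 1 kb / 100 kb | TSS-aligned profile grid |
| front_alpha | 0.5 | recovery/control ratio below which a bin counts as unrecovered |
| rt_window / prompt_window | 10 kb / 5 kb | feature windows |
| epsilon_index | 0.01 | pseudocount on dimensionless feature-index ratios |
| n_bootstrap | 1000 | gene-resampling replicates for the rate CI |

The two pseudocounts differ deliberately: `epsilon` is sized for
RPKM-scale densities, while feature indices (window/body ratios) live
near 0.01–0.5, where a 0.25 pseudocount would crush real fold changes;
`epsilon_index` stabilizes those ratios without distorting them.  In an
index denominator the body density is floored at `epsilon` rather than
shifted, so a well-measured index equals the plain density ratio.

## Front detection and rate fit

The recovery/control ratio is smoothed with a centered 3-bin moving
average (shrunk windows at the edges) and scanned from the TSS; the
front is the right edge of the last bin before the ratio first stays
below `front_alpha` for three consecutive bins.  The persistence rule
rejects single-bin noise dips; on noiseless step profiles the detector
returns the analytic threshold crossing exactly.  If the ratio never
drops, the front is censored at the profiled extent and flagged
`beyond_extent`; such fronts are excluded from the fit.  All-zero
recovery profiles return front 0 with a `no_signal` flag.

The effective time of a labeling is measured from washout to the **end**
of the window (15 and 30 min for the two recovery arms): the front
records the farthest labeled position, which is reached at window end.
The rate is the least-squares slope through the origin — front(0) = 0
by construction, and with two time points an intercept would not be
identified.  Uncertainty comes from resampling cohort genes with
replacement (gene-to-gene variation dominates the aggregate noise),
re-running detection and the fit per replicate, and taking the 2.5/97.5
percentiles; the interval is widened if needed to include the point
estimate.

Known numerical properties: the front is quantized to the bin grid, and
the threshold crossing sits slightly inside the declining coverage ramp,
giving the pooled rate a small (≈2–4%) downward bias relative to the
simulated elongation rate.  At very high depth the bootstrap collapses
onto a single bin, so the CI can degenerate to (essentially) a point and
then under-covers the true rate; the CI is trustworthy as a measure of
cohort sampling noise, not of this discretization bias.  Per-gene fronts
additionally inherit initiation-time granularity: at low initiation
rates the deep ramp of a single gene is resolved by only a handful of
polymerases.

## Study sizes used by the tests and the acceptance script

The routine suite exercises the estimators at reduced scale (tens to a
few hundred genes, 10⁵–10⁶ reads per condition) chosen so the whole
suite runs in well under a minute of simulation time per test.  The
rate-recovery experiments (`rate_recovery_study`) use 100 genes of
150–300 kb at 10⁶ reads per condition — enough that front detection is
read-noise-free — with 50–100 bootstrap replicates.  The mechanism
checks (exponential decay of the drug-arm profile) use 400 long genes,
because the cohort survival curve is an empirical mean of per-gene
first-trap step functions and its fitted λ has relative standard error
≈ 1/√n_genes.

## Degenerate inputs and tie-breaks

Empty read files parse to empty frames with a warning; an empty metagene
cohort is an error that names the thresholds to relax; genes present in
only one condition are excluded from fold-change classification and
logged; all genes the same length collapses size stratification to a
single bin with a warning and an undefined (NaN) trend statistic; a
readthrough window overlapping a same-strand downstream gene, or an
enhancer overlapping an annotated gene, is flagged but still computed.

## Limitations

* The estimators assume non-overlapping, well-annotated transcription
  units; the simulator only emits such layouts.
* The rate estimator is designed for the aggregate cohort; per-gene
  rates are reported for inspection, not inference.
* Feature indices are deliberately agnostic about mechanism (e.g.
  readthrough vs alternative poly(A) usage vs RNA stabilization cannot
  be distinguished from window densities).
* No differential-expression statistics are provided; classification
  uses plain fold-change cut-offs by design.
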