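# Methods

## The model

For one induced sample and its paired pre-induction control, let C⁺ and
C⁻ be a guide's counts after control-median normalization. The method
works on the MA plane,

    A = (lg C⁺ + lg C⁻) / 2,     M = lg C⁺ − lg C⁻     (lg = log10),

and treats M for a phenotypically neutral guide as draws from a
zero-centred distribution whose spread depends only on abundance:
M | A ~ N(0, σ(A)²). σ(A) is estimated empirically from the
negative-control guides — a sliding window along A, each window holding a
fixed fraction of the controls, yields (mean A, sample SD of M) pairs —
and smoothed with the two-parameter exponential

    σ(A) = α · e^(−βA),

fit by Levenberg–Marquardt nonlinear least squares (equal window
weights), with the closed-form OLS of ln σ on A as the starting point and
as a flagged fallback if the NLS does not converge. Each guide is scored
as Z = M/σ(A) with a one-sided upper-tail normal p-value; a gene is a
candidate when at least `min_sgrnas` of its guides have p < `alpha_level`
in every biological replicate. Replicates are scored fully independently
(own control filtering outcome is shared, own variance fit); consistency
is enforced only at the gene level, which is also the only multiplicity
control — with 8 guides per gene and α = 0.05, a null gene passes one
replicate with probability P(Binom(8, 0.05) ≥ 3) ≈ 5.8×10⁻³ and two
independent replicates at ≈ 3.3×10⁻⁵, under one expected false candidate
per ~1,400-gene screen.

Assumptions worth stating: M is approximately normal given A (adequate in
the tails at typical depths, see "Calibration" below); the negative
controls are phenotypically inert so their M spread is pure noise; and a
monotone exponential is an adequate summary of σ(A) over the control
abundance range.

## Parameters

| parameter | default | units / meaning |
|---|---|---|
| `spacer_length` | 19 | nt extracted between the flanks |
| `trim_fraction` | 0.10 | per-sample two-tail control filter (rank percentile) |
| `pseudocount` | 0.5 | added to normalized counts before logs |
| `window_fraction` | 0.02 | fraction of controls per sliding window |
| `window_step` | 1 | controls advanced per window (maximal overlap) |
| `min_window_size` | 20 | floor on window membership for small libraries |
| `alpha_level` | 0.05 | guide-level significance threshold (strict <) |
| `min_sgrnas` | 3 | significant guides required per replicate |

Flanking sequences are screen-specific amplicon constants and are
runtime parameters with no defaults. Control filtering uses average-rank
percentiles computed as (rank − 0.5)/n so that a fully tied control set
has percentile 0.5 everywhere and nothing is removed; filtering is done
on raw counts, before normalization, matching the stage order of the
procedure. P-values are one-sided (upper tail) because enrichment of
bypass clones is the question; `two_sided=True` doubles the folded tail.
The window step of 1 gives the smoothest σ(A) estimate at negligible
cost; windows are built from the retained (stable) controls only, while
σ̂ is evaluated at every guide's A, extrapolating beyond the control
range when necessary (logged).

### The pseudocount

The pseudocount of 0.5 is applied on the normalized scale, where the
control-median is 1 by construction. It guarantees finite A and M for
zero counts, but it is *not* small relative to guides below the control
median: it shrinks their M toward 0 by a factor ≈ C/(C + 0.5). Because
the window SDs are computed from controls transformed the same way, Z
and p remain calibrated — but the *fitted* β no longer reflects the raw
count dispersion trend and is typically negative at depth ~500 (σ of the
pseudocounted M rises with A below C ≈ 1, then falls). Interpret α and β
as a description of the pseudocounted M spread, not of sequencing noise
per se; with a small pseudocount (e.g. 0.01, safe whenever no retained
guide has a zero count) the fitted β is positive and tracks the
dispersion decay, and the test suite probes the generator's
mean-variance structure that way.

## The synthetic generator

`simulate_screen` emulates the study-scale design: 1378 target genes +
56 negative-control genes at 8 guides each (~11,500 guides), two
replicates of (pre-induction, induced) pairs. Per guide, a baseline
relative abundance a ~ LogNormal with log10-SD 0.4 sets its expected
count μ = depth·a/mean(a) (depth 500 reads/guide by default); counts are
gamma-Poisson (negative binomial) with dispersion
φ(μ) = 0.15·e^(−0.5·log10 μ), so the M-spread decays with A and the
exponential fit is exercised in its intended regime (the decay constants
are plausibility choices; no dispersion estimates exist to match).
Spiked "bypass" genes multiply the induced-sample mean of each
*effective* guide by 10^0.6; each guide of a bypass gene is effective
independently with probability 0.75, stressing the ≥3-of-8 rule the way
real guide-efficiency heterogeneity does. `simulate_reads` inverts the
counting path (pad + flank5 + spacer + flank3 + pad per read, optional
single-base spacer errors), making the counter testable against the
generator's bookkeeping.

What the generator does **not** model: infection MOI and coverage
dynamics, bottleneck drift over passages, Cas9 cutting-efficiency
sequence effects, PCR jackpotting, and sample-specific GC or length
biases. Passing tests therefore demonstrate the statistical machinery is
correct under the stated noise model, not that the pipeline is robust to
every artifact of real sequencing data.

## Numerical choices

- Window SDs use ddof = 1; windows with zero SD (all-tied M) are dropped
  before fitting, and fewer than two usable windows is a hard error.
- The NLS is seeded at the log-linear solution; with exactly two windows
  both coincide and the fitted curve passes through the two points to
  machine precision.
- Control filtering ties are resolved by average ranks; duplicate library
  spacers are a hard error at index build (exact assignment would be
  ambiguous); spacer extraction anchors on the *first* flank5 occurrence
  and requires flank3 immediately after the fixed-length spacer.
- Strict inequality p < α at the gene rule; a guide at exactly 0.05 does
  not count.
- Gene output is ordered by (min over replicates of the significant-guide
  count, then the summed −log10 p of the top guides) — a reporting
  convenience only; the calling rule itself induces no ranking.

## Calibration and scale of the checks

Under null screens at the default generator settings, the pooled
guide-level P(p < 0.05) stays within [0.03, 0.07] and 20 independent
screens yield ≤ 2 candidate genes in total. The null p-value histogram is
only approximately uniform (KS distance ~0.03–0.06 at n ≈ 11,000): the
normal tail approximation to negative-binomial log-ratios is imperfect in
the mid-distribution, while the 5% tail that drives calling is well
calibrated. Parameter recovery on M ~ N(0, 0.5·e^(−0.8A)) with 5,000
controls returns α within 10% and β within 15%. Spiked screens (20 bypass
genes, 0.6 log10 enrichment, 75% effective guides, depth 500) are
recovered at ≥ 80% with ≤ 1 false candidate per run averaged over seeds —
in practice 100% recovery and ≤ 0.4 false calls. Test and acceptance
problem sizes (full-geometry screens, 5–20 seeds; counting checks on a
~60-guide library at depth 30) are chosen so the whole suite runs in
about a minute on one core.

## Limitations

- The exponential σ(A) is monotone; if real control noise is U-shaped in
  A (e.g. PCR saturation at the top), the model under- or over-states σ
  at the extremes. The window-σ diagnostic plot exists to catch this.
- Exact-match counting discards every read with a spacer error; depth, not
  accuracy, is what suffers, but libraries with near-duplicate spacers
  (edit distance 1) would see cross-talk only through unassignment, never
  misassignment.
- No copy-number, batch, or guide-efficiency correction at scoring time;
  none is part of the method.
- With >2 replicates the rule generalizes to "all replicates"
  (configurable via `min_replicates`), the strictest reading.
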