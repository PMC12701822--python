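# Methods

This note documents the models, estimators and numerical choices behind
`dsbchrom`, in the spirit of the model documentation of simulation and
statistics packages: what is computed, under which assumptions, and what
the synthetic-data validation does and does not establish.

## 1. The measurement problem

A site-specific DSB reorganizes chromatin at three scales that this
package quantifies:

1. **Contacts (Hi-C).** The break anchors cohesin-extruded loops, seen as
   a cross-shaped stripe through the cut bin in treated-vs-untreated
   differential maps, while contacts *spanning* the cut are attenuated —
   the break acquires insulating, TAD-boundary-like character.
2. **Insulation.** The sliding-square insulation score drops at the cut in
   the treated sample; the per-site change (ΔIS) is a scalar readout of
   acquired insulation, and its correlation with per-site repair-factor
   ChIP enrichment links chromatin reorganization to pathway choice.
3. **ChIP domains.** Resection deposits RPA/RAD51 on kilobase-scale ssDNA
   (strand-asymmetric: the two 3' tails point in opposite directions), and
   the homology search spreads RAD51 over a broad, hundreds-of-kb dsDNA
   domain whose extent is constrained by TAD boundaries and by loop
   extrusion.

## 2. Synthetic-data generator

The generator is first-class, tested code: it defines the study conditions
under which every estimator is validated.

### Contact model

Expected counts for bins at separation `s` on one chromosome:

    E[s] = A * ((s + s0) / s0)^(-alpha)            (power-law decay)
         * m_tad        if both bins share a TAD
         * f_bnd^k      k = TAD boundaries crossed

Treated maps additionally multiply pairs with one end in a cut-site bin by
`1 + k_stripe * g(d)`, where `g` decays linearly from 1 at the cut to 0 at
the stripe extent `L_stripe` (default 1 Mb, the observed span of
DSB-chromatin contacts; the linear form is a stand-in — the true decay law
of the stripe is not established), and multiply cut-spanning pairs by
`f_cut` (default 0.4). Counts are independent Poisson draws per
upper-triangle bin, then symmetrized. TADs tile each chromosome
(`tad_size`, default 1 Mb); boundaries are the interior TAD edges.

Defaults: `alpha = 1`, `s0 = 25 kb`, `A = 150` expected counts at zero
separation, `m_tad = 2`, `f_bnd = 0.5`, `k_stripe = 2`. These give window
sets of ≥1e6 counts for 20 sites at 50 kb resolution — comparable
signal-to-noise to a deep Hi-C experiment aggregated over ~100 sites.

### ChIP model

Untreated expectation is a flat background `b` reads/bin (derived from
`depth`, default 5e6 reads over the simulated region, when not set
explicitly). Treated adds per cut site:

* a **narrow** Gaussian component: total reads `A_n` (default 5000),
  `sigma_n = 2.5 kb` — FWHM 5.89 kb, the scale of the measured
  resection/filament peak (~5–6 kb);
* a **broad** Gaussian component: total reads `A_b` (default 1e5),
  `sigma_b = 250 kb` — FWHM 588.7 kb, the scale of the measured
  homology-search domain (~600 kb). With `truncate_at_boundaries` the
  broad component contributes zero beyond the first TAD boundary on each
  side of the cut (total expectation falls back to background).

Strand assignment: background and broad split 1:1. Within
`±resection_span` of the cut (default 1 kb/side) a fraction `phi`
(default 0.8) of narrow-component reads moves to the strand matching
3'-resection polarity — forward excess on the telomeric (right) side,
reverse on the centromeric (left) side. The convention is recorded in the
truth file so downstream tests are convention-independent.

**Library sizes.** The recorded library is the reads realized on the
simulated region plus the background of the unsimulated genome remainder
(`genome_scale`, default 60 ≈ 3 Gb / 50 Mb). This matters: if the library
were only the simulated reads, the treated sample's signal reads would
inflate its library by ~20% and the treated−untreated RPM difference would
carry a large negative offset in signal-free territory — an artifact real
genome-wide libraries do not show, because per-window signal is a tiny
library fraction.

Noise is independent Poisson per bin per strand; no overdispersion
(sufficient for all estimators here; overdispersion would widen the
recovery tolerances but not change any estimator).

### Sites and truth

`make_sites` places `n_sites` deterministically given the seed, at least
`min_separation` apart and `edge_margin` (default 2 Mb, one analysis
half-window) from chromosome ends, using the compressed-uniform
construction (uniform draws in the separation-deflated span, sorted, then
re-expanded) so feasible configurations always succeed; infeasible ones
raise. Every run writes a `SimulationTruth` (parameters, realized sites
and boundaries, seed, warnings) that round-trips through YAML and
regenerates the data bit-identically.

## 3. Estimator decisions

* **Differential aggregation.** Per site `log2(T+ε) − log2(U+ε)` with
  `ε = 1` count (the log-difference form keeps swap-antisymmetry exact in
  floating point; ε is needed because zeros are common and its value is
  recorded in the output). The center bin (cut self-interaction) is
  included by default; sites whose windows leave the chromosome are kept
  in the stack but flagged invalid and excluded from averages.
* **Insulation.** For bin `i` and square size `d` bins, the raw score is
  the NaN-aware mean of the upstream×downstream block
  `(i−d..i−1) × (i+1..i+d)`; normalized score is `log2(raw / chromosome
  mean)`, hence invariant to global matrix scaling. Bins whose square is
  >50% masked, or within `d` of an end, are NaN. Default square 500 kb at
  25–50 kb bins. ΔIS averages treated−untreated over all bins overlapping
  a 50 kb window at the cut (2–3 bins depending on phase — deterministic);
  sites with any NaN bin are excluded. The one-sample t statistic is NaN
  with a `degenerate` flag when the per-site changes are all identical.
* **Per-site ChIP enrichment** (shared by the correlation and band
  analyses): summed treated−untreated RPM over ±10 kb around the cut
  (configurable).
* **Spearman correlation.** Average ranks for ties; p from the
  large-sample t approximation, with an exact permutation option for
  n ≤ 8 and a seeded Monte Carlo permutation null above that (full
  enumeration beyond 8 is computationally out of reach; the method tag
  records which null was used).
* **Two-component width fit** — the central estimator decision: the data
  reports widths without an estimator definition, so widths here are
  *defined* as the FWHM (2.3548 σ) of Gaussian components fitted on two
  profile scales. Profiles are converted to densities (RPM/bp) so
  amplitudes are comparable across bin sizes. Stage 1 fits
  `c + A_b exp(−x²/2σ_b²)` on the coarse profile (±1.5 Mb, 10 kb bins)
  with the narrow region (±3 σ_n-start) masked; stage 2 fits the narrow
  component on the fine profile (±15 kb, 100 bp bins) with the broad part
  fixed; σ_n ≤ σ_b is enforced by bounds. Five deterministic
  (σ_n, σ_b)-start pairs are tried and the best residual wins, making the
  fit deterministic given its inputs. Tolerances 1e-8, ≤500 residual
  evaluations per stage; non-convergence returns parameters with a flag
  and warning. Standard errors come from the Jacobian with a noise scale
  estimated robustly (MAD) from the far-flank bins. A joint single-stage
  fit is available behind a flag; the two-stage default exists because the
  ~100× scale separation otherwise lets the broad component absorb the
  narrow one.
* **Strand asymmetry.** Forward−reverse difference of per-strand
  meta-profiles. The polarity switch is the zero-crossing of the 3-bin
  moving-average-smoothed profile nearest the cut. The extent is the span
  between the outer edges of the above-threshold runs (|asymmetry| ≥ 10%
  of its max, threshold configurable) nearest the cut on each side — the
  central zero-crossing itself dips below threshold, so the two flanking
  runs are bridged. All-zero asymmetry yields extent 0 with a
  `defined=False` flag.
* **Boundary drop.** For (site, boundary) pairs separated by 200–700 kb,
  the enrichment profile over boundary ± 100 kb is oriented cut-proximal
  side left and normalized by its proximal mean (pairs with non-positive
  proximal mean are excluded and counted), so the drop `1 − distal mean`
  is a unitless fraction invariant to track scaling. "Normalized" is an
  interpretation — the upstream definition is not spelled out. Random
  controls are drawn at boundary-matched distances (inverse-CDF sampling
  of the empirical distance distribution), excluding positions within the
  flank of any true boundary.
* **Band differences.** Half-open bands `[lo, hi)` on the signed
  bin-center offset from the cut; a bin centered exactly at +0.5 Mb
  belongs to the distal band. Unpaired two-sided t-test across sites.

## 4. Validation scenarios and their scales

All validation runs on one CPU in minutes; sizes were chosen as the
smallest that leave the statistics comfortably powered.

* **Oracle agreement**: the production insulation scorer matches an
  independently written double-loop oracle bit-for-bit on 50 random
  matrices up to 200 bins (both reduce each square through the same
  C-ordered mean, so agreement is exact, not approximate).
* **Null calibration** (no perturbation, 20 seeds, 20 sites on 60 Mb):
  mean ΔIS within 3 sem of 0; differential-map mean |log2| < 0.05.
* **Perturbation detection** (126 sites on 2×150 Mb, `f_cut=0.4`,
  `k_stripe=2`): ≥90% of sites lose insulation; cross > off-cross contrast
  on realizations and on the analytic expected matrices.
* **Width recovery** (20 seeds, 10 sites on 40 Mb, 5e6-read depth):
  median FWHMs within 15% of the analytic 5.887 kb / 588.7 kb.
* **Asymmetry recovery** (same runs): opposite flank polarity in ≥19/20
  seeds; median extent within 50% of 2 kb.
* **Boundary truncation** (2×60 Mb, 30 sites): run with `sigma_b = 10 Mb`
  and `truncate_at_boundaries` so the in-TAD profile is an effectively
  flat plateau and the domain extent is *boundary*-determined — the
  regime the truncation models. Two deliberate control-design choices:
  (i) controls are sampled within the damaged TAD
  (`exclude_cross_boundary=True`), because the truncated synthetic domain
  is exactly zero beyond the boundary and the proximal-mean-positivity
  filter applied to pure noise selects positive-noise profiles, biasing
  control drops toward +1 — real chromatin retains signal at random
  distal positions, so this is a generator artifact the control design
  must avoid; (ii) ~4 controls per site, since control windows drawn many
  times from few sites overlap and the iid sem would understate the true
  spread. With the default σ_b = 250 kb Gaussian (no truncation) the drop
  statistic cannot distinguish the domain's smooth radial decay from a
  boundary step — boundary and control drops are then similar by
  construction, which the demo run illustrates.
* **Band broadening** (20 seeds): σ_b ×1.5 in condition B raises the
  distal band in ≥18/20 seeds.
* **Spearman calibration**: exactly 1 on monotone data; mean within 0.05
  of 0.4 over 200 Gaussian-copula replicates (n=100, latent Pearson
  `2 sin(0.4 π/6)`).
* **Determinism**: the demo pipeline writes byte-identical report bodies
  across repeated runs with the same seed (derived seeds are fixed
  offsets; reports contain no timestamps).

## 5. What passing does and does not show

The generator reproduces the *statistical structure* the estimators
assume: power-law decay with TAD blocks, a linearly decaying stripe,
Gaussian narrow/broad ChIP components, independent Poisson noise, exact
polarity switching at the cut. Real data differ in ways the validation
does not cover: overdispersed counts and copy-number structure,
mappability and blacklist artifacts, irregular TADs and nested
boundaries, non-Gaussian domain shapes (so the FWHM estimates are
model-dependent summaries, not model-free widths), inter-replicate
variability, and incomplete cutting (site-to-site cleavage efficiency
enters only through ranks, not through signal attenuation). Recovery
tolerances (15% on widths, 50% on the asymmetry extent) quantify
estimator noise under the stated depths, not under real-library depths.

## 6. Degenerate inputs and edge behaviour

Zero valid sites, all-NaN chromosomes, fully masked viewpoints, infeasible
site packings and infeasible control exclusions raise `ValueError` with a
message naming the offending object. Single-pair t-tests, identical-sample
comparisons and all-zero asymmetry return NaN statistics with explicit
flags rather than raising. A trailing partial bin (chromosome length not
divisible by the bin size) is allowed and flagged in the map metadata.
Overlapping cut sites closer than 2 σ_b superpose and record a warning in
the truth file.
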