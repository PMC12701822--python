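# dsbchrom

Break-centered chromatin analysis around programmed DNA double-strand
breaks (DSBs).

When Cas9 cuts chromatin at defined positions, the break reorganizes its
neighbourhood: cohesin-driven loop extrusion anchored at the break produces
cross-shaped "stripes" in Hi-C contact maps, contacts spanning the cut are
attenuated (the break behaves like a de-novo TAD boundary, visible as a
drop in insulation score), resection generates kilobase-scale
strand-asymmetric RPA/RAD51 ChIP-seq peaks, and the homology search spreads
RAD51 over a broad (hundreds of kb) chromatin domain that is constrained by
TAD boundaries. `dsbchrom` provides a tested, reusable pipeline for all of
these break-centered measurements, together with a synthetic-data generator
that emulates the statistical structure of the sequencing inputs so every
estimator can be validated against known ground truth.

Intended users: genomicists analysing Hi-C and (stranded) ChIP-seq around
site-specific DSBs — multi-target CRISPR systems, restriction-enzyme
systems, or single engineered breaks.

## What it computes

| Analysis | Statistic |
|---|---|
| Differential Hi-C aggregation | site-averaged `log2((T+ε)/(U+ε))` contact maps in windows centered on cut bins; cross (stripe) vs off-cross contrast |
| Virtual 4C | viewpoint contact profiles and treated−untreated differentials |
| Insulation | sliding-square score `log2(mean square / chromosome mean)`; per-site ΔIS = treated − untreated over a window at the cut, one-sample t-test; Spearman correlation of the insulation drop with per-site ChIP enrichment |
| ChIP meta-profiles | RPM-normalized treated−untreated profiles averaged over cut sites, on a fine (100 bp) and a coarse (10 kb) scale |
| Peak widths | FWHM of a two-component Gaussian fit `c + A_n e^{−x²/2σ_n²} + A_b e^{−x²/2σ_b²}`, broad component fitted on the coarse profile (narrow region masked), narrow on the fine profile (broad fixed) |
| Strand asymmetry | forward−reverse enrichment, polarity-switch position and extent of the above-threshold region (resection span) |
| Boundary constraint | normalized enrichment drop across TAD boundaries 200–700 kb from cut sites vs distance-matched random controls, one-sample t-tests |
| Band differences | per-site mean enrichment in signed distance bands (−1.5..0.5 / 0.5..1.5 Mb) compared between two conditions, unpaired t-test |

The generator produces paired treated/untreated contact maps (power-law
distance decay, TAD blocks, break-anchored stripe, cut attenuation) and
stranded ChIP coverage (Poisson background + narrow resection peak + broad
homology-search domain, optional truncation at the first TAD boundary),
with every parameter recorded in a YAML truth file that regenerates the
data bit-identically.

## Worked example

Run the bundled demo pipeline — two 30 Mb chromosomes, 12 cut sites,
contact maps at 50 kb, ChIP coverage at 100 bp:

```bash
dsbchrom --out demo_out run demo_config.yaml
```

Selected values from the printed report (`demo_out/report.json`):

```
"hic":        cross_mean_log2ratio  0.535   off_cross_mean_log2ratio −0.234
"insulation": mean_delta_is −0.709  fraction_sites_decreased 1.0  p 2.8e-08
"chip":       narrow_fwhm_bp 5928   broad_fwhm_bp 587391   asymmetry_extent_bp 2100
"bands":      difference [−0.121, +0.226]
```

Reading these: the cross through the cut bin gains contacts
(+0.54 log2) while the surrounding window loses them (−0.23, the injected
cut attenuation `f_cut = 0.4`); all 12 sites lose insulation score
(mean ΔIS −0.71, i.e. the break acquires boundary character); the fitted
narrow and broad FWHMs (5.93 kb, 587 kb) recover the injected
σ_n = 2.5 kb and σ_b = 250 kb (analytic FWHM 5.89 kb / 588.7 kb); the
strand-asymmetry extent (2.1 kb) recovers the injected ±1 kb resection
span; and a condition with 1.5× broader σ_b gains enrichment in the distal
(0.5–1.5 Mb) band. The boundary-drop contrast against random controls
appears when the generator truncates the broad domain at TAD boundaries
(`simulation: {truncate_at_boundaries: true}`); with an untruncated
Gaussian domain, boundary and control profiles show the same smooth radial
decay.

The CLI also exposes each stage separately (`simulate`, `hic-aggregate`,
`insulation`, `chip-profile`, `strand-asym`, `boundary`, `bands`); the
same functionality is available as a library (`import dsbchrom`).

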