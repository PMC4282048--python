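# Methods

## What the simulator models

Each field stands for a maximum-intensity Z-projection of a starved yeast
culture imaged in up to four channels. Cells are non-overlapping ellipses
placed by rejection sampling (bounding-circle test, at least 8 px wall-to-wall
gap, 10,000 attempts per cell before a placement error). Per cell the
generator draws, in order: an age group from `age_group_weights`
(default V 0.45, YM 0.30, OM 0.25), a bud-scar count from the age group's
law (V: exactly 0; YM: uniform on {1,2}; OM: uniform on {3..8}), a
localization phenotype from that age group's prevalence vector, a PSG count
(uniform on 1..3 for PSG-bearing phenotypes, else 0), and a baseline GFP
level (5% coefficient of variation around 100 intensity units).

The default wild-type prevalences put the PSG class at 65% of virgins, 60%
of young mothers and 30% of old mothers, with nuclear enrichment rising with
age and the remainder in the Equal class:

| age | NUCLEAR | PSG | NUCLEAR_PSG | EQUAL |
|---|---|---|---|---|
| V  | 0.02 | 0.65 | 0.03 | 0.30 |
| YM | 0.03 | 0.60 | 0.04 | 0.33 |
| OM | 0.12 | 0.30 | 0.08 | 0.50 |

Rendering: GFP is flat at the cell baseline *b*, with the nucleus (a
concentric ellipse at 0.4 of the cell diameter) multiplied by the enrichment
factor rho = 2.5 for nuclear-enriched phenotypes, and Gaussian puncta
(sigma 3 px, peak 4x the cytoplasm level) added in the cytoplasmic shell for
PSG-bearing cells. DNA marks the nucleus at a fixed level. CFW draws a 2-px
cell-wall outline (60 units) plus one bright ring (radius 4 px, 200 units)
per bud scar, centred on the boundary with at least ~13 px of arc between
rings. The optional RFP channel is a constant low baseline — the
"little or no new synthesis during starvation" condition. All channels are
blurred with a Gaussian PSF (sigma 1 px) and then corrupted with Poisson
shot noise plus Gaussian read noise (sd 2, i.e. 2% of the baseline). Setting
`noise=None` and/or `psf_sigma_px=0` yields analytically exact renders used
by the oracle tests.

Geometry defaults — cell radius 2.5 +/- 0.4 um, 0.1 um/px, nucleus fraction
0.4 — match typical confocal imaging of yeast at 63x. Every raster and truth
record is a pure function of `(config, seed)`; strain-library fields use
per-(strain, round) seeds derived by SHA-256 from the master seed so any
single field can be regenerated alone.

What the generator deliberately does *not* emulate: 3D stacks (projections
are rendered directly, since the analysis operates on projections anyway),
photobleaching, time-lapse, uneven illumination, autofluorescence background,
vacuole texture, cell clumping/budding contact, or dead cells. Passing tests
therefore demonstrate correctness of the measurement pipeline under
idealized but plausibly scaled imaging, not robustness to every real-world
artefact; the thresholds below are configurable for real data, and an
optional rolling-median background correction hook is left out by design
(simulated backgrounds are near zero).

## Pipeline choices

**Segmentation.** Cells are found on the GFP channel — every phenotype class
has cytoplasmic GFP, whereas CFW stains only the wall — by Gaussian smoothing
(sigma 2), a global Otsu threshold, hole filling, and a distance-transform
watershed seeded at distance maxima at least 15 px apart. A contrast guard
(foreground minus background mean must exceed 5 background standard
deviations) stops Otsu from hallucinating cells on signal-free images.
Objects smaller than a 1.2 um-radius disc and border-touching cells (their
cytoplasm is truncated, biasing the ratio) are removed. Nuclei are
thresholded on the DNA channel within each cell footprint (Otsu over
within-cell pixels); one nucleus per cell (largest component), relabelled
with the parent cell id; cells without a nucleus go to a QC list.

**N:C ratio.** Computed as a cross-multiplied mean ratio
`(sum_N * |C|) / (sum_C * |N|)` with float64 accumulation — sums of float32
rasters are exact, so a uniform raster scores exactly 1.0 and the ratio is
invariant under positive gain to < 1e-12. The cytoplasm mean *includes*
punctum pixels by default (the alternative is `exclude_puncta`): a
PSG-bearing cell therefore scores slightly below 1, which is the documented
behaviour, not a bug.

**Punctum detection.** Scale-normalized Laplacian-of-Gaussian at sigma 3 px;
local maxima at least 5 px apart, restricted to the cytoplasm with the
nucleus dilated by 2 px (the blurred rim of a bright nucleus otherwise
produces edge responses); accepted when the raw peak is at least 2x the
cytoplasm median. The raw-peak criterion is robust to PSG-inflated means and
rejects nucleus-rim blur, whose raw level stays near the baseline.

**Scar counting.** A matched annular filter (mean over a ring of radius
4 +/- 1.5 px, the scar geometry) peaks at ring centres while responding
weakly to the thin wall outline; its tight support keeps rings ~12 px apart
resolvable where Gaussian blob smoothing merges them. Peaks are searched in
a band from 7 px inside to 2 px outside the boundary and accepted at 2x the
"outline floor". The floor is estimated field-wide
(`scar_reference_level`: 25th percentile of the response over all cells'
boundary ribbons) because a crowded 7-8-scar cell has no scar-free stretch
of its own boundary to calibrate against; standalone single-cell calls fall
back to the cell's own ribbon percentile, which is accurate up to ~6 scars.
Counts saturate at 12. Only the >2-scar bin must be reliable for age
grouping; in practice counts are exact on noise-free renders and match truth
>99% under default noise.

**Thresholds.** `r_nuclear = 1.5` sits far above the Equal-cell ratio
distribution (1.0-1.05 after blur and noise) and far below the rendered
nuclear enrichment (~2.4 after blur erodes rho = 2.5), so the call is
insensitive to its exact value over a wide range; the boundary value counts
as enriched. Manual scoring in this assay is by eye; the automated calls are
defined to reproduce the same categories and are validated against simulator
truth, not against human annotation.

**Statistics.** Prevalence fractions are per (replicate, age group) with all
four phenotypes reported (they sum to 1 by construction). The paired
two-tailed Student's t-test uses the n-1 sample standard deviation of the
paired differences; a zero-variance difference with nonzero mean is reported
as the limiting p = 0 with a `degenerate` flag rather than an exception.
Stars follow the usual convention (* P<0.05, ** P<0.01). No multiple-testing
correction is applied across a strain library — the screen design relies on
successive re-screening rounds instead; this is noted in the output
metadata by the hit rule itself (z >= 2.5 in *every* round).

**Screen scoring.** z = (median strain ratio - median control ratio) /
(1.4826 x MAD of control per-cell ratios), per round, with a 20-cell floor
per side. The median summary is deliberately robust: it responds only when
the *majority* of a strain's cells shift, which is exactly the planted
nuclear-retention hit profile (~75% of cells nuclear-enriched; measured
z 12-26 against threshold 2.5, null strains |z| < 1). A consequence worth
knowing: a mutant profile that moves only a minority class — e.g. the
NatC-like configuration, where PSG prevalence stays at wild-type values and
only Equal-class mass converts to nuclear retention — cannot move the median
at all, because the PSG class alone holds ~55% of a starved population.
Such shifts are detected by the `summary="mean"` variant (measured z 4.5-11),
which is the configurable alternative; the default stays median-based for
plate-scale robustness.

**CFW gating.** Total CFW per cell is integrated over the cell plus a
boundary halo wide enough to capture scar rings straddling the wall. The
lowest and highest 2.5% tails (exactly `floor(0.025 n)` cells each, stable
tie-breaking) are virtually pure virgin and old-mother pools in simulation
(100% observed at cohort scale), mirroring the flow-sorting verification the
gate models.

## Mutant-profile configurations

`natB_like_config()` raises the Nuclear class and collapses PSG and
Nuclear+PSG to near zero (PSG formation lost); `natC_like_config()` keeps
the PSG class exactly at wild-type prevalence while converting Equal-class
mass to Nuclear and Nuclear+PSG and raising the per-cell enrichment factor
to 3.5 (stronger retention per cell); `nuclear_retention_config()` is the
screen-hit profile (Nuclear 0.55, Nuclear+PSG 0.20 in every age group,
rho >= 3.0). The exact numbers are package defaults chosen to respect the
qualitative directions of the respective knockout phenotypes; only the
wild-type PSG fractions are quantitative anchors.

## Problem sizes used by tests and the acceptance script

Chosen as the package's standard verification workload: the wild-type
cohort is 16 fields x 150 cells (~2400 cells, comfortably above the
1500-cell floor at which the binomial error on a 30-65% fraction is ~2
percentage points); the screen check is one full 96-strain x 3-round
library (640 px fields, 40 cells each) plus repeated scaled-down screens
(4 masters x 16 strains x 2 rounds) for hit-calling error rates; noise-free
fidelity checks use one 150-cell field. The acceptance script derives all
field seeds from its `--seed` argument.

## Known limitations

- Scar counting assumes scars are resolvable rings; heavily clustered scars
  (real old mothers can exceed 8) saturate toward the cap, so absolute
  counts above the OM boundary are indicative only. Age *grouping* is
  unaffected.
- The N:C ratio is a 2D projection measurement; genuine 3D
  nuclear/cytoplasmic volumes are not modelled.
- The screen's median-based z is blind to minority-class shifts (see above).
- Segmentation is classical (threshold + watershed); it assumes mostly
  convex, non-overlapping cells, which holds for spotted/fixed samples but
  not for clumped live cultures.
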