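# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions a maintainer would need.

## AP-MS assembly (`micoskit.apms`)

A bait run is a map from prey protein to spectral counts. Peptides whose
sequence matches several proteins are apportioned before any cross-protein
comparison:

- **proportional** (default): a shared peptide's count is split across its
  matched proteins in proportion to each protein's unique-peptide
  evidence; when no matched protein has unique evidence the count is split
  equally. This conserves the total PSM count.
- **parsimony**: the whole count goes to the matched protein with the most
  unique evidence (lexicographic tie-break for determinism); proteins with
  no unique evidence anywhere are dropped, as in Occam's-razor protein
  inference. Counts of peptide groups in which *no* protein has unique
  evidence are discarded under this policy.

Replicate merging divides by the number of replicates *acquired*, not the
number detecting the prey, so absence in one technical duplicate halves
the average — this is what makes the reproducibility exponent in the
scoring meaningful. Replicate aggregation is the arithmetic mean
("average" peptide spectral matches); a sum-based variant was considered
and rejected because every downstream statistic is scale-covariant in X
and the mean keeps APSM values comparable across panels with unequal
replicate counts.

Stats-table TSVs carry bait/prey ordering and the cell-line label in
comment lines so that read/write is an exact identity, including baits
with no detected preys. Floats are written with `repr` (shortest exact
decimal) and parsed with round-trip precision.

## Interaction scoring (`micoskit.compass`)

For a panel of k baits, with X the APSM matrix and p the
replicate-detection matrix, each prey column j (zeros included) yields
mean x̄_j, sample standard deviation σ_j (ddof = 1, hence k ≥ 2), and
detection frequency f_j. The variability weight is ω_j = max(1, σ_j/x̄_j)
and

    WD[i,j] = sqrt( X[i,j] · ((k / f_j) · ω_j)^p[i,j] ),
    Z[i,j]  = (X[i,j] − x̄_j) / σ_j   (0 when σ_j = 0).

WD therefore rewards abundance, rarity across the panel, column
variability (a prey that is huge in one bait and absent elsewhere), and
replicate reproducibility. NWD rescales WD by the 98th percentile
(configurable) of all positive WD values so that NWD > 1 marks roughly
the top 2% of pairs; the threshold comparison is strict. The percentile
uses linear interpolation on the sorted values. Z-scores are reported but
not used as a default filter.

HCIP filtering is the conjunction NWD > threshold, X ≥ abundance floor
(0 by default; 2 is the conventional choice for small FLAG-tag panels),
and optional membership in a compartment list (e.g. a mitochondrial
protein inventory). Degenerate inputs: a one-bait table and an all-zero
table are rejected rather than scored.

## Network assembly (`micoskit.network`)

Baits are nodes; a bait recovering another bait makes an ordinary edge,
and observation of both directions sets the edge's `reciprocal` flag.
Evidence for the same unordered pair from different baits or cell lines
merges onto a single edge (the validation runs in a second cell line are
evidence about the same interaction, not new edges). Self-hits are
dropped; duplicate (bait, prey, cell line) records are de-duplicated with
a warning. Prey–prey edges can only arise when a prey was itself run as a
bait. Construction sorts entries internally, so the result is invariant
to input order. Exports: edge-list TSV (node roles in comment lines so
isolated baits survive the round trip, per-edge evidence JSON-encoded)
and GraphML via networkx with the same attributes.

## Complexome profiling (`micoskit.complexome`)

**Calibration.** A 20-slice gel from 1000 kDa (slice 1) down to 60 kDa
(slice 20), equally spaced in log10 mass, matching standard BN-PAGE
practice of slicing a lane whose migration is roughly log-linear in
mass. `mass_to_slice` uses half-open [upper, lower) intervals and clamps
out-of-range masses to the terminal slices with a flag.

**Ratios.** The per-protein, per-slice H:L ratio is the quotient of
summed heavy and summed light peptide intensities (median-of-peptide-
ratios is available as `method="median"` for robustness against single
outlier peptides). Scaling both channels of any peptide by a common
factor leaves every ratio unchanged (1:1 mixing invariance). One-channel
cells: light-only gives ratio 0; heavy-only is capped at 100 and flagged,
so heatmaps and window means stay finite; the cap's reciprocal (0.01) is
also the floor applied to zero ratios before log2. Both-absent cells are
missing (NaN), distinct from ratio 0.

**Shift calls.** Windows are ±1 slice around the slice of the mature
(default 700 kDa) and sub-complex (default 500 kDa) masses. With the
default calibration these windows are slices {2,3,4} and {4,5,6}; slice 4
is dominated by the mature band's migration tail, so shared slices are
assigned to the mature window only (sub window {5,6}). Without this
disjointness a depleted mature tail would drag the sub-complex window
mean below the accumulation threshold and mask genuine intermediates.
With m and s the window means of log2 H:L and t = log2 of the total
ratio, and δ = log2 1.5 (a 1.5-fold change, the smallest change
reliably read off a quantitative blot; configurable):

1. `subcomplex_shift` if m < −δ and s > +δ;
2. else `degraded` if t < −δ (global loss without accumulation);
3. else `depleted` if m < −δ;
4. else `no_change`; a window with no quantified slices gives
   `insufficient_data`.

The ordering matters: a globally degraded subunit also satisfies the
`depleted` inequality, and the total-abundance criterion is the more
specific description.

**Heatmap.** log2 ratios on a symmetric green–white–red scale centred at
ratio 1 (green = depleted in the heavy/knockdown channel), missing cells
grey.

## Immunogold statistics (`micoskit.goldmap`)

Distances are straight-line 2D distances in the micrograph plane to the
nearest annotated CJ point (CJs are points, not arcs; projections are
what the microscope records, so no 3D correction is attempted).
Histograms use half-open 50 nm bins — 50 nm is the conventional
"CJ-proximal" cutoff — with an open-ended last bin; fractions sum to 1.

The enrichment test formalises "located within x nm of CJs": the null
scatters the observed number of particles uniformly by arc length along
the annotated cristae membranes (immunogold label is membrane-bound, so
membrane-uniform, not area-uniform, is the right reference), recomputes
the statistic (default: mean nearest-CJ distance), and reports the
one-sided add-one p-value p = (1 + #{null ≤ obs})/(1 + B). The add-one
estimator makes the minimal achievable p equal 1/(B+1) and keeps the null
distribution of p uniform on a lattice, which the calibration test
verifies by Kolmogorov–Smirnov.

## Synthetic data (`micoskit.simulate`)

**AP-MS.** Background preys get a per-prey detection frequency drawn
uniformly from (0.02, 0.6) — panels mix rare contaminants with sticky
ribosomal/chaperone-like proteins — and replicate counts from a negative
binomial with mean 4 and dispersion 2, since spectral counts are
overdispersed relative to Poisson. Planted interactors appear in exactly
their own bait (frequency 1/k) with counts at a programmed multiple
(default 5×) of the background mean and are reproducible by construction
(each acquired replicate has at least one count; acquisition probability
defaults to 1). The generator emulates the *rank structure* of a real
panel — rare-and-abundant versus frequent-and-modest — not peptide-level
properties such as protein length bias, shared-peptide ambiguity, or
correlated contaminant blocks, so recovery results speak to the scoring
statistics, not to protein inference.

**Complexome.** Each subunit's light channel is a mixture of a Gaussian
(in log10 mass, sd 0.03 — so a 700 kDa band spans one to two slices, the
discrete banding seen on BN-PAGE) at the complex mass and a minor
sub-complex component (share 0.1) at 500 kDa, evaluated as band mass per
slice; peptide base abundances are log-normal (sd 0.5). The heavy channel
is light × programmed per-component effect × mean-one log-normal noise
(CV 0.2), so programmed ratios are unbiased and the control channel is
the noise-free reference. Slices receiving under 1e-4 of a peptide's
band mass are unquantified, which produces the missing-cell pattern of
real gels. Not emulated: incomplete isotope incorporation, co-migrating
contaminant complexes, and intensity-dependent missingness.

**Micrographs.** Uniform mode samples arc-length-uniform positions on the
membrane polylines. CJ-concentrated mode picks a CJ uniformly, anchors it
to the nearest membrane position, and walks a half-normal(σ, default
30 nm) arc distance in a random direction, reflecting at path ends;
optional isotropic Gaussian jitter models localization error (antibody +
10 nm gold offset). On straight, well-separated geometry the nearest-CJ
distance equals the programmed displacement, which is what lets the
within-50 nm fraction be checked against the half-normal closed form
erf(50/(σ√2)).

## Problem sizes and tolerances

The recovery experiments run at the sizes the analyses are designed for:
50 baits × 500 background preys with 10 planted pairs for scoring
recovery; 100 seeded simulations each for the knockdown and null
complexome scenarios (nine proteins, five peptides each); 1000-particle
placements for the half-normal check (±0.05 covers ~5 binomial SDs);
200 annotations × 199 null draws for p-value calibration (KS at
α = 0.01). Oracle agreement is asserted at 1e-9, far above float64
accumulation error for these sizes. All randomness flows through
`numpy.random.default_rng` seeds; every generator is byte-deterministic
for a fixed seed.

## Known limitations

- The scoring background model assumes the panel's baits are unrelated;
  panels enriched for one complex weaken the frequency term.
- The NWD normalizer is a percentile of the analysed panel itself, so
  NWD values are not comparable across panels scored separately.
- The shift caller reads two fixed mass windows; it does not fit full
  migration profiles and will miss intermediates that co-migrate with the
  mature complex.
- The enrichment test conditions on the annotated geometry; unannotated
  membranes bias the null toward the annotated regions.
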