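# Methods

## The locus model

The package models a single ~25.5-kb genomic segment as a 1-based, fully
closed coordinate system (`Chr3:6372413..6373650` style; BED writers
convert to 0-based half-open and this conversion is unit-tested). The two
low-copy repeats (LCRs) are direct, non-overlapping 1238-bp copies whose
alignment differs at 11 paralogous sequence variants (PSVs). Two PSV
offsets are fixed by the homology-track structure of the repeat — sites at
231 and 769 delimit uninterrupted identity tracks of 230 and 537 bp in the
5' half — while the remaining nine sites accumulate in the 3' half of the
alignment and are placed at evenly spaced offsets 810–1210 (step 50). All
PSV positions and alleles are configuration-overridable; every geometric
result that depends only on the two printed offsets is insensitive to this
choice.

NAHR geometry is pure arithmetic: recombination between the repeats
removes `right.start − left.start` bp (one repeat plus the intervening
block, 4955 bp at the default coordinates), so the deletion-junction
amplicon is the no-deletion amplicon minus that quantity. The
duplication-junction amplicon length (3404 bp) is a locus-map constant
rather than a derived quantity because the duplication primers anneal in
sequence that exists only in rearranged genomes; extended duplications add
their extension length.

The 11 isolated PSVs partition the alignment into 12 breakpoint-
localization bins (before the first site, between consecutive sites, after
the last). Published descriptions of this repeat count "10 intervals",
which cannot be reconciled with 11 isolated sites without unprinted
adjacency information; the package reports all maximal identity tracks and
all 12 bins, and breakpoint results are expressed as (lower, upper) offset
pairs so they remain correct under any binning convention.

## Synthetic panel

The generator's defaults are the study conditions: a 189-accession panel
with 67 `basic`, 101 `del-2`, 1 `dupl-1`, 9 `dupl-2`, 6 `dupl-3-a` and 5
`dupl-3-b` accessions, with fixed per-pattern copy-number rosters that
reproduce the per-gene cluster structure (MSH2 2/4/6/≥8 copies in
177/5/2/5 accessions; block 0/2/4/6/≥8 in 101/68/10/3/7). Accessions are
homozygous inbred lines, so all copy numbers are even and one haplotype
represents the genome; MSH2 deletions never occur. Deletion-junction
breakpoints fall in the first PSV bin and duplication junctions mostly in
the second, with small configurable fractions carrying gene-conversion
toggles or the 790-bp extended duplication joined at a planted 9-nt
microhomology. Country labels are drawn uniformly from twelve region
names; no geographic autocorrelation is modelled.

MLPA signals follow a one-parameter saturating dose response
`S(c) = s0·(c/2)/(1 + σ(c/2 − 1))` with σ = 0.108, chosen analytically so
the calibrated ratio at 12 copies is ≈ 3.9 — the regime in which cluster
spacing shrinks and the assay stops resolving integer steps. Zero copies
emit a background of 0.01·s0. Noise is multiplicative lognormal at CV 5%
per measurement (no quantitative noise model is published for this assay;
5% keeps the control-probe SD comfortably inside the < 10% QC bound)
plus a lognormal per-sample scaling factor at CV 10% so control-probe
normalization is actually exercised. dupl-3-b accessions get a 2× boost on
probe mlpaD.

ddPCR wells draw positives as `Binomial(N, 1 − e^(−λ))` with
λ = λ_ref·c/2, N = 18,000 droplets per well, λ_ref = 0.3 copies/droplet
for a two-copy locus and λ_NTC = 0.001 for no-template controls. Droplet
volume and DNA mass are abstracted into λ_ref since only rate ratios
enter the copy-number estimate; a droplet-volume constant is configurable
for users who want absolute copies/µl.

Pseudogenomes are reference-projected sequences with uncalled sites as N:
deletion accessions have the whole repeat+block span masked, everyone
receives background N noise (default 3%). SNP matrices cover two 20-kb
flanking windows with per-site MAF uniform on [0.10, 0.50], 5%
missingness, and alleles drawn independently of CNV pattern, so SNP–CNV
LD is sampling noise by construction (an `ld_rho` parameter can create
local LD blocks).

What the generator does **not** emulate: read-level sequencing error,
alignment artefacts at breakpoints, heterozygotes, population structure,
and geographic autocorrelation of genotypes. Passing round-trip tests
therefore demonstrates internal consistency of the callers under the
stated noise model, not robustness to every failure mode of real
electropherograms or WGS data.

## Analytical choices

- **Normalization/calibration order.** Peaks are divided by the
  within-sample control mean, then by the calibrator's normalized values;
  both steps are scale-invariant and idempotent, and the calibrator's own
  ratios are 1 by construction.
- **QC.** FAIL at control-probe CV ≥ 10%; WARN (retained) when any control
  ratio leaves [0.8, 1.2] — observed single-probe deviations to 0.67/1.38
  are tolerable. Report-only.
- **Gene states and CN.** Categorical states use probe means (MSH2:
  mlpaB/C; block: mlpaD–G) with strict thresholds, ties resolving to
  normal. Integer block CN uses the interior probes mlpaE/mlpaF only; the
  outer probes mlpaD/mlpaG sit near variable breakpoints and feed a
  discordance flag (|Δ| > 0.5 with neither ratio near zero). The
  dupl-3-a → dupl-3-b upgrade triggers at mlpaD > 1.5× mean(mlpaE–G); no
  published boundary exists, so the factor is configurable.
- **Clustering.** Manual 2-D cluster reading is replaced by deterministic
  1-D largest-gap clustering (minimum gap 0.35 ratio units) on the probe-
  pair mean, labelled 0/2/4/6/">=8" ascending and anchored at the
  calibrator's cluster = 2. Labels stop at 6 because cluster spacing
  decreases with copy number; at 5% CV the 6-vs-≥8 boundary can blur, and
  the tests only assert the combined high-copy group there.
- **ddPCR merging and rounding.** Replicate wells are pooled (counts
  summed) before λ estimation, preserving the Poisson likelihood, rather
  than averaging per-well λ. `cn_int` rounds to the nearest integer — the
  assay resolves single-copy steps; evenness is a property of the panel,
  not the estimator. Fully positive wells raise a distinct saturation
  error instead of returning a clamped estimate.
- **Repeat search.** BLASTN windowing is replaced by an internal k-mer
  seed (k = 16), same-diagonal chaining (gap ≤ 400 bp), exact outward
  extension and identity filtering (≥ 0.9 over ≥ 500 bp), for both direct
  and inverted orientations. Planted-repeat simulations define
  correctness: recovery is exact on the default locus across seeds, with
  zero hits on repeat-free sequences of equal composition.
- **Junction painting.** PSVs are anchored by exact 7-bp flanking contexts
  (PSV spacing ≥ 41 bp guarantees context uniqueness at the defaults); a
  fallback accepts one substitution anywhere in the context while
  requiring the PSV base to match exactly, since scattered substitutions
  near breakpoints are expected. Paintings with < 50% callable PSVs fail.
  Flank sequences outside the repeat act as pseudo-calls at the alignment
  bounds, which is what localizes junctions whose PSVs all derive from a
  single parent (first and last bins).
- **Conversion masking.** The minimal set of PSV flips making the call
  vector a single monotone switch is found by scanning all cut positions
  (linear, versus the exponential subset oracle used in tests); among
  minimal sets, ties resolve to the sites nearest the resulting switch, on
  the rationale that conversion tracks border the exchange region.
- **LD.** Accessions are treated as haploid (inbred homozygous), so R² is
  the squared Pearson correlation of 0/1 indicators over co-called
  accessions; on complete data this equals the haplotype
  D²/(p_A p_a p_B p_b) formula (verified exhaustively on small tables).
  CNV patterns enter one-vs-rest, reporting the per-SNP maximum.
- **Missingness classifier.** The evaluation region defaults to the
  inter-repeat block (left LCR end + 1 to right LCR start − 1); the call
  threshold is inclusive at 0.80. Frequencies print at 2 decimals with a
  1-decimal prose mode.

## Problem sizes and determinism

Every generator is a pure function of (config, seed); one master seed
spawns per-stage substreams via `numpy.random.SeedSequence`, so stages
re-run independently and the pipeline report is byte-identical at a fixed
seed. The test suite and the acceptance script use the study-scale sizes
throughout — 189-accession panels, 18,000-droplet wells (3–10 replicates),
a 1135-accession pseudogenome panel, 200–300-SNP matrices — which keeps a
full run in the tens of seconds on one CPU.

## Known limitations

- Breakpoint mechanics are modelled only for the deletion and the
  block duplication; the composite dupl-3 genotypes are generated as
  plain tandem copies without junction semantics, and their mechanism is
  not analysed.
- The painting engine is ungapped: indels inside the repeat would defeat
  exact-context anchoring (the fallback tolerates substitutions only).
- Network construction (NeighborNet) and LD visualization are out of
  scope; the package emits Nexus input for external tools instead.
- MLPA integer calls above six copies are reported only as ">=8"; that is
  a property of the assay's saturating response, not of the caller.
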