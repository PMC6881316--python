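# Methods

## Scope and model

The package implements a replicate biotyping workflow over linear-mode
protein mass fingerprints: preprocessing of profile spectra, consensus
(main-spectra-projection) reference building, correlation-distance
clustering, log-score identification, and a commercial-label audit. A
synthetic-spectra generator stands in for raw instrument data, emulating a
market survey of 34 truffle specimens across seven *Tuber* species.

## The generator

Each species is a *panel*: `peaks_per_species` (default 40) peak masses
drawn uniformly on the 2–20 kDa acquisition window with a minimum spacing
of 25 Da (an exact shrunken-interval construction), and relative abundances
drawn log-normally with unit median (σ = 0.6). Sister species in a complex
share a configurable fraction of peak positions (default 0.5): a master
position set with global minimum spacing is drawn for the whole group and
partitioned into shared and private subsets, so the overlap is exact to
within one peak and shared masses never collide with private ones. In the
study fixture the complex is *T. indicum* / *T. longispinosum* /
*T. himalayense*.

A replicate spectrum is rendered on a uniform grid (1 Da step) as

    x(m) = Σ_k A_k · G(m; μ_k(1+δ), FWHM = μ_k / R) + b₀·e^{−(m−2000)/τ} + ε

with Gaussian peak shapes at resolution R = 600 (m/Δm, typical linear
mode), a single per-spectrum calibration offset δ ~ N(0, 300 ppm), an
exponentially decaying chemical baseline (b₀ = 50 a.u., τ = 3000 Da),
additive noise ε ~ N(0, 1 a.u.), and clipping at zero. The amplitude
A_k = 100 a.u. × (panel abundance) × (specimen, biological-replicate and
technical-replicate log-normal multipliers, each with CV 0.25), zeroed
with dropout probability 0.05. The peak amplitude, noise, and baseline
scales are not prescribed by the emulated protocol; they were fixed once
at values giving apex signal-to-noise in the tens-to-hundreds, the regime
in which fingerprint biotyping is actually practised.

Biological and technical replicates share the generative model; biological
replicates carry one extra multiplier layer. Mislabeled specimens are
declared in the design table (marketed ≠ true species), never drawn at
random, so ground truth is always known. All randomness flows from one
seeded generator in a fixed order; identical configuration and seed give
byte-identical serialized studies.

What the generator does **not** emulate: isotopic fine structure, detector
saturation, matrix-cluster ions, non-uniform (quadratic TOF) m/z grids,
mass-dependent intensity roll-off, and correlated (pink) noise. Passing
tests therefore demonstrate the pipeline's internal correctness and its
calibration on idealized replicate structure, not performance on real
instrument exports.

## Preprocessing

Stages run in a fixed order — trim → smooth ×2 → top-hat → TIC-normalize →
noise estimate → pick — and contain no randomness.

- **Window widths in Da** are converted to odd point counts via the median
  grid spacing, so non-uniform grids are supported. A width below one grid
  spacing degenerates to the identity (nothing to smooth).
- **Savitzky–Golay**: 5 Da window read as full width, polynomial order 3,
  two passes, polynomial edge handling. The filter reproduces polynomials
  up to its order exactly; tiny undershoots are clipped at zero.
- **Top-hat**: the baseline is the morphological opening (erosion then
  dilation, flat element, default 500 Da — wide against linear-mode peak
  widths of ≤ 33 Da at 20 kDa, narrow against the baseline decay). The
  signal is padded by half an element width with a linear extrapolation of
  the terminal trend before filtering; a plain opening cannot follow a
  monotone baseline at the spectrum edges and leaves a spurious edge hump
  (~8 % of b₀ at the low-mass edge in the baseline model above). The
  corrected signal is the non-negative residual and the decomposition
  reconstructs the input to machine precision.
- **Noise**: 1.4826 × MAD of the first-differenced signal divided by √2
  (differencing doubles the variance), in 10 equal windows, interpolated
  to every grid point. The estimator is robust to isolated spikes.
- **Peak picking**: strict local maxima with S/N ≥ 3; apexes closer than
  5 m/z (read as a minimum apex separation, the parameter's observable
  effect) are resolved greedily — higher intensity wins, ties to lower
  m/z; at most 150 peaks, most intense first. The picker is
  oracle-equivalent to an exhaustive reference implementation.
- **TIC normalization** (sum of intensities = 1) makes intensities
  comparable across spectra; it was chosen over base-peak normalization
  because it is robust to single-peak dropout. S/N is unaffected.

## Consensus reference spectra

Replicate peak lists are restricted to 3–15 kDa and renormalized to unit
sum (so replicates contribute comparably regardless of how much of their
signal the window retains), pooled, and binned by single linkage: walking
in ascending mass, a peak joins the open bin while its gap to the bin's
intensity-weighted centroid is within 2000 ppm. Within a bin at most one
peak per source survives (closest to the centroid; ties to lower mass,
then higher intensity). Each bin reports the consensus mass rounded to
200 ppm precision, the mean normalized intensity (summed in sorted order,
so the result is independent of replicate numbering), and the frequency =
contributing sources / all sources. Bins under 25 % frequency are dropped;
if more than 70 survive, frequency, then mean intensity, then mass decide.

Two tolerances appear in the emulated protocol without stated semantics;
here 2000 ppm governs cross-replicate binning and 200 ppm is the reported
precision of the consensus mass, matching their magnitudes. Single-linkage
centroid binning avoids the edge-split artifacts of fixed-grid binning,
at a known cost: when pooled peaks are dense (many source lists, heavy
noise), chains can bridge neighbouring true peaks — at 2000 ppm the window
(20 Da at 10 kDa) approaches the 25 Da panel spacing above ~12.5 kDa.
This blurs consensus masses but is neutral to ranking and clustering,
which compare spectra through the same binning. Libraries can be built
per specimen (default; 34 leaves for the dendrogram) or per species
(pooling all of a species' replicate lists; used for identification).

## Clustering and the audit

Consensus spectra are compared by d = 1 − Pearson r over the union of
their binned peak intensities (absent = 0), range [0, 2]; a constant
vector leaves r undefined and d = 1 (uninformative). `d = 1 − r` is used
rather than (1 − r)/2 as the most direct reading of "correlation
distance". Average linkage (UPGMA) is monotone, so merge heights never
decrease. The flat cut is chosen by maximizing the mean silhouette width
over k = 2…12 (ties to smaller k) — an automated substitute for reading
clusters off a dendrogram by eye; a fixed k can be forced on the CLI.
Concordance with the molecular assignments is the adjusted Rand index
plus per-cluster purity.

The audit needs name semantics, not spectra: `T. uncinatum` is a junior
synonym of `T. aestivum` (applied always), and the *T. indicum* complex
has an accepted-sale set, declared in a policy file
(`spectratype/data/default_policy.toml`), not in code. Under the
**lenient** policy a complex member sold under the nominal name is a
mislabel only if the assignment falls outside the accepted set
{*T. indicum*, *T. longispinosum*}; under **strict**, only exact canonical
matches pass. On the packaged roster the two tallies are 9/34 (26 %) and
10/34 (29 %, with 4/6 = 67 % of the marketed-*T. indicum* subgroup) — the
policies exist precisely because both tallies are defensible accountings
of the same roster, and both are reported.

## Identification score

score = log₁₀(1000 · s1 · s2 · s3) clipped to [0, 3], with s1 = matched
fraction of query peaks, s2 = matched fraction of reference peaks, s3 =
(r + 1)/2 over matched intensities (s3 = 1 with fewer than three matches
or constant vectors; (r+1)/2 rather than r² so anti-correlated intensity
patterns are penalized, not rewarded). Matching is greedy one-to-one:
query peaks by descending intensity, each to the nearest unmatched
reference peak within 2000 ppm of the reference mass. The query is first
restricted to the library's 3–15 kDa window: reference entries carry no
information outside it, so out-of-window query peaks would only dilute s1
(`ScoreParams(mass_range=None)` restores the unrestricted form).

Fixed points: self-match = 3 exactly, disjoint = 0, half-overlap with
agreeing intensities = log₁₀(250) ≈ 2.398. Thresholds follow the
biotyping convention: ≥ 2.0 species-level, 1.7–2.0 low-confidence, < 1.7
unreliable. The score's structure follows the published description of
the commercial composite score; its numeric values on real data are not
claimed to equal any proprietary engine's.

## Problem sizes and numerical choices

The study-scale experiments run 204 spectra of 18 001 points each
(~10 s for the full pipeline); property tests use 300-point spectra and
8-leaf matrices; seed-sweep checks (species recovery in ≥ 18/20 seeds,
noise monotonicity, score separation) run 20 seeds at study scale or on
reduced 2–3-species studies with a coarser grid. Tie-breaks are fixed
everywhere (intensity desc, then mass asc; labels lexicographic), so every
stage is order- and permutation-invariant and byte-deterministic.
Degenerate inputs fail loudly: empty trims, all-zero spectra, empty
consensus output, NaN distances and synonym cycles all raise with
diagnoses rather than propagating silently.

## Known limitations

- The generator's idealizations listed above; in particular real Bruker
  grids are non-uniform, which preprocessing supports but the generator
  does not produce.
- Single-linkage chaining at 2000 ppm can merge true neighbouring peaks
  at high mass (see above).
- The silhouette criterion assumes clusters of at least two members score
  0; a species represented by a single specimen contributes no silhouette
  support of its own.
- Scores are calibrated on synthetic replicate structure; absolute score
  values on real spectra will differ from any proprietary engine's.
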