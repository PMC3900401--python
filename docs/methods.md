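# Methods

This note records the models, numerical choices and limitations behind each
module, and what the synthetic generators do and do not emulate.

## Evolutionary trace

**Score.** The real-valued evolutionary trace implemented here is
`rho_i = 1 + Σ_{n=1}^{N-1} (1/n) Σ_{g=1}^{n} s_ig`, where at partition
level n the tree is cut into the n groups obtained by removing its n-1
highest internal nodes (root first), and `s_ig` is the natural-log Shannon
entropy of the amino-acid frequencies `f_ia^g` of column i over the non-gap
rows of group g. The 1/n level weight down-weights deep partitions, so full
invariance (every `s_ig = 0`) is the unique minimum rho = 1, and variation
that respects early tree splits scores better than variation that cuts
across them. Only the ranking matters downstream, so the entropy base is
irrelevant; natural log is used. This is one member of the real-valued
trace family; the package treats the exact level weighting as a design
choice, not a canonical constant, and it is isolated in `trace_scores`.

**Tree.** UPGMA on identity distances
(d = 1 − matches / co-non-gap-columns; a pair with no co-non-gap columns
gets d = 1 with a warning). UPGMA is deterministic given the tie rule —
ties on the merge distance go to the candidate pair with the
lexicographically smallest (then second-smallest) member id — and yields
the rooted, height-ordered nodes the partition rule needs. The same
smallest-leaf rule breaks height ties when cutting. UPGMA is implemented
in-package because the partition logic needs explicit node heights and a
documented tie-break; unit tests cross-check its merge heights against
scipy's average-linkage.

**Gaps.** Frequencies are computed over non-gap rows only; an all-gap group
contributes entropy 0. Gaps carry no amino-acid type, so they neither count
as a 21st letter nor penalize a group.

**Clustering significance.** The observed statistic is the number of
selected-residue CA–CA pairs within a cutoff (default 12 Å); the null
re-draws equally sized residue sets uniformly from the structure (default
1000 permutations, seedable). The z-score is reported rather than a
permutation p-value because typical selections saturate the null tail.
A null with zero variance (e.g. a structure where no subset ever has a
contact pair) is rejected rather than reported as an infinite z.

**Numbering.** Columns and residues are 1-based; structure mapping is an
explicit integer offset (residue = column + offset).

## Synthetic domain family

The generator evolves an ungapped alignment along a balanced bifurcating
tree. Internal node heights are the clade size plus a small exponential
jitter: heights stay strictly decreasing from the root, so the first
n-1 cuts always recover the natural top-level clades (which the
class-specific planting relies on), while branch lengths still vary
stochastically. Mutations are per-branch Bernoulli events per site with a
uniform proposal over the 19 other letters. Planted columns are imposed
after evolution: invariant columns get one letter everywhere;
class-specific columns get one distinct letter per top-level clade. When
the substitution rate is positive, a freely evolving column that comes out
residue-constant across all leaves has one leaf flipped, so the planted
truth is exactly recoverable by a column scan (at rate 0 this fix is
skipped and all sequences are identical, the degenerate limit). The
defaults (32 sequences × 300 columns, rate 0.05/branch) are stand-ins for
a curated dioxygenase-family alignment, not a reconstruction of it; real
alignments have gaps, rate heterogeneity and non-balanced trees, so
passing tests show correctness of the scoring machinery, not performance
on hard homology data.

The toy structure places selected residues uniformly inside one ball
(radius default 8 Å, so pairwise distances ≤ 2r) and the rest on a
self-avoiding 3.8 Å-step random walk starting well away from the cluster;
coordinates are rounded to 0.001 Å so PDB round-trips are exact. It makes
no attempt at protein-like packing beyond a 3 Å exclusion.

## Three-point bending

**Beam model.** The simulator emits a piecewise-linear elastoplastic
response: zero load over a toe region, elastic rise at stiffness k to the
yield load Fy, post-yield rise at slope k2 < k to the failure displacement,
then load drops to zero; Gaussian noise of a chosen sd is added to every
load sample. Closed-form truths are recorded both at the bilinear corner
(yield = Fy, elastic energy = Fy²/2k) and — via `BeamTruth.offset_truth` —
for the offset construction itself, whose ideal intersection sits past the
corner at x* = Fy/k + k·δ/(k−k2) with load F* = Fy + k·k2·δ/(k−k2).
Recovery is judged against the offset closed forms, because that is what
the offset method measures even on a perfect record.

**Pipeline.** Analysis region = first sample at/above the preload (default
0.5 N, configurable; the preload magnitude is a lab choice) up to the
maximum load. Stiffness is the maximum least-squares slope over sliding
windows (default 10 % of the region, minimum 5 samples); the same fitted
line, translated by the displacement offset (default 0.00876 mm, exposed as
a flag), defines the offset yield. The crossing is located on the
difference (curve − line) smoothed with a centered moving average
(`persistence` samples, default 3): a sample-wise first-crossing rule is
biased early under load noise, while a symmetric window is unbiased when
the difference is locally linear — which it is, provided the smoothing
half-width stays inside the offset region; callers with dense records
should scale `persistence` accordingly. The yield load is read off the
offset line at the crossing (curve and line coincide there). Failure is
the first sample after maximum load with load ≤ 0; if the load never
returns to zero the record end is used and flagged censored. Energies are
trapezoids with the interpolated yield point inserted on both region
boundaries; energy/displacement/toughness additivity identities hold
exactly by construction.

**Stress and strain.** σ = F·L·c/(4I) and ε = 12·c·D/L² with c = h/2.
These are the mutually consistent outer-fibre forms for a centrally loaded
simply supported beam: a beam with k = 48·E·I/L³ yields a σ–ε slope of
exactly E. Because σ, ε are fixed multiples of F, D, intrinsic properties
are computed from the extrinsic ones by those multiples — identical to
re-running the fits on the transformed curve, and exactly additive. The
coefficients are module constants so an alternate convention is a
one-line change. The claimed equivalence of the 0.00876 mm offset to a
0.2 % offset strain depends on specimen diameter and is not enforced.

**CSMI.** I = Σ_foreground (y − ȳ)² · pixel⁴ about the centroidal bending
axis (loading direction = image rows by default); h is the foreground
extent along that axis. The per-pixel self-inertia term (area·px²/12) is
deliberately omitted — it vanishes quadratically with pixel size and keeps
the single-pixel degenerate case at exactly 0. Annulus masks converge to
π(r_o⁴−r_i⁴)/4 well inside 0.5 % at 5 µm pixels.

**Recovery-study conditions.** The parameter sweeps simulate a 0.05 mm
toe, k2 = 0.4k, post-yield extent 50/k mm (keeping the maximum load well
above the noise-extreme bias of a raw max), sampling step xy/400 where
xy = Fy/k (a constant 400 samples across the elastic rise), a 300-sample
fit window, smoothing span about a third of the offset-region width,
preload 0 for noiseless runs and 0.5 N for noisy runs. Noiseless recovery
is then limited only by corner discretization (≤ 0.1 %); with 0.2 N noise
the seed-averaged errors are dominated by the steepest-window bias and
preload-trim area and stay under ~2 %.

**Units.** mm, N, MPa, N·mm throughout; no unit inference from files.

## PTM occupancy and cross-links

m/z = (M + Σ shifts + z·1.00728)/z with monoisotopic shifts +15.9949
(Hyp/Hyl), +162.0528 (Gal), +324.1056 (GlcGal), all fixed in one constants
table at 4 decimals. Ion matching sums peak intensities within a ppm
tolerance (default 250 ppm, ion-trap-era resolution; configurable); an
ambiguous peak goes to the nearest target with a warning, ties to the
lower index. Occupancy = 100 · Σ modified / Σ all, scale-invariant by
construction. The isobaric correction keeps the 4-Hyp share φ of the +16
ion in the denominator (it is the same tryptic peptide, differently
modified); the alternative convention (exclude it from the total) is a
flag, since the source procedure is stated only as "taken into account".
When several charge states are observed, per-state occupancies are
averaged weighted by state total intensity, which equals pooling the
intensities. HP/LP response factors default to 1 (relative quantitation);
an LP of zero leaves the ratio undefined rather than infinite.

The scan simulator plants one peak per variant with multiplicative
log-normal noise (mean-1 normalization, so zero-noise recovery is exact to
machine precision); it does not emulate isotope envelopes, chromatographic
elution or charge-state envelopes, so matching tolerances and averaging
behavior on real spectra are exercised only in the arithmetic sense.

## Morphometry statistics

Summaries are mean ± sample SD (n−1); single-measurement groups are
flagged rather than given SD 0. The two-sample test is Student's pooled-
variance t (two-sided) matching the source study's stated test; Welch is a
flag. Fibril-diameter histograms use user-supplied half-open bins with
explicit underflow/overflow so proportions always sum to 1. The
small-fibril comparison aggregates to per-animal fractions before testing:
with the default design (15 fields × 10 fibrils = 150 fibrils per animal,
3 animals per genotype) a per-fibril test would pseudo-replicate ~50-fold.
Whether the original fibril comparison was computed per fibril or per
animal is not stated in the source; per-animal is the defensible default
and the difference matters for borderline p-values.

## Known limitations

- No maximum-likelihood or Bayesian trees, and no integer-valued
  (original-flavor) trace variant.
- The bending pipeline assumes a monotone displacement ramp and a single
  yield; cyclic or multi-peak records are out of scope.
- No peptide-spectrum matching, fragment prediction or peak detection; the
  φ fraction must come from external MS/MS evidence.
- No mixed-effects models or multiple-testing correction in the statistics
  module (none were used in the source study's design).
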