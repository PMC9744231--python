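# Methods

## smFRET trace model and correction

A two-color smFRET trace from an immobilized chromatin fiber is modeled
as donor and acceptor photon counts per camera frame. With true transfer
efficiency E and total detected intensity I (photons/frame, arbitrary
units), the ideal channels are F_D = I·(1−E) and
F_A = γ·I·E + β·F_D, where β is the fraction of donor emission leaking
into the acceptor channel and γ the acceptor/donor detection-efficiency
ratio (donor detection efficiency normalized to 1). Inverting this model
gives the corrected efficiency used throughout:

E = (F_A − β·F_D) / (F_A − β·F_D + γ·F_D).

Defaults β = 0.161 and γ = 0.436 are the calibration of the reference
instrument and can be overridden per dataset, either directly or by the
bleach-step estimator below. γ is applied globally (one value per
dataset); a per-molecule mode exists but is off by default because a
single fixed calibration is the normal operating mode.

Numerical choices: E values are clamped to [−0.2, 1.2] (noise pushes
E slightly outside [0, 1] and the histograms must admit small negative
values); frames whose denominator magnitude falls below 10⁻⁶ times the
median total intensity are masked out; when bleach events are supplied,
only frames strictly before the first event of either channel count as
valid, because the correction assumes both dyes active.

## Photobleach detection and γ calibration

Each channel is scanned by greedy binary segmentation with a
least-squares cost; a split is accepted when its error reduction exceeds
a BIC-like penalty 2σ²·log n, with σ the robust per-frame noise
(1.4826·MAD of first differences / √2). The bleach candidate is the
first drop of at least `min_step` (default 6σ) whose level never
recovers. Ties between equal-cost splits break to the earliest frame so
output is deterministic. An acceptor-channel drop within 2 frames of a
donor-channel drop is attributed to donor bleaching — the acceptor goes
dark because excitation transfer stops, not because it bleached.

γ is the median over molecules of ΔF_A,bleach/ΔF_D,bleach at acceptor
bleach events, with the median absolute deviation as dispersion; events
with a nonpositive donor rise are excluded and counted. Both steps are
measured as means over symmetric 20-frame windows around the
changepoint. One subtlety: the acceptor step is measured on the
leakage-corrected channel F_A − β·F_D. On the raw acceptor channel the
leakage pedestal rises together with the donor at the bleach, so the raw
step ratio equals γ−β rather than γ; correcting for leakage first makes
the ratio an unbiased estimate of γ under the forward model above.

## Population histograms and Gaussian decomposition

Histograms pool all valid frames across molecules with equal per-frame
weight (time-averaged histograms; a per-molecule-mean mode is provided
as an option), over [−0.2, 1.2] with bin width 0.02 — fine enough to
separate centers at 0.34 and 0.66 with ~2000-frame traces. "Density" is
per-bin probability mass and sums to 1; lists of lists of traces are
treated as independent repeats whose densities are averaged with equal
weight. The decomposition fits y(x) = Σ Aᵢ·exp(−½((x−cᵢ)/dᵢ)²) for one
or two components by bounded nonlinear least squares on the binned
densities (A ≥ 0, d > 0, c inside the data range), multi-started from
quantile-based center pairs to cope with the shallow two-peak surface;
standard errors come from the Gauss–Newton covariance. A two-component
fit whose smaller amplitude is below 1% of the larger is flagged
effectively unimodal. A maximum-likelihood EM mixture on raw values is
provided purely as a cross-check mode. Components are labeled open when
c < 0.1; the rest split at c = 0.5 into medium and high (the 0.5 split
is this package's convention — the states it separates are exemplified
by centers near 0.34 and 0.66). Population fractions are normalized
component areas Aᵢ·dᵢ·√(2π).

## Spike-in normalization

Each sample's coverage is multiplied by
scale = spikein_reads_reference / spikein_reads_sample, with the
reference (the wild-type sample of the matching stage) fixed at 1. This
makes the spike-in signal equal across samples, so genuine global gains
in the target genome survive normalization while sequencing-depth
differences cancel. Rescaling any non-reference library together with
its spike-in reads leaves every fold change exactly unchanged; rescaling
the reference rescales the absolute normalized level of all samples (by
construction), which interacts only with the pseudocount term of the
fold-change definition.

## Segmentation and classification

Domain-scale marks are segmented by a 3-state Gaussian-emission HMM on
log(coverage + 0.5) after a 1-kb moving-average smoothing (default bins
200 bp). Initialization is deterministic — emission means at the 0.30,
0.645 and 0.99 quantiles, shared variance, sticky transitions (0.99
self-transition), uniform start — and there are no random restarts, so
segmentation is a pure function of track and parameters. After EM,
states are ordered by emission mean; states whose means differ by less
than 0.5 log-units are collapsed onto one level so that a track with
only two real levels (background + one enrichment tier) does not have
its background split in two. When only two levels survive they map to
the extreme labels (none/high, low/high). Viterbi segments shorter than
`min_domain_length` (default 1 kb) are absorbed, shortest first, into
the flanking level whose emission mean is closer to the segment's
observed mean. A constant track returns one background-level domain per
chromosome with a warning.

Point-source peaks (Pho at PREs) are called per bin by a Poisson test
against the maximum of the global mean and local means in ±5-kb and
±10-kb windows (on the control track, depth-rescaled, when one is
given), with Benjamini–Hochberg control at q < 0.01; significant bins
within 1 kb merge, and the summit is the center of the highest bin.

Classification: high-H3K27me3 domains containing ≥ 1 Pho summit are
canonical; intermediate domains are noncanonical; high domains without
Pho are also noncanonical but flagged for review rather than silently
forced (Pho absence in a high domain is unusual but not impossible);
H3K27me3-free intervals are subdivided at H3K36me2 domain boundaries and
pieces covered ≥ 50% by an H3K36me2-enriched domain become active; the
remainder is neutral. The output partitions the genome. Coordinates are
0-based half-open everywhere; marks are unstranded so strand is ignored.

## Quantification

Gene-body coverage is the length-weighted mean of bin values overlapping
the gene (partial bins weighted by overlap fraction); a gene's chromatin
class is the annotation label at its midpoint, matching the one-class-
per-gene coloring of gene-level scatter plots. Fold changes use
FC = (mut + pc)/(wt + pc) with pseudocount pc = 0.5 normalized-coverage
units — enough to stabilize near-empty bins without materially
distorting 20–30-fold signals (at background coverage 10 it biases a
20-fold gain to ≈ 19.1, visible in the recovery numbers). Class
summaries use the median, robust to the long right tail of per-gene
fold changes. Metaprofiles rescale each domain body to 50 meta-bins by
linear interpolation, add 25 fixed-width flank bins per side (default
5 kb flanks), weight domains equally and drop flank bins that fall off
the chromosome. The accessibility/H2Aub1 scatter computes both log2 fold
changes per region with the same pseudocount rule.

## Synthetic data: what it emulates, what it does not

Trace generator: conformational switching is a discrete-time Markov
chain with geometric dwells (default mean 100 frames) over user E
levels; acquisition defaults are 2000 frames at 100 ms. Bleaching is a
single irreversible step per channel at a caller-chosen frame; after
acceptor bleach the donor reverts to full intensity and the acceptor
keeps only the leakage pedestal; after donor bleach both channels go
dark. Noise is additive Gaussian per channel (default sd 20 at
I = 1000) — deliberately not a camera model: no EMCCD gain, shot noise,
background fluorophores, blinking, baseline drift or slow bleaching.
Passing tests therefore demonstrate correctness of the inversion,
detection and fitting machinery, not robustness to every instrumental
artifact of real movies.

Genome generator: planted non-overlapping class domains with neutral
gaps, PRE point positions (each canonical domain is guaranteed one),
genes tiled so every class is represented, and per-bin counts drawn
Poisson — or negative binomial with variance μ + α·μ² when a dispersion
α is given — around background_rate × multiplier(mark, class, genotype),
with a "pre" pseudo-class for point-source gains. Spike-in reads are
derived from the realized target total so counts are partitioned, never
resampled: spike = round(f/(1−f)·total). For genotypes sharing spike-in
material with a reference, the implied spike-in fraction shrinks as the
sample's expected target yield grows (f_s = S/(S + T_s)); this is what
makes global biological gains recoverable after normalization. The
generator does not simulate reads, fragment-length effects, mappability,
GC bias or replicate structure.

Standard study conditions (`caly_like_design`): one 600-kb chromosome,
200-bp bins, background 10 reads/bin, two canonical domains (50 kb and
30 kb; H3K27me3 ×8, Pho ×40 at PREs), one noncanonical domain (40 kb;
H3K27me3 ×3), one active domain (60 kb; H3K36me2 ×6), wild-type
spike-in fraction 0.1; the mutant genotype carries H2Aub1 ×4 genome-wide
and ×20 over canonical domains plus ATAC ×2 over canonical domains —
the signature of losing H2A deubiquitinase activity. Problem sizes in
the test-suite and the acceptance script (40–100 molecules of 2000
frames, 10–20 genome seeds, 10⁵ pooled frames per histogram) were chosen
so each recovery statistic is comfortably inside its tolerance band
while the whole run stays desk-scale.

## Known limitations

- The HMM assumes three or fewer genuine coverage levels per mark; finer
  hierarchies are collapsed.
- The peak caller's local background includes the peak bin itself, which
  slightly deflates enrichment estimates for very broad peaks (PRE-scale
  peaks are unaffected).
- γ estimation requires observed acceptor bleaching; datasets without it
  must fall back to a fixed calibration (the estimator raises and says
  so).
- The bleach detector models one irreversible step per channel; blinking
  dyes can be misread as early bleaching.
- Bin-level simulation cannot expose artifacts that originate below bin
  resolution (e.g. fragment-boundary effects).
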