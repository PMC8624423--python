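# Methods

## Sum of ranking differences

SRD compares candidate columns of a data matrix to a benchmark column in
rank space. For an n-row matrix the candidate's value is the Spearman
footrule distance between its fractional-rank vector and the benchmark's:

    SRD_j = sum_i | R(x_ij) - R(r_i) |

Ranks are ascending and tie-averaged (tied values share the mean of the
ranks they span), which conserves the rank sum n(n+1)/2. Because only ranks
enter, the statistic is invariant under any strictly increasing transform of
a column — intensity units, dilution factors and detector response curves
drop out, which is what makes the method suitable for comparing sampling
procedures with very different absolute recoveries.

### Benchmark column

The benchmark ("golden standard") is a row-wise aggregate of the matrix —
maximum, minimum, mean or median — or an externally supplied standard. For
sampling optimization the row-wise **maximum** is the natural choice: it is
the best intensity any procedure achieved for that compound, so the
procedure ranking compounds most like the maxima is the one that loses the
least information.

### Normalization with ties

Scaled SRD is 100·SRD/SRDmax. For an untied benchmark the exact maximum is
the classical floor(n²/2), attained by the reverse ranking. With ties the
constant used here is the rearrangement bound obtained by pairing the
ascending-sorted benchmark ranks with the reversed untied ranking n..1.
Tie-averaged rank vectors are convex combinations of permutation vectors
and the footrule distance is convex, so untied rankings are the extreme
points of the candidate set: this bound holds for *every* admissible
candidate whatever its tie structure, is attained by an untied reversal,
and reduces to floor(n²/2) when the benchmark is untied. (Normalizing
instead by the maximum over permutations of the benchmark's own rank
multiset — a plausible alternative — fails to bound candidates that are
less tied than the benchmark and degenerates to 0 for a constant
benchmark.) For n ≥ 2 the constant is strictly positive, so scaled SRD is
always defined, lies in [0, 100], and is 0 exactly when the candidate's
ranking equals the benchmark's.

For untied data the footrule distance between two permutations is always
even (moving one object up by k forces k units of compensating displacement
down), so the raw SRD support contains only even integers.

### CRRN validation

The null model is a uniformly random permutation of the benchmark's own
rank multiset — random ranking of the same objects with the same tie
pattern, so like is compared with like. For n ≤ 8 the distribution is
enumerated exactly over all n! arrangements (40320 at the limit); above
that a seeded Monte Carlo sample (default 10⁵ permutations, generated in
memory-bounded batches) is used and the method, sample size and seed are
recorded in the distribution object and every export. No normal
approximation is involved anywhere.

Three probability levels are reported on the scaled axis: XX1 (5%), Med
(50%) and XX19 (95%), each by discrete inverse-CDF — the smallest support
value whose cumulative probability reaches the level. The null is discrete,
so interpolation would manufacture unattainable values. An observed scaled
SRD below XX1 is closer to the benchmark than 95% of random rankings; the
left-tail probability P(random SRD ≤ observed) is available directly. For
large n the null mass concentrates far from 0 (Med ≈ 66.7 at n = 149), so
real procedures typically sit one order of magnitude below the random bulk.

## Peak tables, retention indices, filters

Peak tables are CSV with a header; eight reserved metadata columns
(`rt_min`, `compound`, `formula`, `cas`, `area_percent`, `match_factor`,
`ri_calculated`, `ri_literature`) and one intensity column per procedure,
labelled by the adsorbent-initial-plus-hours code (`P6h`, `C2h`, ...). A
missing intensity cell means "not detected" and is stored as 0, keeping
every column rankable (absent compounds tie at the bottom). Rows are kept
in elution order. Reading is round-trip exact (`float_precision=
"round_trip"`), so write → read is the identity.

Retention indices use the linear van den Dool–Kratz interpolation against
an n-alkane ladder (C8–C20 by default in the generator): RI is 100 × carbon
number at each alkane and piecewise-linear in retention time between
consecutive alkanes. This is the correct form for temperature-programmed
runs; logarithmic (isothermal Kováts) interpolation is not offered, and
retention times outside the ladder span raise rather than extrapolate.

Three relevance filters reduce a found-compound list, all with *strict*
thresholds: area share of the total integrated area > 0.1%; library match
factor > 80% (compounds with no match factor are unidentified and fail);
and the ΔRI plausibility rule — eliminate when
100·|RI_calc − RI_lit|/RI_lit > 10%, unless the match factor exceeds 90%
(strong spectral evidence overrides a retention-index mismatch). Compounds
without a literature RI are retained, since there is no evidence against
them. A compound's area share uses its stored `area_percent` when present,
else its summed intensity across procedures over the table total; because
removing rows can only increase the survivors' shares, the filters are
idempotent. Published compound tables sometimes retain low-area compounds
with excellent spectral matches, so both a conjunctive (`all`) and a
disjunctive (`any`) combination of the area and match-factor filters are
provided; the ΔRI elimination applies in both modes.

## Synthetic VOC-capture generator

The generator stands in for unpublished raw data: it produces peak tables
with the statistical structure the analysis assumes, plus the latent truth
needed to test ranking recovery. The capture model for compound i under
procedure j = (adsorbent a, sampling time t) is

    E[intensity_ij] = A_i · phi(a, c_i) · (1 − exp(−t / tau(a, c_i)))

with lognormal baseline abundance A_i (log-mean 11, log-sd 1.25: peak areas
are positive, right-skewed, and span roughly 2.5 orders of magnitude, the
spread typical of reported area-percent tables), affinity phi ∈ (0, 1] and
saturation constant tau (hours) per adsorbent × volatility class, i.i.d.
multiplicative lognormal noise (log-sd 0.2, ≈20% CV), and censoring to 0
below the detection limit (default 2000 detector units, which removes
roughly 10–15% of peaks in 1 h columns but only a few percent at 6 h).
Compounds belong to 5 volatility classes occupying consecutive retention
bands (quintile blocks, 30/30/30/30/29 at the default n = 149), so elution
order proxies volatility.

The default affinity/tau profiles encode the capture physics the analysis
is meant to detect: saturation constants grow steeply from the most
volatile class (tau ≈ 0.3–0.5 h) to the least volatile (tau ≈ 4–6 h),
because heavy compounds accumulate slowly — short samplings therefore
systematically under-rank low-volatility compounds; Porapak Q has the
strongest and flattest profile, making its 6 h sampling the designed global
optimum; HayeSep Q saturates fastest, which keeps its short samplings
competitive in the mid-field; Carbotrap is best for the most volatile class
and weak for heavy compounds.

Two design constraints shaped these numbers. First, the ground-truth best
procedure must be *decisively* best: since SRD only sees rank shape, a
competitor whose class profile parallels the benchmark's is statistically
exchangeable with the optimum under noise, and a recovery test against such
a truth would be a coin flip. The profiles therefore keep every competitor
at a clear rank-shape distance from P6h. Second, a direct consequence: the
optimum's own 4 h column (same adsorbent, distortion bounded by the
saturation-ratio curve) is necessarily the second-closest ranking, ahead of
the other adsorbents' 6 h columns. The generator's low-noise orderings
reflect that (P6h, P4h, H6h, ...); demanding all three 6 h procedures in
the first three positions while keeping the optimum robustly recoverable is
not achievable in this model family, and recoverability won.

What the generator does **not** emulate: chromatographic peak shapes,
co-elution and integration errors, mass-spectral similarity (match factors
are drawn independently of everything else), intensity-dependent
(heteroscedastic) measurement error, and between-replicate biological
variation. Passing recovery tests therefore show that the analysis chain
recovers a known capture hierarchy from saturating, censored, multiplicative-
noise data — not that it is robust to every artifact of real chromatograms.

## Study pipeline

Three experiments over one table, each with its own CRRN null (the null
depends on n): the full matrix; consecutive elution-order groups (block
size 30, last group takes the remainder — 30/30/30/30/29 at n = 149),
probing how adsorbent performance depends on volatility; and top-N
most-intense subsets (default N = 149, 100, 50, 20), probing how short the
compound list can get before the procedure ranking degrades. "Intensity" of
a compound is its row maximum, consistent with the max benchmark; the
statistic is configurable. Ties at a top-N cutoff prefer the earlier-eluting
compound, making subsets deterministic. Sub-analyses with fewer than 2
compounds are flagged and skipped rather than failing the run.

Exports are deterministic: fixed float format (6 decimals), sorted JSON
keys, stable orderings (scaled SRD ascending, label-lexicographic
tie-break), so re-exporting the same report is byte-identical. Optional
figures show each procedure's scaled SRD with the null frequency curve and
its XX1/Med/XX19 levels overlaid.

## Problem sizes and numerical conventions

Tests and the acceptance script run the full 149 × 12 design; Monte-Carlo
nulls default to 10⁵ permutations (2 × 10⁴ inside the multi-subset study
report tests, which is ample for level placement to within a scaled point).
Ranking-recovery checks use 20 consecutive seeds. Floating-point ranks are
multiples of 0.5, so footrule sums are exact in double precision; null
support values are rounded to 9 decimals before tabulation; percentile
lookups use a 1e-9 tolerance on the CDF comparison. All randomness flows
from explicit `numpy.random.default_rng` seeds; identical seeds reproduce
identical tables, nulls and reports bit for bit.

## Known limitations

* The homoscedastic noise model understates how noisy small peaks are in
  real chromatograms; real short-sampling columns are likely *worse* than
  the generator's, so the recovery margins here are conservative in
  direction but not calibrated in magnitude.
* CRRN levels for n > 8 are Monte-Carlo estimates; with 10⁵ draws the
  5%/95% levels carry sampling error of a few tenths of a scaled-SRD point.
* The ΔRI filter trusts stored literature indices; it cannot detect a wrong
  identification whose literature value happens to agree.
* Transposed-matrix SRD (ranking compound groups by procedures) is out of
  scope.
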