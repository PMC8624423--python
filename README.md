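# srdkit

Sampling-procedure optimization for volatile-compound (VOC) analysis by the
**sum of ranking differences** (SRD) method, with **CRRN** permutation
validation (comparison of ranks with random numbers).

## The problem

When headspace volatiles are collected on different adsorbents (Porapak Q,
HayeSep Q, Carbotrap) for different sampling times (1–6 h) and measured by
GC–MS, every combination yields one intensity column over the same compound
list. Which procedure is best? Comparing dozens of compounds across a dozen
procedures by eye, or by parametric statistics on heavily skewed peak areas,
is unreliable. SRD answers the question non-parametrically: it measures how
close each procedure's *ranking* of the compounds comes to a benchmark
ranking, and a permutation test says whether that closeness could be chance.

## The method

Given an intensity matrix **X** (n compounds × m procedures):

1. define a benchmark column *r* (here the row-wise maximum: the best
   achievable intensity per compound);
2. rank-transform *r* and every column of **X** (fractional ranks; ties get
   the average of the ranks they span);
3. for each procedure *j* compute the Spearman-footrule distance
   SRD*_j* = Σ_i |rank(x_ij) − rank(r_i)|;
4. scale to 0–100 by the maximum attainable distance (floor(n²/2) for an
   untied benchmark), giving the **scaled SRD**: 0 = identical ranking to
   the benchmark, 100 = exact reversal;
5. validate by CRRN: the null distribution of SRD under uniformly random
   rankings (exact enumeration for n ≤ 8, seeded Monte Carlo above), with
   its 5% (XX1), median (Med) and 95% (XX19) levels. Procedures whose scaled
   SRD falls far below XX1 are significantly closer to the benchmark than
   chance.

Around this core the package provides GC–MS peak-table I/O, linear
(van den Dool–Kratz) retention-index calibration against an n-alkane ladder,
the standard compound-relevance filters (area fraction, library match
factor, ΔRI plausibility), elution-order group and top-N subset analyses,
and a synthetic VOC-capture generator with known ground truth.

## Worked example

```python
from srdkit import (SyntheticConfig, generate_dataset, srd_analysis,
                    crrn_null, rank_with_ties, reference_column)

table, truth = generate_dataset(SyntheticConfig(seed=0))   # 149 x 12
result = srd_analysis(table, reference_mode="max")
null = crrn_null(rank_with_ties(reference_column(table.intensities, "max")),
                 n_permutations=100_000, seed=0)
print("designed optimum:", truth.global_best)
for lab in result.ordering:
    print(f"{lab:>4s}  scaled SRD = {result.scaled_of(lab):6.2f}")
print(f"CRRN levels (n=149): XX1={null.xx1:.2f}  Med={null.med:.2f}  XX19={null.xx19:.2f}")
```

Output:

```
designed optimum: P6h
 P6h  scaled SRD =   5.55
 P4h  scaled SRD =   7.73
 H6h  scaled SRD =   9.41
 C6h  scaled SRD =   9.71
 H4h  scaled SRD =  10.32
 P2h  scaled SRD =  10.90
 C4h  scaled SRD =  11.24
 H2h  scaled SRD =  14.40
 P1h  scaled SRD =  14.86
 C2h  scaled SRD =  15.68
 H1h  scaled SRD =  18.99
 C1h  scaled SRD =  20.05
CRRN levels (n=149): XX1=60.92  Med=66.68  XX19=72.32
```

Reading it: the 6 h sampling on Porapak Q (P6h) ranks the compounds most
similarly to the per-compound intensity maxima and is the recovered optimum;
every procedure sits far below the XX1 = 60.9 level, so none of the
orderings is mistakable for random. Longer samplings beat shorter ones, and
all three 1 h procedures come last — the generator's designed capture
hierarchy, recovered from noisy, detection-limited data.

The same analysis is available from the shell:

```sh
srdkit study --synthetic --seed 0 --out results/study
srdkit crrn --n 149 --out results/null.csv
srdkit simulate --out results/sim --seed 0
srdkit filter --input results/sim/peak_table.csv --output filtered.csv --mode any
srdkit srd --input filtered.csv --output srd.csv
```

`study` writes one CSV per sub-analysis (full matrix, five elution-order
groups, top-N subsets), a `rank_stability.csv` table of each procedure's
rank across sub-analyses, and a `summary.json` with orderings, CRRN levels
and the full run configuration.

## Documentation

`docs/methods.md` describes the model, the normalization with ties, the
CRRN null, the synthetic generator's assumptions and limitations, and the
numerical conventions.
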