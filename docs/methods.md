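# Methods

`haplogeo` analyses fine-scale mitochondrial phylogeographic structure
from a sample of aligned sequences (here, a cytochrome *b* fragment
concatenated with a control-region fragment into 801-base per-individual
haplotype sequences) plus a table of sampling locations. This note
records the models and formulas implemented, the parameters that matter,
the numerical conventions, and the limits of what the synthetic data can
demonstrate.

## Haplotype identification

Sequences live over `{A, C, G, T, -, N}`; `-` is a genuine indel state,
`N` is missing data. Two collapse conventions are provided because the
field's two standard tools disagree:

* **GAP_AS_STATE** (ARLEQUIN-like, the default): a gap is a fifth
  character state, so haplotypes separated only by an indel stay
  distinct.
* **EXCLUDE_GAP_SITES** (DnaSP-like): any column containing a gap is
  removed alignment-wide before comparison, merging indel-only classes.

Missing data (`N`) is a wildcard: a sequence joins the unique haplotype
compatible with it; when several are compatible it joins the most
frequent (ties: first occurrence in input order), and a sequence
compatible with none is flagged, dropped from the table, and counted.
This is deterministic and conservative; a stricter `N`-as-state policy is
available. Haplotypes are named `H1, H2, ...` by descending count (ties:
first occurrence); a user-supplied label map keyed by canonical sequence
supports parity with externally published labels.

Positions are reported in 1-based reference coordinates anchored by a
single alignment offset (the study alignment starts at reference
position 14,771; the cytochrome *b* window is 14,771–15,146 and the
control-region window 15,147–15,571). A variable site is a column with
at least two distinct non-`N` states; contiguous gap-versus-base columns
are additionally reported as indel runs.

## Distances

Three pairwise distance conventions:

| mode | definition |
|---|---|
| `PER_COLUMN_GAP` | count of differing columns, gap-versus-base included |
| `INDEL_AS_EVENT` | substitutions + one per maximal contiguous gap-versus-base run |
| `SUBSTITUTIONS_ONLY` | substitutions after removing every gap-containing column alignment-wide |

`N` columns never contribute (pairwise deletion). Caveats worth knowing:
pairwise deletion of `N` breaks the triangle inequality (a masked column
can hide a difference), and event-coded indel distances are not metric in
general either — a gap run spanning substitution-variable columns can
shortcut them. `PER_COLUMN_GAP` on fully called sequences is plain
Hamming distance and metric; `SUBSTITUTIONS_ONLY` is metric because the
gap columns are removed globally, not per pair. On the study haplotypes
all three modes satisfy the triangle inequality (tested).

## Diversity indices

For haplotype counts `c_i`, `n = Σ c_i`, `p_i = c_i / n`:

* Haplotype diversity `Hd = n/(n−1) · (1 − Σ p_i²)`, with Nei's (1987)
  sampling variance for the standard deviation.
* Mean pairwise differences `k = Σ_{i<j} c_i c_j d_ij / C(n,2)`,
  computed from the haplotype distance matrix (equivalent to the naive
  sum over all individual pairs; tested for exact agreement). Its sd is
  the square root of Tajima's (1983) total (stochastic + sampling,
  no-recombination) variance `V(k) = (3n(n+1)k + 2(n²+n+3)k²) /
  (11(n²−7n+6))`.
* Nucleotide diversity `π = k / L` over the `L` aligned sites.

The headline `k`/`π` use `PER_COLUMN_GAP` (so the 2-base indel
contributes two column differences), which reproduces the conventions of
the software the field uses for gapped mitochondrial data. On the
reconstructed study data this gives `k = 8035/5151 ≈ 1.5599` and
`π ≈ 0.00195`.

## Neutrality tests

**Tajima's D** uses the substitutions-only pathway throughout: `S`
counts polymorphic columns after excluding gap columns, and `k_subst` is
the mean pairwise difference in `SUBSTITUTIONS_ONLY` mode. With
Tajima's (1989) constants (`a1 = Σ 1/i`, etc., functions of `n` only),

```
D = (k_subst − S/a1) / sqrt(e1·S + e2·S·(S−1))
```

`S = 0` yields an explicit undefined result (`nan`), never a division.

**Fu's Fs** compares the observed allele (haplotype) count `K` with its
expectation under the Ewens sampling distribution at `θ` estimated by the
headline `k`:

```
Pr(K = j | θ, n) = |s(n, j)| θ^j / (θ)_n ,   S' = Σ_{j ≥ K} Pr(K = j),
Fs = ln( S' / (1 − S') )
```

with unsigned Stirling numbers of the first kind and the rising
factorial `(θ)_n`. The Stirling triangle is evaluated entirely in log
space (no overflow up to at least `n = 1000`; normalisation is tested to
1e−10 at `n = 200`). `Fs` is computed as the difference of the log upper
and lower tail sums, which keeps the symmetric point exact (`Fs = 0` at
`n = 2, K = 2, θ = 1`) and degrades gracefully to signed infinity when a
tail underflows (flagged, not raised).

**Simulation p-values.** Both statistics get one-tailed p-values from
replicates simulated under the standard neutral coalescent: exponential
inter-coalescence times at rate `j(j−1)/2`, infinite-sites mutations
either Poisson at rate `θ/2` per branch (`THETA`; `E[S] = θ·a1`) or
exactly `S` mutations placed multinomially by branch length (`FIXED_S`,
the default for D, matching a statistic computed at fixed `S`). The tail
follows the observed direction: `p = Pr(stat ≤ obs)` when the
observation falls below the null median, else `Pr(stat ≥ obs)`, and the
tail identity is reported. The exact tail convention differs between
published tools (some always use the lower tail for Fs); ours is a
documented choice, and with the lower-tail reading our Fs p-values match
the ARLEQUIN-style ones as `1 − p`.

The simulator was cross-validated against analytic expectations
(`E[S] = θ·a1(n)`; `E[pairwise] = θ` at `n = 2`). Tajima's D averaged
over neutral replicates at `n = 50` is slightly negative (about −0.08 to
−0.10 depending on conditioning) — an intrinsic small-sample property of
the statistic's normalisation, not a simulator bias; the calibration test
asserts the mean lies within ±0.1 of zero under the default `FIXED_S`
conditioning at the study's `S = 5`.

## Median-joining network

The network starts from the minimum spanning network (union of all
minimum spanning trees: an edge survives iff its endpoints are not
connected by strictly cheaper edges), then iteratively proposes the
columnwise majority consensus ("median") of every mutually connected
triple, adding novel medians whose connection cost (summed distance to
the triple) is within `ε` of the minimum, until a fixed point; median
vectors left with degree < 2 are pruned. Defaults: `ε = 0`,
`INDEL_AS_EVENT` distances, so the 2-base indel is a single mutation on a
single edge. Medians at gap columns treat each indel run as one binary
character, so a consensus cannot produce a partial gap. Tie-breaks
(median votes, node ordering) are lexicographic and the output is
deterministic given the input.

Edge labels list the mutated reference positions (an indel run as one
`start–end` label), so each edge's label count equals the distance
between its endpoints in the active mode, and every variable site appears
on at least one edge. On data forming a perfect phylogeny the output is
exactly the generating tree (tested).

## Spatial null models

`SampleRecord`s carry planar kilometre coordinates (samples at the same
site share coordinates; coordinate-less samples are logged and
excluded). The minimum convex polygon (MCP) is the 100% convex hull;
fewer than three distinct non-collinear points give area 0 with a
degeneracy flag.

Both tests use the same null: permute the complete haplotype-label
vector across samples, which preserves the haplotype frequency spectrum
and every site's sample count exactly in each replicate (multinomial
resampling with replacement is available behind a flag, but a confidence
interval for the area expected *given a haplotype's frequency* requires
holding that frequency fixed, which the permutation does). Per
replicate:

* **MCP test** — recompute the focal haplotype's hull area. Degenerate
  replicate hulls are retained. Haplotypes seen fewer than `min_count`
  times (default 5, the minimum for a meaningful hull) must first be
  merged into a pooled rare class `HX`, which keeps their samples in the
  permutation pool.
* **Richness test** — recount distinct haplotypes at each site with at
  least `min_site_n` samples (default 3).

Each result reports the observed value, null mean, 2.5th/97.5th
percentile interval from `n_reps` replicates (default 1000), and the
CI-exclusion flags: observed below the interval = significantly
localised (or haplotype-poor), above = significantly widespread (or
rich). Note the nominal size: each flag is a one-tail ~2.5% event, so
either-direction significance runs at ~5%; simulation under random
assignment confirms the two-sided rate sits inside the binomial 95% band
around 5%. No multiple-testing correction is applied across labels or
sites (recorded in the run manifest); with eight sites tested, one
nominal exclusion per analysis is expected by chance.

## Synthetic data

* **Study fixture** — the published variable-site patterns and haplotype
  frequencies (counts 8, 52, 33, 3, 4, 1, 1 over n = 102) fully determine
  the haplotype structure, so the alignment is reconstructed exactly:
  seven variable columns at reference positions 14,910–15,560 with the
  published states, embedded in a seed-generated uniform-base invariant
  background (invariant columns affect no statistic except `L`). The
  accompanying site assignment honours the published totals (H1 at 4
  sites, H2 at 29, H3 concentrated at 6, eight sites with ≥ 3 samples)
  but the memberships and coordinates are synthetic inventions — tests
  about specific site significance patterns are therefore not meaningful
  on the fixture and are not made.
* **Spatial simulator** — `n_sites` sites uniform in a box (default
  100 × 100 km, 30 sites), an exact haplotype frequency vector (default
  30/40/15/10/5 over 100 samples, focal frequency 30 matching the scale
  of the study's localised haplotype), and a clustering parameter
  `c ∈ [0, 1]`: each focal carrier is placed at one of `n_tight_sites`
  (default 3) sites confined to a corner sub-box (default a tenth of
  each box side) with probability `c`, otherwise uniformly. `c = 0` is
  exchangeable (the permutation null is exact); `c = 1` confines the
  focal haplotype completely.
* **Coalescent sampler** — as in the neutrality section; positions are
  drawn on an 801-site lattice with collision redraw (infinite sites over
  a finite map).

What passing these tests shows: the estimators agree with their exact
oracles; the permutation machinery has correct size and high power under
the simulator's idealised geography. What they cannot show: behaviour
under real sampling artefacts — uneven per-site effort (the study's
Regent's Park oversampling), per-sample missing data, or spatially
autocorrelated sampling — none of which the simulator reproduces.

## Numerical and reproducibility choices

* All report rounding happens at the report layer; library functions
  return full precision.
* Percentile intervals use NumPy's default (linear interpolation)
  percentile definition.
* Every stochastic routine takes an explicit seed or `numpy` Generator;
  the pipeline derives independent per-stage substreams from one config
  seed via `SeedSequence.spawn`, so stages can be rerun alone and a rerun
  with the same config is byte-identical. The run manifest records the
  config, its hash, and all stage seeds.
* Test problem sizes (200 simulated datasets for the size check, 20 for
  power, 5000 coalescent replicates for calibration, subsamples of
  n ≤ 30 for brute-force oracles) were chosen to keep each Monte-Carlo
  assertion at least ~3 standard errors away from its pass/fail boundary
  while remaining quick to run.

## Known limitations

* The alignment is assumed given; no alignment or trimming is performed.
* One mitochondrial locus pair, one population: no AMOVA/FST, no
  recombination, no demographic models beyond constant-size neutrality.
* Event-coded indel distances are not metric in general (above).
* The equirectangular lon/lat helper is approximate and intended only
  for study areas up to a few hundred kilometres.
* The sd printed for `k` follows Tajima (1983); other tools ship
  variants of this variance and may print slightly different values for
  the same data.
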