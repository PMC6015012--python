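# Methods

## The threat model

A *signal profile* is a per-base (or per-bin) vector of non-negative read
depth from a functional-genomics assay. The profiles are shared; the raw
reads and genotypes are not. The adversary additionally holds an identified
genotype dataset: a panel of deletion variants with per-individual genotype
calls coded as intact copies (0 = homozygous deletion, 1 = heterozygous,
2 = no deletion; `.` = missing).

The premise is physical: read depth over a deleted region scales with the
number of intact copies. A homozygous deletion is a dip to (near) zero, a
heterozygous one a half-depth dip. Small deletions are visible in deep,
narrow coverage (RNA-seq over exons); large deletions in broad, shallow
coverage (pooled ChIP-seq, Hi-C marginals).

## Features and coordinates

Coordinates are 1-based and inclusive; a deletion `[i, j]` has length
`l = j − i + 1`. The flanking neighborhood is `left = [2i−j+1, i−1]`,
`right = [j+1, 2j−i+1]` — asymmetric as stated (the right flank has length
`l`, the left `l − 2`), and deliberately not symmetrized. Consequences:

- intervals of length 1–2 have an empty left flank and are excluded from
  feature computation and small-deletion genotyping, exactly like
  intervals whose flanks leave the chromosome (no clamping, so features
  stay comparable across deletions);
- features: `s̄` (mean signal in `[i,j]`), `m̄` (mean multi-mappability),
  `ρ = 2s̄/(s̄_L + s̄_R)`, `η = min(s̄_R/s̄_L, s̄_L/s̄_R)`,
  `τ = (s̄_L + s̄_R)/2`.

Features are binned as `⌊log₂ x⌋`. Non-positive values (zero means, zero
denominators) map to a reserved UNDEFINED bin. UNDEFINED-binned records
*fail genotyping filters* but *participate in predictability estimation*
as their own bin level: on count data a homozygous deletion frequently has
interior signal exactly 0, and "signal exactly zero" is the single most
informative feature value for genotype 0 — dropping those records would
discard precisely the deletions whose leakage is being measured.

## Predictability and characterizing information

For one individual, `π_GW` is estimated by binning all panel deletions on
the 5-tuple of feature bins and taking the empirical genotype distribution
per occupied cell (self-inclusion: each deletion contributes to its own
cell). The per-cell support is reported so users can discount singleton
cells, which trivially predict themselves with probability 1. Estimation
is strictly per-individual by default; pooling (deletion, individual)
pairs across a cohort is possible by concatenating feature/genotype lists.

`ICI(g) = −log₂ f(g)` with `f(g)` the population frequency of genotype `g`
at that variant — the standard surprisal, matching the qualitative
description (rare genotypes characterize individuals more) and the bits
scale of prior leakage work.

The randomized baseline rotates a profile circularly by a seeded offset.
This preserves the value multiset (hence all genome-wide moments) while
destroying the positional association between dips and genotypes, so
`π_GW(real) − π_GW(shuffled)` isolates genuine leakage from binning
artifacts.

## Genotyping

Small deletions: candidates must pass `m̄ < m̄_max` (mappable),
`τ > τ_min` (enough flanking signal to judge a dip), `η > η_min`
(balanced flanks); survivors are sorted by ascending `ρ` and the top
`n_top` called homozygous. Large deletions: only the mappability filter,
sorted by ascending `s̄`. Defaults `m̄_max = 1.5`, `τ_min = 10`,
`η_min = 0.5`; accuracy is insensitive to these within reason. The method
calls *only* homozygous genotypes — deliberately crude, yet sufficient for
linking. Ties in the extremity sort break by genomic coordinate, making
call lists fully deterministic. When no panel is available, candidates are
non-overlapping tiling windows: 5 bp inside exons (small), 1000 bp
genome-wide (large); trailing partial windows are dropped, and windows are
not merged after calling (overlap matching during linking absorbs
fragmentation).

Hi-C matrices are collapsed to marginal profiles by column summation; the
marginal of a bin overlapping a homozygous deletion collapses, so the
large-deletion path applies directly at bin resolution.

## Linking and reliability

Panels are matched by ≥1 bp interval overlap (largest overlap wins, ties
to the smaller start coordinate). Only variants the genotyper actually
called enter the attack: matched-and-called variants carry predicted
genotype 0, everything else is treated as missing and skipped pairwise in
the Hamming distance. Each query links to the argmin-distance individual
(ties to the first, reported with gap 0 so they never pass a positive
threshold). The first distance gap is `d⁽²⁾ − d⁽¹⁾`, i.e., second-best
minus best, a non-negative reliability score; sensitivity is the fraction
of *all* individuals correctly linked above a gap threshold, PPV the
fraction correct among those above it. A random-selection baseline (mean
PPV over random linking subsets of equal size) is what gap selection must
beat. A panel-hygiene filter keeps variants whose least-frequent observed
genotype has frequency above a cutoff (default 0.01), removing variants
whose rare genotypes would single out individuals by themselves.

## Anonymization

For each known deletion `[i, j]`, every interior position `a` is replaced
by the median of the original values in `[a − l, a + l]` (clamped at
chromosome edges) with the deletion's own positions excluded from the
window; the median is sort-and-pick-middle, taking the lower-middle
element on even counts. Masking the deletion out of its own window is the
decisive choice: a plain median whose window is about the deletion's size
leaves a full-width dip entirely unchanged (the dip's values are the
majority of every window), and even much wider plain windows leave
carriers at a systematically lower order statistic of flank noise —
measurably enough residual signal to re-identify most of a cohort. With
the mask, the filtered interior depends only on flanking signal and is
identically distributed for carriers and non-carriers, which is what
drives post-anonymization linking to chance. Positions outside filtered
intervals are bit-identical to the input; every output value is an element
of its window. Overlapping panel intervals are filtered sequentially in
coordinate order (later windows see earlier output). The filter is not
claimed to be idempotent; re-running it modifies no more positions than
the first pass. Large deletions remain harder to protect: their calls rest
on `s̄` over regions far wider than any local window, so this local
smoother is aimed at small-deletion leakage.

## Synthetic cohorts

The generator encodes the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_individuals | 50 | cohort size K |
| n_variants | 500 | deletion panel size |
| min_len / max_len | 1 / 10 bp (small); 1000 / 5000 (large) | deletion lengths, uniform |
| af_min / af_max | 0.1 / 0.5 | deletion-allele frequency, uniform per variant |
| baseline_depth | 30 (small) / 5 (large preset) | expected read depth of covered regions |
| low_depth_fraction, low_depth | 0.2, 12 | fraction of variants in low-coverage regions |
| noise | poisson | `nb` adds gamma-Poisson overdispersion (`nb_dispersion`, var = μ + αμ²); `none` returns expectations |
| repeat_fraction, repeat_mappability | 0.05, 3.0 | variants inside repeat-like stretches (fail the `m̄` filter) |
| exon_length / intron_length | 100 / 100 bp | RNA-seq-like layout: deletions centered in exons, introns at zero |
| hic_bin_size, hic_depth | 1000 bp, 100 | Hi-C kernel `depth/(1+|i−j|)`, bins over deletions scaled by copies/2 |

Genotypes are Hardy–Weinberg (`p²`, `2p(1−p)`, `(1−p)²` for 0/1/2 intact
copies), independent across variants and individuals. Expected signal
inside a deletion is `region depth × copies/2`. The Hi-C preset uses a
100-variant panel so a typical individual carries ~10 homozygous
deletions, enough to identify each of 20 individuals uniquely.
`expand_by_resampling` grows a genotype dataset by drawing each variant
independently from its empirical genotype frequencies. All outputs are
bit-reproducible from one integer seed.

What the generator deliberately omits — and therefore what passing tests
do *not* demonstrate about real data: linkage disequilibrium between
variants (independent resampling also destroys it), alignment edge
artifacts at deletion boundaries, GC/coverage trends and library-size
variation, transcript-level RNA-seq structure, and deletion calls whose
boundaries disagree with the true dip. Real cohorts also share relatives;
kinship-aware linking is out of scope.

## Numerical and procedural choices

- Problem sizes in tests and the acceptance script (K = 50 × 500 variants
  for the attack sweep; 200 variants for predictability; K = 20 × 100 for
  Hi-C; n = 10,000 draws for calibration) are chosen as the smallest
  cohorts where the studied effects are unambiguous.
- The attack's variant-count axis is `n_top`: sweeping it reproduces the
  rise–plateau–fall accuracy curve — at full panel size every query calls
  every survivor homozygous, queries become nearly identical, and accuracy
  collapses toward 1/K.
- The moderate-noise regime for gap-reliability analysis (NB dispersion 2,
  K = 40, n_top 30, gap threshold 1) targets overall accuracy near 50%,
  where reliability selection matters; at dispersion 4 most gaps are 0 and
  the gap carries no information.
- Noise-robustness is swept over NB dispersion at fixed depth rather than
  over depth, because depth interacts with the `τ_min` filter (low depth
  empties the candidate list, which tests the filter, not the noise).
- Genotype distances are integers; all float comparisons in tests use
  explicit tolerances (1e-9 relative for feature oracles, exact for
  integer-valued medians and column sums).
- bedGraph writers emit zero runs so read/write round-trips preserve
  profile length exactly; bigWig/BAM are intentionally unsupported.
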