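# sigleak

Quantify, exploit, and close **genotype leakage from functional-genomics
signal profiles**.

Read-depth tracks shared from RNA-seq, ChIP-seq, or Hi-C experiments look
like harmless aggregates, but a genomic deletion leaves a dip in the track:
the signal inside a deletion is proportional to the number of intact copies
of the region. Someone holding a panel of known deletion genotypes (e.g., a
public SV call set) can genotype those dips from a shared track and
cross-reference them against the panel to re-identify the "anonymous"
donor. `sigleak` is a toolkit for studying exactly this risk — for
data-sharing consortia deciding what to release, and for privacy
researchers measuring what leaks.

## What it computes

**Per-deletion features.** For a deletion `[i, j]` on a signal profile
**S** with multi-mappability track **M**:

- `s̄` — mean signal inside the deletion,
- `m̄` — mean multi-mappability inside (high = repeat-like, untrustworthy),
- `ρ = 2 s̄ / (s̄_left + s̄_right)` — self-to-neighbor ratio over the flanks
  `[2i−j+1, i−1]` and `[j+1, 2j−i+1]`; a dip gives small `ρ`,
- `η = min(s̄_right/s̄_left, s̄_left/s̄_right)` — flank balance,
- `τ = (s̄_left + s̄_right)/2` — neighborhood signal level.

**Leakage metrics.** Genome-wide predictability `π_GW(g) = P(G = g |
⌊log₂ feature⌋ bins)` is the empirical conditional probability of the true
genotype given the binned features, estimated over all deletions of one
individual; individual characterizing information `ICI(g) = −log₂ f(g)` is
the surprisal of a genotype at its population frequency, in bits. A
circular-shuffle baseline (rotating the profile) measures how much of
`π_GW` is real signal rather than binning artifact.

**Genotyping and linking.** Candidates passing `m̄ < m̄_max`, `τ > τ_min`,
`η > η_min` (defaults 1.5, 10, 0.5) are ranked by extremity — ascending
`ρ` for small deletions, ascending `s̄` for large or Hi-C-derived ones —
and the top *n* are called homozygous (genotype 0). Calls are matched to a
genotype panel by ≥1 bp interval overlap, the Hamming genotype distance
`d_{k−l}` is computed to every panel individual, and each query links to
the argmin. The first distance gap `d⁽²⁾ − d⁽¹⁾` scores reliability;
sensitivity and PPV are evaluated over a gap threshold.

**Anonymization.** Each known deletion is median-filtered: every interior
position is replaced by the median of the surrounding `±l` window with the
deletion's own positions masked out, so the filtered interior is the same
order statistic of flanking signal whether or not the donor carries the
deletion.

**Synthetic cohorts.** A generator produces Hardy–Weinberg genotypes,
copy-number-scaled Poisson/negative-binomial profiles (RNA-seq-like
deep/narrow and ChIP-seq-like broad/shallow regimes), repeat-like
mappability stretches, and Hi-C matrices with distance-decay backgrounds —
so the entire pipeline runs end to end without any restricted-access data.

## Worked example

```python
import sigleak as sl
from sigleak.genotyping import GenotypingParams
from sigleak.linking import attack_cohort, evaluate_linking
from sigleak.anonymize import anonymize_profile

config = sl.SimulationConfig(n_individuals=20, n_variants=300, seed=0)
truth, cohort, mappability = sl.simulate_cohort(config)
profiles = {ind: cohort.pooled(ind) for ind in cohort.individuals}

results = attack_cohort(profiles, mappability, truth.panel, truth.genotypes,
                        GenotypingParams(n_top=40), truth=truth.identity)
sens, ppv, acc = evaluate_linking(results, truth.identity, gap_threshold=1)
print(f"linking accuracy: {acc:.2f}")
print(f"sensitivity at gap>1: {sens:.2f}, PPV: {ppv:.2f}")

anon = {ind: anonymize_profile(p, truth.panel)[0] for ind, p in profiles.items()}
results = attack_cohort(anon, mappability, truth.panel, truth.genotypes,
                        GenotypingParams(n_top=40), truth=truth.identity)
_, _, acc_anon = evaluate_linking(results, truth.identity)
print(f"after anonymization: {acc_anon:.2f} (chance = {1/config.n_individuals:.2f})")
```

prints

```
linking accuracy: 1.00
sensitivity at gap>1: 1.00, PPV: 1.00
after anonymization: 0.05 (chance = 0.05)
```

Every one of the 20 simulated donors is re-identified from their raw
read-depth track (and every linking passes the gap-reliability filter);
after median-filter anonymization the attack does no better than guessing.

The same pipeline is available from the shell:

```sh
sigleak simulate --seed 0 --out-dir cohort/
sigleak genotype --mode small --panel cohort/panel.bed \
    --profile cohort/ind0000.bedgraph --mappability cohort/mappability.bedgraph \
    --n-top 40 --out calls/ind0000.calls.tsv
sigleak link --calls calls/ --panel cohort/panel.bed \
    --genotypes cohort/genotypes.tsv --truth cohort/truth.tsv --out links.tsv
sigleak anonymize --profile cohort/ind0000.bedgraph --panel cohort/panel.bed \
    --out anon.bedgraph --report report.tsv
```

Subcommands: `simulate`, `features`, `predictability`, `genotype`,
`hic2signal`, `link`, `anonymize`, `evaluate`. Signal travels as bedGraph,
panels as BED, genotypes as TSV (`{0,1,2}` intact copies, `.` missing).

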