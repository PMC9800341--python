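# polwave

Quantitative analysis of two linked questions in transcription biology:

1. **Alternative polyadenylation (APA) from long-read 3′ ends** — which genes
   shift cleavage from their TSS-distal to their TSS-proximal
   polyadenylation site (PAS) between two conditions (e.g. a factor
   depletion vs control)?
2. **Pol II elongation rates from DRB/TT-seq** — how fast does RNA
   polymerase II travel into gene bodies, measured by following the nascent-RNA
   "wave" after release from DRB inhibition?

It also includes the supporting ChIP-style machinery — anchored metagene
profiles and a sliding-window Poisson peak caller — and a synthetic-data
generator that emulates all three experiment types with known ground truth,
so every analysis path is testable end to end.

The package is aimed at computational biologists who want a small,
deterministic, plain-text-format pipeline for these analyses, or a simulator
to benchmark their own.

## The statistics at the core

**APA classification.** Each read's 3′-terminal base is assigned to the
nearest same-strand PAS within ±50 bp (ties broken toward the distal site).
For a gene with proximal count *p* and distal count *d* in a library, the
usage ratio is *r = p/d*. Genes need ≥2 annotated PAS and ≥5 distal reads in
both libraries to be testable. Between case and control the fold change is

    f = r_case / r_control

and a gene is *proximal-dependent* if f ≥ τ, *distal-dependent* if f ≤ 1/τ,
else *independent* (τ = 1.5). Per-replicate classifications are intersected:
the consensus dependent set contains genes dependent in **every** replicate,
which is what controls false dependence calls (at 200 reads/gene a single
replicate mislabels ~6.5% of null genes; three-replicate intersection drops
false dependent calls below 0.01%).

**Elongation rates.** Coverage is binned into TSS-anchored windows
(−2 kb … +120 kb, 200-bp bins, strand-flipped, rpm-normalized) for
non-overlapping genes 60–300 kb long. Per release time *t*, the wave peak
x(t) is the argmax of a cubic smoothing spline (GCV penalty) downstream of
the TSS; genes with window coverage < 100 rpm or a first-time-point peak
< 2 kb are excluded. The elongation rate is the OLS slope of x(t) on *t* in
kb/min; a free intercept absorbs the labeling delay. Gene groups are compared
with a Welch two-sided t-test.

**Peak calling.** Each sliding window (500 bp, step 100 bp) is tested
one-sided against a Poisson expectation from a depth-scaled input track
(locally averaged over 5 kb) or the genome-wide background, at a raw
p ≤ 10⁻⁵ cutoff; significant windows merge into peaks annotated
TSS / gene body / intergenic.

## Worked example

Simulate a small two-condition experiment and classify APA shifts:

```python
import numpy as np
import polwave.simulate as sim
import polwave.apa as apa

cfg = sim.SimulationConfig(n_genes=50, seed=3)   # 0.3 -> 0.6 proximal shift
genes, sizes = sim.make_genome(cfg)              # in half of the genes
pas = sim.make_pas(genes, cfg)

classes = []
for rep in (1, 2, 3):
    summaries = {}
    for cond in ("control", "case"):
        ends, _, _ = sim.simulate_reads(genes, pas, cfg, cond, rep, sizes)
        counts, _ = apa.pas_usage_table(ends, pas, f"{cond}{rep}")
        summaries[cond] = apa.usage_summary(counts)
    classes.append(apa.classify_genes(summaries["case"], summaries["control"]))

res = apa.intersect_replicates(classes)
shifted = {f"g{i:04d}" for i in range(25)}
print("recovered:", len(res["consensus_dependent"] & shifted), "/ 25")
print("false dependent:", len(res["consensus_dependent"] - shifted))
```

Output:

```
recovered: 25 / 25
false dependent: 0
```

All 25 truly shifted genes land in the consensus proximal-dependent set and
no unshifted gene does. The same dataset's TT-seq arm recovers the set
elongation velocity: a noiseless wave simulated at 2 kb/min yields metagene
peaks at ≈20/40/60/80 kb for t = 10/20/30/40 min and a regression slope of
exactly 2.0 kb/min.

The full pipeline (simulate → APA → elongation → ChIP, with a hash manifest)
runs from the shell:

```bash
polwave run --out-dir demo_run --seed 42
```

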