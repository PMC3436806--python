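# exocnv

Detection and absolute genotyping of **common copy-number variants (CNVs)
from exome-capture read depth** in case–control cohorts.

Exome sequencing reads a captured fragment a number of times roughly
proportional to its copy number in the sample, so read depth carries CNV
information. It also carries strong technical structure — capture-array
batch effects, GC-dependent capture efficiency, DNA-source differences —
that inflates naive case–control tests far beyond any real signal.
`exocnv` implements a principal-component strategy for separating the two:

1. **Normalize**: per-base depth `r_ijk` in capture region *i*, base *j*,
   sample *k* is the raw depth divided by the sample's mean depth over the
   capture footprint.
2. **Summarize each region**: the first *local* principal component
   FPC<sub>i</sub> of the centered `M × N` matrix `R_i = {r_ijk}` — one
   number per sample, computed with a memory-light alternating power
   iteration (`t ← R v`, `v ← Rᵀt/‖Rᵀt‖`) that never forms `R Rᵀ`.
3. **Learn cohort-wide structure**: the first *K* = 50 *global* PCs
   (GPC<sub>1..K</sub>) of the stacked regions × samples FPC matrix, by
   dense SVD. These directions capture batch and GC structure shared
   across regions.
4. **Adjust and test**: project the first *H* GPCs out of every FPC,

   FPC<sub>i</sub><sup>(H)</sup> = FPC<sub>i</sub> − Σ<sub>h≤H</sub>
   (⟨FPC<sub>i</sub>, GPC<sub>h</sub>⟩/⟨GPC<sub>h</sub>, GPC<sub>h</sub>⟩) GPC<sub>h</sub>,

   and fit `logit P(case) = β₀ + β₁ · FPC_i^(H)` per region. The
   genomic-control factor λ = median(χ²)/0.4549 diagnoses residual
   inflation across an H grid (default 0, 5, 20, 40, 50), together with
   QQ and GC-content–vs–significance tables.
5. **Genotype associated loci**: average depth in non-overlapping 100-bp
   windows, project out GPCs, and fit a population hidden Markov model —
   Gaussian emission clusters per copy number 0–4 (initial means 0, 0.5,
   1, 1.5, 2) shared by all samples, sticky transitions along windows —
   by 20 iterations of EM. Each sample's copy number is its maximum mean
   posterior state; the maximum is the call's certainty, and low-certainty
   calls are set missing.

A synthetic-cohort generator (`exocnv.simulate`) draws genotypes under
Hardy–Weinberg equilibrium, phenotypes from a logistic disease model, and
negative-binomial depth with per-base capture profiles, low-rank
capture-batch factors, GC response and batch–phenotype confounding, so
the whole pipeline is testable end to end without external data.

## Worked example

Simulate a confounded cohort (2000 capture targets, 30 cases / 30
controls, one 32.2-kb deletion at allele frequency 0.6 embedded at
`region_01000`), scan it, and genotype the locus:

```bash
exocnv simulate --out fix --n-case 30 --n-control 30 --n-regions 2000 \
    --causal region_01000 --causal-length 32200 --odds-ratio 3 \
    --confounding 0.5 --batch-effect-sd 0.08 --seed 3

exocnv scan --regions fix/regions.bed --manifest fix/manifest.tsv \
    --depth-table fix/depth.tsv --out scan --h-grid 0,5,10,20 -K 30 --seed 3
```

```
H=0     lambda=2.6400   n_regions=2000
H=5     lambda=1.2174   n_regions=2000
H=10    lambda=1.0781   n_regions=2000
H=20    lambda=0.9279   n_regions=2000
```

The uncorrected scan is inflated (λ = 2.64: half the genome would look
"associated"); projecting out 10–20 global PCs restores calibration
(λ ≈ 1). In `scan/association_H10.tsv` the causal region is now ranked
1 of 2000 with p = 1.8e-3 — small cohort, large simulated effect — while
the QQ table (`scan/qq_H10.tsv`) hugs the diagonal. Then:

```bash
exocnv genotype --regions fix/regions.bed --manifest fix/manifest.tsv \
    --depth-table fix/depth.tsv --locus region_01000 --out geno \
    --truth fix/truth.tsv --seed 3
```

```
missing_rate    0.0000
accuracy        1.0000
```

`geno/genotypes.tsv` holds one absolute copy-number call (0/1/2) with a
posterior certainty per sample; `geno/clusters.tsv` records the EM
trajectory of the depth clusters (they converge near 0, 0.5 and 1.0 —
homozygous deletion, heterozygous deletion, diploid); `metrics.tsv`
compares calls against the simulated truth. All of this is also available
programmatically (`exocnv.pipeline`), which is what the test-suite and
the reproduction script use.

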