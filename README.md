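# heron

Ranking antibody-binding probes, epitopes and proteins from whole-proteome
tiled peptide binding arrays.

Ultra-dense peptide arrays tile every protein of a proteome with short
overlapping peptides (here 16-mers at a 1-4 amino-acid step) and measure
serum antibody binding to each peptide in control ("negative") and
experimental ("positive") samples.  This package takes a normalized
probe-intensity matrix and answers, per positive sample: which probes are
differentially bound, which contiguous probe blocks form epitopes, and
which proteins carry at least one significant epitope — each with a
p-value, a Benjamini-Hochberg FDR, and a K-of-N consensus count across
samples.

## The statistics in brief

For probe *i* and positive sample *s* with intensity *x*:

* **global p-value** — one-sided z-test against the pooled distribution of
  all intensities: `p_g = P(Z > (x − μ)/σ − δ)` with μ, σ the mean/SD of
  every cell and δ a shift in pooled-SD units (δ = 3/6/10 give the
  inclusive/moderate/restrictive regimes);
* **differential p-value** — one-sided t-test of the single positive
  observation against the negative group:
  `t = (x − x̄_neg − Δ) / (s_neg √(1 + 1/n_neg))`, df = n_neg − 1, with Δ
  an absolute shift on the normalized scale (Δ = 1 ≈ 2-fold for log2 data);
* **combined** — Wilkinson's max of the two: `p_c = max(p_g, p_d)²`;
* BH adjustment per positive-sample column, calls at `p_adj < cutoff`
  (strict), optional **one-hit filter** removing calls with neither an
  adjacent called probe in the same sample nor a call in another sample;
* **epitopes** — runs of adjacent called probes, either reported per sample
  (`unique`) or segmented by contiguity-constrained complete-linkage
  clustering (`hclust`) or path-graph edge cutting (`skater`), selecting
  the partition with the best average silhouette width on binary-hamming or
  z-score-Euclidean probe distances;
* **meta p-values** — member-probe p-values combine into epitope p-values
  (Wilkinson's r-th max by default: most probes must be significant) and
  epitope p-values into protein p-values (Tippett / min-Bonferroni: one
  significant epitope suffices); Fisher, harmonic-mean (Landau tail) and
  Cauchy combination are also available.  Each level is BH-adjusted,
  thresholded and summarized as K of N.

Epitopes are identified as `Protein_FirstProbe_LastProbe` (1-based start
coordinates of the first and last member probes; a block covers amino
acids `[first, last + 15]`).

## Worked example

```python
from heron import SynthConfig, StatParams, generate, run_workflow

config = SynthConfig(seed=7, effect=12.0, n_planted=1)
data, truth = generate(config)
planted = truth.planted[0]
print(f"planted: {planted.protein_id}[{planted.start}-{planted.end}] "
      f"carried by {', '.join(planted.carriers)}")

result = run_workflow(data, StatParams(use_global=False))
top = result.epitope.raw.min(axis=1).sort_values().head(3)
for epitope_id, p in top.items():
    print(f"{epitope_id}  best raw p = {p:.3g}")
print(result.protein.k_of_n_frame().to_string())
```

prints

```
planted: PROT001[63-82] carried by P1, P2, P4
PROT001_49_81  best raw p = 3.07e-51
            k  n  percent_called
feature_id
PROT001     3  6            50.0
```

The generator plants a 20-aa high-binding region on PROT001 (amino acids
63-82) in 3 of the 6 positive samples.  The workflow reports a single
epitope whose member probes start at positions 49-81 — exactly the 16-mers
overlapping the planted interval (probe 49 covers 49-64) — and the protein
is called in 3 of 6 samples (50%), the three carriers.

The same pipeline is available from the shell:

```sh
heron synth --seed 7 --outdir data/
heron run --matrix data/intensities.tsv --samples data/samples.tsv \
          --meta data/probe_meta.tsv --no-global --outdir results/
```

which writes `probe_results.tsv`, `epitope_results.tsv`,
`protein_results.tsv`, `epitopes.tsv` and a YAML run manifest.  Stage-wise
entry points (`heron probe-pvals`, `heron segment`, `heron metap`) expose
the intermediate tables.

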