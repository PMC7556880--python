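# comotif

Tools for asking whether two transcription factors share regulatory
territory and regulatory grammar, built around the case of Gli3 and Hand2
in the developing mouse mandible: Gli zinc-finger factors recognize the
canonical high-affinity word GACCACCC (cGBM), but at elements co-occupied
with the bHLH factor Hand2 the prevalent site is a low-affinity "divergent"
variant with T at the fifth position (GACC**T**CCC, dGBM), typically near a
bHLH E-box (CANNTG), and the pair activates transcription synergistically
— more than additively — in dual-luciferase assays.

The package implements each step of that analysis as a tested, reusable
library with a thin CLI (`comotif`):

- **Intervals and I/O** — BED/FASTA/TSV readers and writers, replicate
  merging with a minimum-support rule, intersection, and nearest
  upstream/downstream gene (TSS) assignment. Coordinates are 0-based
  half-open throughout.
- **Co-occupancy enrichment** — a permutation test for peak-set overlap:
  the observed number of A-peaks touching B is compared against nulls in
  which each A-peak is relocated uniformly on its own chromosome,
  preserving length. Reports fold enrichment, z, and both empirical and
  normal-tail p-values. A companion test measures gene-set enrichment
  among genes proximal to a peak class.
- **Motifs** — PWM scanning with a min–max-normalized log-odds score
  (a hit is a window scoring ≥ 80% of the matrix maximum), E-box and
  CCTCC-core detection, three-way peak classification
  (cGBM / dGBM / neither), and a reverse-complement-collapsed 8-mer census
  over the 32,896 canonical 8-mers with competition ranking.
- **Spacing and orientation** — tabulation of GBM/E-box pairs within
  100 bp on a signed-gap × orientation grid, with a uniform-multinomial
  permutation test (BH-adjusted) for preferred configurations.
- **Expression integration** — DE filtering (|fold change| > 1.5,
  adjusted p < 0.05), exact hypergeometric overlap of DE gene sets,
  direction concordance, and DE-gene counts per peak class.
- **Reporter synergy** — dual-luciferase normalization
  (firefly/renilla, scaled to the control mean) and a one-sided
  Welch-type test of the super-additive excess
  `mean(AB) − (mean(A) + mean(B) − 1)`, with a stratified-bootstrap
  alternative.
- **Synthetic data** — seeded generators for genomes, peak sets with a
  planted co-occupancy fraction, motif-embedded sequences, gene
  annotations, DE tables with planted sharing/concordance, and reporter
  wells with a planted interaction, so the whole pipeline runs and is
  testable with no downloads.

## Worked example

Simulate a study with the default configuration (two 5-Mb chromosomes,
1000 peaks per factor, 62% planted co-occupancy, co-occupied peaks planted
85% dGBM / 9% cGBM / 6% neither) and run every stage:

```sh
comotif pipeline --seed 1 --outdir study/
python - <<'PY'
import json
r = json.load(open("study/results.json"))
print("overlap %:", 100 * r["cooccupancy"]["frac_a_overlap"])
print("fold:", round(r["cooccupancy"]["enrichment"]["fold"], 1),
      "empirical p:", r["cooccupancy"]["enrichment"]["p_empirical"])
print("class fractions:", r["classification"]["fractions_overlap_peaks"])
print("top spacing cell %:", round(100 * r["spacing"]["top_fraction"], 2))
print("dGBM construct synergy p:", r["reporter"][1]["p_synergy"])
PY
```

prints (seed 1):

```
overlap %: 62.0
fold: 10.6 empirical p: 0.000999000999000999
class fractions: {'cGBM': 0.0967..., 'dGBM': 0.8048..., 'neither': 0.0983...}
top spacing cell %: 1.14
dGBM construct synergy p: 1.0767479346746947e-07
```

Read: 62% of factor-A peaks co-occur with factor B, ~10-fold more than
uniform relocation predicts (the empirical p sits at the Monte-Carlo floor
for 1000 permutations); the co-occupied peaks are dominated by the
divergent low-affinity motif class; no GBM/E-box spacing configuration
concentrates more than ~1% of pairs (flexible grammar); and only the
dGBM+E-box reporter construct shows significant super-additive activation.

Every subcommand is also available separately (`comotif merge`,
`intersect`, `nearest`, `enrich`, `classify`, `kmers`, `spacing`,
`integrate`, `synergy`); see `comotif --help`.

## Documentation

The model assumptions, parameter choices, null models, and known
limitations are described in [docs/methods.md](docs/methods.md).
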