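# meioconjsim

Quantitative models and assay operators for chromosome segregation after
loss of **alternative homolog conjunction (AHC)** in *Drosophila* male
meiosis.

Male fruit flies hold their homologous chromosomes together without
crossovers or synaptonemal complexes, using a dedicated protein linkage
(MNM/SNM/TEF/UNO).  When that linkage is lost, homologs enter meiosis I
as free univalents and segregate at random; whether the *second*
division then still splits sister chromatids 1:1 is invisible to direct
imaging but leaves a statistical fingerprint in spermatid FISH data.
This package implements the models and measurement operators needed to
read that fingerprint, for geneticists and cell biologists analyzing
meiotic segregation, spermatid DNA-content, time-lapse and
protein-motif data — with seeded synthetic-data generators replacing
the fly work so every operator is testable end to end.

## What it computes

**Segregation models** (`meioconjsim.model`).  A scenario lists up to 8
homolog pairs, each *bivalent* (splits 1:1 at meiosis I) or a
*univalent pair* (each homolog, an intact 2-chromatid unit, tosses a
fair coin for its pole).  Meiosis II either splits each chromosome's two
sister chromatids 1:1 (`regular_sisters`) or sends every chromatid
independently to either spermatid (`random_chromatids`).  The package
enumerates the full tetrad sample space exactly (rational arithmetic)
and also simulates it (seeded Monte Carlo).  Key statistics:

* **FISH class probabilities** — with a red probe on the X and a green
  probe on the Y, each spermatid is `none`, `red_only`, `green_only` or
  `both`.
* **0/RG ratio** = P(none) / P(both).  For X/Y univalents it
  discriminates the meiosis II rules:
  random M I + regular M II gives 0/RG = **1**, while random M I +
  random chromatid M II gives 0/RG = 25/9 = **2.77**
  (class law 25/64, 15/64, 15/64, 9/64).
* **Meiosis I centromere patterns** — with all 8 centromere units free,
  the unordered pole splits 4:4, 5:3, 6:2, 7:1, 8:0 occur with
  probabilities 70/256, 112/256, 56/256, 16/256, 2/256.
* **DNA-content variability** — per-cyst s.d. of mean-normalized
  spermatid DNA contents; for 8 independent unit-content univalents the
  spermatid content is Binomial(8, ½) and the statistic converges to
  √2/4 ≈ 0.354.

**FISH scoring** (`meioconjsim.fish`): classify per-nucleus red/green
spot counts (nuclei with ≥2 spots of one color and none of the other
are excluded as unscorable), summarize per cyst, aggregate per genotype
(mean ± sample s.d.).

**Image quantification** (`meioconjsim.imagequant`): the published
measurement chain for spermatid DNA content — max projection, min-max
histogram reset inside the ROI, local-mean threshold (radius 15 px),
distance-transform watershed for touching nuclei, particle filter
(area 1–25 µm², circularity 0.70–1.00), ≤10%-missed QC rule, integrated
intensity, per-cyst normalized s.d. — plus the time-lapse dot-intensity
normalization (ten brightest frames → 100 a.u.).

**Motif scanning** (`meioconjsim.motifs`): exhaustive search for the
separase cleavage consensus **[E/D]XXR** and the docking motif
**[L/V/I/M]PE**, the in-silico non-cleavable mutation (both anchors →
alanine, the E130A/R133A design), and per-column conservation of a hit
across a multiple alignment.

**Synthetic data** (`meioconjsim.synth`): seeded generators for FISH
count tables, cyst images with ground-truth labels, motif-planted
protein families and intensity traces.

## Worked example

```
$ meioconjsim predict --scenario examples/xy_univalent_random.yaml
scenario: xy_univalent_random_chromatids (hash 6224e489ebf6)
FISH class probabilities (exact):
  none         0.390625
  red_only     0.234375
  green_only   0.234375
  both         0.140625
  0/RG: 25/9 = 2.7778
  normal:abnormal: 15/17 = 0.8824
M I centromere segregation patterns (exact):
  1:1   0.500000
  2:0   0.500000
```

Reading: if X and Y univalents segregate randomly at both divisions,
39% of spermatids carry no sex chromosome and 14% carry both, so
zero-signal nuclei should outnumber red+green nuclei 2.77-to-1.  An
observed 0/RG near 1 instead indicates that meiosis II still splits
sisters regularly (compare `--scenario conjunction_null`, which prints
0/RG = 1 and the 4:4 … 8:0 pattern spectrum).

The same prediction can be confronted with (synthetic) data:

```
$ meioconjsim synth fish --scenario examples/xy_univalent_random.yaml \
      --n-cysts 13 --seed 1 --out-prefix /tmp/run
$ meioconjsim fish-score --in /tmp/run_fish.csv --out-prefix /tmp/run
0/RG = 2.831 +/- 0.632 (n = 13 cysts); abnormal fraction = 0.519 +/- 0.087
```

Thirteen 64-spermatid cysts carry a lot of sampling noise in the ratio
(both-signal nuclei are rare); the per-cyst table written next to the
summary has the class fractions.  Other commands: `simulate`,
`quantify`, `trace-normalize`, `scan`, and `synth image|proteins|trace`;
every file-writing command also writes a JSON run manifest with seeds
and input/output paths.

## Layout

```
src/meioconjsim/   scenario.py  model.py  fish.py  imagequant.py
                   motifs.py    synth.py  io.py    cli.py
tests/             unit, property and headline-prediction tests
docs/methods.md    model assumptions, parameter choices, limitations
examples/          ready-made scenario files
```
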