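# tetramap

Nucleosome positioning and promoter architecture analysis for archaeal
MNase-seq data.

Archaea such as *Haloferax volcanii* package their GC-rich circular genomes
with histone **tetramers** that protect only ~60 bp of DNA (versus ~147 bp
for the eukaryotic octamer), producing a dense, short-period chromatin
landscape: roughly one nucleosome every ~70 bp, with tighter spacing inside
genic regions than between genes. `tetramap` implements the full desk-side
analysis for this kind of data:

* **Smoothing.** Per-base MNase protection coverage `x[i]` is smoothed with
  a symmetrical convolution sum

  `y[i] = Σ_{j=-M/2}^{M/2} G[j] · x[i-j]`,  `G[j] ∝ exp(-j²/2σ²)`,  `σ = M/6`,

  so the length-M window spans 6σ (~99.7% of the Gaussian mass). The default
  bandwidth is M = 27 bp; a two-pass simple moving average (40 bp, 15 bp) is
  available as an alternative, and bandwidth selection by Pearson
  correlation against the raw track is built in.
* **Nucleosome calling.** Maxima of the smoothed signal are dyads
  (midpoints), minima are linkers; peak magnitude is not considered by
  default. Spacing and density statistics are stratified by genic regions
  (transcribed span + 40 bp upstream of the 5′ end) versus non-genic,
  and occupancy can be normalized into occupied / depleted / transition
  states.
* **Dyad sequence composition.** Mono- and dinucleotide counts around
  called dyads, the GC gradient from fragment edge to midpoint, position
  probability / information-content (bit) matrices, and an exact
  permutation test for ~10-bp dinucleotide periodicity.
* **Transcript-unit refinement.** RNA-seq coverage classifies predicted
  annotations as expressed, trims/extends their boundaries to the coverage
  plateau, merges operon neighbors whose intergenic gap is fully covered,
  and calls novel transcripts in annotation deserts.
* **Promoter architecture.** TSS/TTS-anchored occupancy matrices
  (anchor ± 200 bp, strand-oriented, row-mean normalized), aggregate
  profiles, detection of the nucleosome-depleted region (NDR) with its
  −1/+1 flanking nucleosomes, 5′-versus-3′ NDR comparison with bootstrap
  confidence intervals, and average-linkage hierarchical clustering
  (1 − Pearson r distance) of per-transcript profiles into subclades.
* **Synthetic data.** A fully seeded generator plants every one of those
  features — genome GC, class-specific dyad spacings, NDR geometry, dyad GC
  ramps, operons, novel transcripts — with ground-truth tables, so each
  stage is testable without any external download.

## Worked example

```python
from tetramap.simulate import SimulationConfig, simulate, truth_compare
from tetramap import smoothing, calling

bundle = simulate(SimulationConfig(seed=1))          # 200 kb circular genome
smoothed = smoothing.convolve(bundle.mnase, smoothing.gaussian_kernel(27))
calls = calling.call_nucleosomes(smoothed)

regions = calling.RegionSet(bundle.replicon, bundle.genic_mask)
spacing = calling.peak_spacing(calls, regions)
density = calling.nucleosome_density(calls, bundle.replicon)
recovery = truth_compare([c.midpoint for c in calls],
                         bundle.truth_dyads.midpoint.to_numpy(),
                         tolerance=5, length=bundle.replicon.length)

print(f"nucleosome calls:      {len(calls)}")
print(f"density:               {density:.1f} per kb")
print(f"genic spacing:         {spacing['genic']['mean']:.1f} bp (n={spacing['genic']['n']})")
print(f"non-genic spacing:     {spacing['non_genic']['mean']:.1f} bp (n={spacing['non_genic']['n']})")
print(f"dyad recovery (+/-5):  {100*recovery['recall']:.1f}%  MAE {recovery['mae']:.2f} bp")
```

prints

```
nucleosome calls:      2615
density:               13.1 per kb
genic spacing:         69.1 bp (n=1032)
non-genic spacing:     76.9 bp (n=1431)
dyad recovery (+/-5):  96.7%  MAE 0.94 bp
```

The generator planted dyads with mean spacing 68.5 bp in genic and 76.1 bp
in non-genic regions at 30× coverage; the caller recovers 96.7% of them to
within 5 bp and reproduces both class means to ~1 bp. Density (13.1/kb) is
the reciprocal of the overall mean spacing, about one nucleosome per 75 bp —
the short repeat characteristic of tetramer-based chromatin.

The same stages are available from the shell:

```bash
tetramap simulate --seed 1 --out-dir sim/
tetramap coverage sim/fragments.bed --genome sim/genome.fasta --out cov.bedgraph
tetramap smooth cov.bedgraph --genome sim/genome.fasta --m 27 --out smooth.bedgraph
tetramap callnuc smooth.bedgraph --genome sim/genome.fasta --out calls.bed
tetramap transcripts sim/rna.bedgraph --annotations sim/annotations.gff3 \
    --genome sim/genome.fasta --out units.gff3
tetramap report sim/mnase.bedgraph --genome sim/genome.fasta --units units.gff3 \
    --out report.tsv
```

## Layout

```
src/tetramap/
  core.py        domain types (Replicon, CoverageTrack, NucleosomeCall, ...)
  io.py          FASTA / bedGraph / BED / GFF3 / config readers and writers
  smoothing.py   Gaussian & SMA convolution, window selection, correlation
  calling.py     extrema -> dyad calls, spacing/density, occupancy states
  dyadseq.py     dyad-centered composition, GC gradient, periodicity tests
  transcripts.py RNA-seq-driven transcript-unit refinement
  profiles.py    anchored matrices, NDR detection, profile clustering
  simulate.py    seeded ground-truth generator and recovery scorers
  cli.py         `tetramap` command-line interface
```

See `docs/methods.md` for the modeling choices, parameter defaults, and
known limitations.
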