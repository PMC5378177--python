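# nucpos

Genome-wide nucleosome positioning analysis from paired-end MNase-seq, built
for gene-dense genomes where the ATG serves as the profile anchor (e.g.
*Dictyostelium*, whose 5′ UTRs are mostly <100 bp). The package turns
MNase-protected fragment alignments into dyad-midpoint maps, gene-anchored
occupancy profiles, nucleosome peak calls, nucleosome-repeat-length (NRL)
estimates, and per-gene differential-positioning ("remodeled" /
"mismodeled") classifications, and links those calls to expression gene sets
with hypergeometric enrichment statistics. A ground-truthed synthetic
MNase-seq generator makes every stage testable without external data.

It is intended for chromatin/regulatory-genomics analysts comparing
nucleosome organization between conditions (developmental stages, remodeler
mutants) with replicated MNase-seq.

## Method

- **Dyads.** Properly paired fragments are size-selected at 150 ± 30 bp
  (SAM ISIZE, inclusive) and reduced to their midpoints — putative
  nucleosome dyads — binned at 1 bp.
- **Profiles.** Per-gene windows (default −600..+600 bp) are cut around the
  ATG, stop codon, or +1 nucleosome in coding orientation (downstream
  positive), averaged across genes, and normalized to the window mean.
  Dividing chromatin by an MNase-digested naked-DNA control (CHR/DNA ratio)
  corrects sequence/mappability structure and exposes the promoter
  nucleosome-depleted region (NDR).
- **Peaks and NRL.** Profiles are smoothed with an Epanechnikov kernel,
  K(u) = 0.75(1 − u²) for |u| ≤ 1, bandwidth 30 bp; peaks are strict local
  maxima above a noise floor. The +1 nucleosome is the first peak downstream
  of the ATG; the NRL is the OLS slope of cumulative peak distance from the
  +1 against nucleosome index, y_k = β₀ + NRL·k, over the first five
  nucleosomes.
- **Differential positioning.** Per gene, peaks from two conditions are
  paired summit-to-summit (optimal assignment within 85 bp); a nucleosome is
  *nonmatching* when summits differ by >10 bp or heights by >2-fold, or when
  it has no partner. A gene is called remodeled when every replicate
  comparison finds ≥3 nonmatching nucleosomes within 1000 bp 3′ of the ATG.
- **Statistics.** Per-gene profiles cluster with Euclidean k-means (k = 5);
  overlap between positioning calls and differential-expression sets is
  scored with the upper-tail hypergeometric probability
  P = Σ_{i≥k} C(K,i)·C(N−K,n−i)/C(N,n).

See `docs/methods.md` for assumptions, parameter defaults, and the
synthetic-data model.

## Worked example

```python
from nucpos import SimulationConfig, hypergeom_enrichment
from nucpos.pipeline import simulate_cohort, condition_nrl, measure_ndr

cfg = SimulationConfig(seed=1, n_genes=200)          # growth + mound, 2 replicates
cohort = simulate_cohort(cfg)                        # fragments -> dyad tracks
for cond in cfg.conditions:
    est = condition_nrl(cohort.pooled_track(cond), cohort.genes)
    print(f"{cond:7s} NRL = {est.nrl:6.1f} bp  (r^2 = {est.r_squared:.4f})")
center, width = measure_ndr(cohort.pooled_track("growth"),
                            cohort.naked_track, cohort.genes)
print(f"promoter NDR: width = {width} bp, center = {center:+.1f} bp from ATG")
res = hypergeom_enrichment(N=12750, K=2856, n=7000, k_obs=1700)
print(f"remodeled x DE overlap: expected {res.expected:.0f}, "
      f"observed {res.k_obs}, p = {res.p_value:.2e}")
```

prints

```
growth  NRL =  169.8 bp  (r^2 = 1.0000)
mound   NRL =  173.0 bp  (r^2 = 1.0000)
promoter NDR: width = 166 bp, center = -94.5 bp from ATG
remodeled x DE overlap: expected 1568, observed 1700, p = 9.08e-09
```

The two NRLs recover the generator's planted repeat lengths (170 bp growth,
173 bp mound); the ~170 bp depleted run upstream of the +1 nucleosome is the
promoter NDR; and the enrichment line scores a 1700-gene overlap between a
2856-gene remodeled set and a 7000-gene DE set in a 12,750-gene genome —
134 genes above expectation, far beyond chance.

The same stages are scriptable from a shell:

```sh
nucpos simulate --seed 3 --n-genes 60 -o sim/
nucpos dyads --alignments sim/growth_rep1.sam -o growth1.bedgraph
nucpos profile --track growth1.bedgraph --gff sim/genes.gff3 \
       --window -600 1200 -o profile.tsv
nucpos callpeaks --profile profile.tsv -o peaks.tsv
nucpos nrl --peaks peaks.tsv -o nrl.tsv
nucpos all --seed 5 -o run/        # every stage + manifest
```

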