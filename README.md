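# loopshift

Statistics for acute-depletion chromatin experiments: what happens to cohesin
occupancy and 3D genome organisation when a chromatin-binding transcription
factor is rapidly degraded?

Studies of this design pair untreated and degron-treated samples across
several readouts — Hi-C-style contact maps, cohesin/factor ChIP-seq with
spike-in controls, ATAC peak sets, 4C profiles, ChIP-MS peptide-count tables
— and connect them with a chain of bespoke statistics.  `loopshift`
implements that chain as a tested, reusable library:

- **Contact maps**: ICE balancing with low-coverage masking, the >20 kb pair
  filter, exact-depth downsampling, distance-expected profiles and the
  observed/expected (O/E) transform, distance-decay curves.
- **Compartments**: correlation-matrix eigenvector (E1), orientation against
  an active-chromatin track, and the saddle compartmentalization score
  **(AA + BB) / 2AB**, including a split-half cross-validated variant that is
  unbiased on compartment-free maps.
- **Pileups & insulation**: aggregate peak analysis (APA) with the central
  3×3 enrichment score, diagonal (local) pileups, rescaled meta-domain maps,
  diamond insulation scores and aggregated insulation deltas around features.
- **Loops**: multi-resolution loop merging, per-loop strength and log2FC,
  length-rank GSEA with a label-permutation null, element enrichment at loop
  anchors and gene-category enrichment inside loops (both with
  length-preserving relocation nulls), and the responsive-loop classifier
  (top/bottom-N scoring of >500 kb loops by factor signal + |cohesin log2FC|
  at ATAC peaks).
- **ChIP quantification**: RPGC and spike-in scale factors, feature matrices
  and meta-profiles, priority peak annotation, bound/unbound gene selection,
  row z-scores, Ward clustering with an elbow choice of k, co-occupancy
  categories, the ChIP-qPCR percent-input formula, expression-breadth and
  CRISPR-essentiality annotations.
- **ChIP-MS**: isoform→protein PSM aggregation, the ≥2× chip/input candidate
  filter, log2 enrichment, Venn partitions.
- **4C**: 50 bp-bin profile smoothing and region-over-background ratios.
- **Synthetic data** (`loopshift.simulate`): every input class with planted,
  recorded truth — power-law maps with biases/compartments/TADs/loops,
  factor-binding landscapes with co-occupancy, paired depletion experiments,
  PSM tables, 4C profiles — so the full pipeline is testable without any
  external download.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Simulate a paired depletion experiment, normalise the untreated map, and run
the three headline statistics:

```python
import loopshift as ls
from loopshift.compartments import cross_validated_saddle
from loopshift.pileup import apa
from loopshift.loops import classify_responsive_loops

cfg = ls.SimulationConfig(seed=7)
exp = ls.simulate_perturbation_experiment(cfg)

balanced = {c: ls.ice_balance(ls.filter_min_distance(m, 20_000))
            for c, m in exp.matrices_before.items()}
expected = {c: ls.expected_by_distance(m) for c, m in balanced.items()}

saddle = cross_validated_saddle(exp.matrices_before, seed=7)
print(f"compartment score (AA+BB)/2AB: {saddle.enrichment:.2f}")

pile = apa(balanced, exp.loops, expected, flank_bins=10)
print(f"APA central 3x3 enrichment:    {pile.enrichment:.2f} over {pile.n_windows} loops")

cls = classify_responsive_loops(
    exp.loops, exp.tf_peaks, exp.down_cohesin_peaks, exp.atac_peaks,
    exp.tf_track, exp.cohesin_lfc_per_atac,
    top_n=len(exp.truth.responsive_loops))
truth = set(exp.truth.responsive_loops.tolist())
hit = len(truth & set(cls.responsive.tolist()))
print(f"responsive loops recovered:    {hit}/{len(truth)}")
```

Output:

```
compartment score (AA+BB)/2AB: 1.61
APA central 3x3 enrichment:    1.99 over 20 loops
responsive loops recovered:    12/12
```

The saddle score of 1.61 reflects the planted compartment amplitude (a
compartment-free map scores 1.0); the APA enrichment of 1.99 recovers the
planted loop strength of 2.0; the classifier recovers every planted
responsive loop from the factor/cohesin/ATAC evidence alone.

The same analysis runs end to end from the command line, writing every
artifact plus a checksummed manifest:

```sh
loopshift --seed 7 pipeline --outdir results/run1
```

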