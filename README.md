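# atacdyn

Time-course chromatin accessibility analysis for replicated ATAC-seq-style
designs. Given a peak-by-sample fragment count matrix over a day grid
(the canonical layout is days 0, 3, 7, 10, 28 with two replicates each —
an experimental-evolution course in which a selective regime acts between
days 0 and 7 and is then released), the package answers four questions:

1. **Which peaks change between consecutive timepoints?** A
   negative-binomial Wald test with median-of-ratios normalization,
   trend-shrunk method-of-moments dispersions, and BH adjustment within
   each day pair (`compare_day_pair`, `consecutive_comparisons`,
   `summarize_wave`).
2. **Which peaks are temporally dynamic over the whole course?** A
   Gaussian-process likelihood-ratio screen comparing an RBF + white
   kernel against a static white-noise model on standardized profiles;
   peaks are called *strict* (χ²(1) p < 0.05) or *loose* (LR < −0.25)
   dynamic (`dynamic_screen`).
3. **What temporal shapes do the dynamic peaks follow?** A truncated
   mixture of hierarchical GPs with MAP-EM, hyperparameter optimization
   and an integrated-marginal merge phase, exposed as a
   scikit-learn-style estimator (`GPMixtureClusterer`).
4. **Are particular annotation classes or gene sets involved?**
   Two-proportion Z tests on annotation composition
   (`compare_composition`), hypergeometric ORA and preranked GSEA with a
   permutation null, including reversibility flags for sets enriched with
   opposite signs at selection onset (day 0 vs 3) and release
   (day 7 vs 10) (`preranked_gsea`, `flag_reversible_sets`).

Supporting machinery: BED interval I/O with bookended merging and
provenance (`merge_intervals`), fragment counting (`count_fragments`),
midpoint-based peak annotation (`annotate_peaks`), a fully
ground-truthed synthetic study generator (`simulate_dataset`), a pipeline
orchestrator (`run_full`), and an `atacdyn` CLI. The statistical details
are in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a small study and run the main analyses:

```python
import numpy as np
from atacdyn import (SimulationConfig, simulate_dataset, consecutive_comparisons,
                     summarize_wave, dynamic_screen, fit_gp_mixture, percent)
from atacdyn.pipeline import standardized_profiles

config = SimulationConfig(n_peaks=400, seed=1)
annotation, peaks, cm, truth = simulate_dataset(config)
print("counts shape:", cm.counts.shape, "days:", cm.days)

wave = summarize_wave(consecutive_comparisons(cm))
print(wave.to_string(index=False))

dyn = dynamic_screen(cm, seed=1)
n_strict = int(dyn["dynamic_strict"].sum()); n_loose = int(dyn["dynamic_loose"].sum())
print(f"dynamic peaks: {n_strict} strict ({percent(n_strict, len(dyn), 2)}%), "
      f"{n_loose} loose ({percent(n_loose, len(dyn), 1)}%)")

profiles = standardized_profiles(cm)
loose = dyn["dynamic_loose"].to_numpy()
model = fit_gp_mixture(profiles[loose], cm.samples["day"].to_numpy(float), K_max=12, seed=1)
print("clusters:", model.n_clusters_, "sizes:", np.bincount(model.labels_).tolist())
```

Output:

```
counts shape: (400, 10) days: [0.0, 3.0, 7.0, 10.0, 28.0]
 day_a  day_b  n_up  n_down  n_sig
   0.0    3.0    35      29     64
   3.0    7.0     2       3      5
   7.0   10.0    51      55    106
  10.0   28.0     1       1      2
dynamic peaks: 97 strict (24.25%), 225 loose (56.2%)
clusters: 12 sizes: [18, 17, 31, 10, 21, 34, 48, 2, 9, 9, 14, 12]
```

The injected two-wave structure is visible immediately: significant
changes concentrate in the day 0→3 and 7→10 transitions, and the
transitions that received no injected effects (3→7, 10→28) stay near the
false-discovery floor.

## Command line

Every stage is also a subcommand:

```bash
atacdyn simulate --n-peaks 400 --seed 1 --outdir synthetic
atacdyn diff --counts synthetic/counts.tsv --samples synthetic/samples.tsv --outdir diff_out
atacdyn dynamics --counts synthetic/counts.tsv --samples synthetic/samples.tsv --out dynamics.tsv
atacdyn run --outdir full_run --n-peaks 3500 --seed 0   # everything, ~3 min
atacdyn report --rundir full_run
```

`atacdyn run` writes one TSV per stage plus `report.json` (headline
numbers) and `manifest.json` (seed, config hash, package versions). Exit
codes: 0 success, 2 validation error, 1 stage failure.

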