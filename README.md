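# poremod

Detection of RNA modifications in nanopore direct-RNA sequencing data.

Therapeutic RNAs carry backbone (phosphorothioate), ribose (2′OMe, 2′MOE,
2′F, LNA) and base (m1Ψ, 5moU, m5C, 5iodoC) modifications for which
dedicated modification-aware basecallers mostly do not exist. `poremod`
implements the two complementary detection routes that work without one,
plus the tooling to benchmark both:

1. **Basecall-error analysis.** Modified nucleotides disturb basecalling,
   producing deletion-dominant errors at and near modified sites. The
   per-position statistic is the *total variation percentage*

   ```
   TV = 100 · (mismatches + deletions + insertions)
            / (A + C + G + U calls + deletions + insertions)
   ```

   computed from a pileup of aligned reads (mapping quality ≥ Q20,
   secondary/unmapped excluded), with a per-error-type breakdown whose
   components sum exactly to the total.

2. **Raw-current analysis.** Independent of the basecaller, a modification
   perturbs the ionic current. From per-read, per-position features
   (dwell time, current mean, current SD; log-dwell, robustly scaled per
   position), sliding 3-nt windows give 9-dimensional vectors per read, and
   the modified and control samples are compared per position with the
   two-sample **energy distance**

   ```
   E(X, Y) = 2/(nm) Σᵢ Σⱼ ‖xᵢ − yⱼ‖ − 1/n² Σᵢ Σⱼ ‖xᵢ − xⱼ‖ − 1/m² Σᵢ Σⱼ ‖yᵢ − yⱼ‖
   ```

   a nonparametric multivariate statistic that is zero when the
   distributions coincide.

Around these two scores the package provides site-level benchmarking
(AUROC, step-wise average precision, thresholded confusion matrices, and
proximity attribution of false positives to nearby true sites),
summarization of modification-aware basecaller output (bedMethyl-style
pileups, the canonical-call percent-modified denominator, cumulative
modification curves), and a fully seeded synthetic-data generator that
emulates the error and signal phenomenology of direct-RNA runs so that
every stage is testable without sequencing data.

## Worked example

```python
from poremod import (SimConfig, simulate_dataset, coverage_filter, preprocess,
                     profile, ScoredPositions, auroc, auprc)

cfg = SimConfig(seed=1)                       # 120-nt reference, 9 modified sites
bundle = simulate_dataset(cfg)

tv = bundle.pileup_modified.total_variation()
sites = list(bundle.truth.positions)
print(f"median TV at modified sites: {tv.loc[sites].median():.1f}%")
print(f"median TV elsewhere:         {tv.drop(sites).median():.1f}%")

mod, ctl = (coverage_filter(s) for s in
            (bundle.signal_modified, bundle.signal_control))
mod_p, ctl_p, _ = preprocess(mod, ctl)
prof = profile(mod_p, ctl_p)

for name, scores in (("total variation", tv), ("energy distance", prof.values())):
    sp = ScoredPositions.from_scores(scores, sites)
    print(f"{name:16s} AUROC {auroc(sp):.3f}  AUPRC {auprc(sp):.3f}")
```

prints

```
median TV at modified sites: 21.5%
median TV elsewhere:         3.8%
total variation  AUROC 0.999  AUPRC 0.989
energy distance  AUROC 0.919  AUPRC 0.337
```

The modified sample's error rate jumps from a ~4% background to >20% at
modified sites, so ranking positions by total variation separates sites
almost perfectly. The energy distance also detects every site cluster but
deliberately responds to a *wider* footprint (any 3-nt window touching a
perturbed position, plus the dwell effect ~10 nt downstream in reference
coordinates), so at exact-site granularity its AUPRC is lower — the same
behavior seen on real constructs, where signal disruption extends beyond
the modified nucleotide.

The same stages are available from the command line:

```sh
poremod simulate --seed 1 --out sim/
poremod run --config run.yaml          # errors → signal → evaluate → modsummary
poremod pileup aligned.bam ref.fasta --out pileup.csv   # from a real BAM
```

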