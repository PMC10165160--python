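# abtau

Surface-based analysis of amyloid (Aβ) and tau PET deposition and their
distinct and joint effects on cortical thickness.

Amyloid and tau are the two hallmark proteinopathies of Alzheimer's
disease, but they start in different cortical territories and relate to
neurodegeneration differently: at *normal* deposition levels both tend to
accompany slightly **thicker** cortex, while *abnormal* tau accompanies
**thinning** — and when both pathologies are abnormal and spatially
overlapping, thinning is strongest. This package implements that analysis
end to end:

1. **Quantify** per-vertex SUVR overlays into regional means and three
   composites (global Aβ, global tau, medial-temporal tau).
2. **Categorize** old subjects into four groups (`nAb/nTau`, `aAb/nTau`,
   `nAb/aTau`, `aAb/aTau`) against normative cut-points — the 96th
   percentile of a normal fitted to a young reference cohort. Tau is
   abnormal if *either* the global or the medial-temporal composite
   exceeds its cut.
3. **Correct** partial-volume spill-in with a per-vertex regression model
   fitted on the young cohort (whose gray signal is pure spill-in).
4. **Map** per-group probabilistic abnormality atlases and Aβ × tau
   regional cross-correlograms.
5. **Associate** thickness with deposition: vertex-wise GLMs with
   Benjamini-Hochberg FDR, and two-step residualized regional models with
   permutation family-wise thresholds.
6. **Resonance**: a per-subject Pearson correlation between the Aβ and tau
   vertex maps, quantifying how spatially overlapping the two pathologies
   are, and its (negative) association with thickness in the doubly
   abnormal group.

A synthetic cohort generator with known ground truth (group labels, true
specific binding, true spill-in, true effect sizes) drives testing and the
worked examples; its defaults match the study conditions (97 + 47 young
subjects, 200 per old group, 4,096 gray vertices). See
[docs/methods.md](docs/methods.md) for the full model.

## Worked example

```python
from abtau.synthetic import GeneratorConfig, generate_cohort
from abtau.pipeline import PipelineConfig, analyze_cohort
from abtau.categorize import GROUPS

# a small cohort (30 subjects/group on a 34 x 8 grid) for a quick run;
# drop the overrides to use the full study conditions
gen = GeneratorConfig(seed=5, grid_shape=(34, 8), n_young_abeta=30,
                      n_young_tau=20, n_per_group={g: 30 for g in GROUPS})
cohort = generate_cohort(gen)
cfg = PipelineConfig(generator=gen, n_perm=500, seed=5)
res = analyze_cohort(cohort.subject_frame, cohort.overlays,
                     cohort.geometry, cfg)

c = res.cutpoints
print(f"cut-points: abeta={c.abeta_global:.3f} "
      f"tau={c.tau_global:.3f} mtl={c.tau_mtl:.3f}")
for g in GROUPS:
    m = res.summary["resonance_mean"][g]
    signs = res.summary["vertexwise_signs"][g]
    print(f"{g}: resonance={m:+.3f} "
          f"abeta:{signs['global_abeta']['direction']} "
          f"tau:{signs['global_tau']['direction']} "
          f"resonance:{signs['resonance']['direction']}")
```

Output:

```text
cut-points: abeta=1.209 tau=1.100 mtl=1.106
nAb/nTau: resonance=-0.000 abeta:+ tau:+ resonance:0
aAb/nTau: resonance=-0.076 abeta:- tau:+ resonance:0
nAb/aTau: resonance=-0.024 abeta:0 tau:- resonance:0
aAb/aTau: resonance=+0.482 abeta:0 tau:- resonance:-
```

Already at this small scale the headline structure appears: tau associates
*positively* with thickness in tau-normal groups and *negatively* in
tau-abnormal ones, resonance is high only in `aAb/aTau`, and the
FDR-surviving negative resonance-thickness association appears only there.
(The stray `abeta:-` in `aAb/nTau` is a small-sample artifact — with only
272 gray vertices a single significant vertex can set a direction; at the
default 4,096-vertex, 200-per-group scale the full expected sign pattern
is recovered, which is what the acceptance tests check.)

The same pipeline is available from the command line, writing a complete
run directory (cohort files, per-stage tables, stat maps, `summary.json`,
log):

```bash
abtau run --seed 7 --out runs/demo            # full pipeline
abtau categorize --out runs/demo              # re-run one stage in place
```

## Package layout

| Module | Purpose |
| --- | --- |
| `abtau.cohort` | geometry, overlays, subjects, region means |
| `abtau.io` | text/MGH/GIFTI readers and writers, cohort round-trip |
| `abtau.quantify` | SUVR, composite definitions, regional tables, panel |
| `abtau.categorize` | young reference fits, cut-points, group assignment |
| `abtau.pvc` | PSF, spill-in synthesis, model fit, correction |
| `abtau.atlas` | binarized probabilistic atlases, cross-correlograms |
| `abtau.association` | GLMs, FDR, residualization, permutation FWE |
| `abtau.resonance` | per-subject Aβ-tau spatial correlation and its model |
| `abtau.synthetic` | ground-truth cohort generator |
| `abtau.pipeline` / `abtau.cli` | stage orchestration, run directories, CLI |
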