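# hemilat

Hemispheric asymmetry analysis of weighted brain networks.

The two hemispheres of the human brain are not topologically
equivalent: structural (white-matter) and functional (resting-state)
connectivity can each favor one hemisphere, and the two modalities do
not have to agree. `hemilat` implements the complete analysis chain
used to ask that question with graph theory, for researchers working
with connectome matrices on the AAL-90 parcellation (45 homotopic
region pairs per hemisphere):

1. **Network construction** — functional connectomes from ROI time
   series (Pearson correlation, Fisher r-to-z, negative connections
   removed) and structural connectomes from streamline counts and ROI
   volumes (streamline density `w_ij = counts_ij / (vol_i + vol_j)`).
2. **Hemispheric decomposition** — interhemispheric connections are
   discarded, leaving two 45×45 intrahemispheric networks per subject
   ordered by homotopic pair, and functional networks are thresholded
   over a sparsity grid (default 0.10–0.35 in steps of 0.01, retaining
   supra-threshold weights) with metrics integrated over the grid.
3. **Weighted small-world metrics** — clustering coefficient *C*<sub>w</sub>
   (Onnela geometric-mean triangle intensity), characteristic path
   length *L*<sub>w</sub> on reciprocal-weight edge lengths
   (*L*<sub>ij</sub> = 1/*w*<sub>ij</sub>), global/local/nodal
   efficiencies, and small-worldness
   σ = γ/λ = (*C*<sub>w</sub>/*C*<sub>w</sub><sup>rand</sup>) /
   (*L*<sub>w</sub>/*L*<sub>w</sub><sup>rand</sup>) against 100
   degree-preserving rewired null networks.
4. **Laterality index** — per subject and metric,
   `AS(X) = 100 × [X(R) − X(L)] / [X(R) + X(L)]`, bounded in ±100;
   negative values indicate a leftward advantage for every metric
   except *L*<sub>w</sub>, whose sign flips in interpretation.
5. **Lateralized connections** — a paired network-based statistic
   (NBS): edge-wise paired t-tests between homotopic edges,
   suprathreshold connected components, and a within-subject
   hemisphere-swap permutation null of maximal component size
   (family-wise error controlled, default 5,000 permutations).
6. **Group statistics** — hemisphere-effect ANCOVA with gender
   covariate and Benjamini–Hochberg FDR across metrics/regions, and
   partial correlations between asymmetry scores and behavioral
   measures adjusting for age, gender, handedness and education.

Because suitable public datasets with paired structural/functional
connectomes are scarce, the package ships a first-class synthetic
cohort generator (`hemilat.synth`) producing paired connectomes with
*known, injectable* hemispheric asymmetry at the global, nodal and
edge-subnetwork level, plus behavioral scores coupled to each subject's
true asymmetry — so every stage of the pipeline is testable end to end.

## Worked example

Recover a known 10% leftward structural weight advantage:

```python
import numpy as np
from hemilat import (
    simulate_cohort, split_hemispheres, default_node_table,
    normalize_weights_joint, small_worldness, asymmetry_score,
)

spec = {"global_scale_delta": 0.1, "direction": "leftward"}
cohort = simulate_cohort(
    12,
    {"asymmetry": spec, "structural": {"noise_sd": 0.05},
     "timeseries": {"n_timepoints": 100}},
    seed=42,
)
node_table = default_node_table()
as_cw = []
for subj in cohort.subjects:
    left, right = split_hemispheres(subj.structural, node_table)
    left, right = normalize_weights_joint(left, right)
    gm_l = small_worldness(left, n_null=20, seed=1)
    gm_r = small_worldness(right, n_null=20, seed=2)
    as_cw.append(asymmetry_score(gm_r.c_w, gm_l.c_w))

print(f"mean AS(C_w) = {np.mean(as_cw):+.3f}  (closed form for a 1.1x "
      f"left scaling: {100*(1-1.1)/(1+1.1):+.3f})")
print(f"sigma (left hemisphere, subject 1) = {gm_l.sigma:.3f}")
```

Output:

```
mean AS(C_w) = -4.749  (closed form for a 1.1x left scaling: -4.762)
sigma (left hemisphere, subject 1) = 1.045
```

The mean laterality of the clustering coefficient sits at the
closed-form value for a uniform 1.1× left scaling (scale-homogeneous
metrics inherit the weight ratio: AS = 100(1−c)/(1+c) for left = c ×
right), and σ ≈ 1 for these distance-free random networks, as expected
when a graph is its own degree-matched null.

The same analysis runs from the shell:

```sh
hemilat run --seed 42 --out results/        # full pipeline, 20 subjects
hemilat simulate --n-subjects 20 --seed 1 --out data/
hemilat build --modality functional --in data/ --out built/
hemilat metrics --in built/ --out metrics.tsv --n-null 100 --seed 1
hemilat asymmetry --metrics metrics.tsv --out asymmetry.tsv
hemilat nbs --left built/L --right built/R --t-threshold 3.0 \
    --n-perm 5000 --seed 1 --out nbs.json
hemilat stats --metrics metrics.tsv --asymmetry asymmetry.tsv \
    --cohort data/cohort.tsv --out stats
```

Every output file carries a comment header with the tool version, seed
and parameters; `run` writes a `manifest.json` with per-file checksums,
and two runs with the same config and seed are byte-identical.

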