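# morphattn

Individual-level morphological covariance brain networks with a
self-attention classifier and attention-based biomarker mapping.

## The problem

Structural MRI studies of autism spectrum disorder (ASD) need features that
capture how the *coordination* of gray-matter morphology between brain
regions differs between patients and controls, not just region-wise
averages. A morphological covariance network does this within a single
subject: every pair of regions is scored by how similar their distributions
of gray-matter voxel values are. This package builds those networks,
classifies subjects with a small self-attention model over the region
feature vectors, reads candidate biomarker regions off the attention
coefficients, and tests classifier significance with a label-flip
permutation test. A synthetic-cohort generator with known ground-truth
effect regions makes every stage testable without scan data.

## The model

For one subject, each retained atlas region contributes its gray-matter
voxel values. Regional densities are estimated by Gaussian-kernel KDE on a
grid of N points shared by all regions; for regions P and Q the symmetrised
Kullback–Leibler divergence

    D(P,Q) = Σᵢ [ P(i) log(P(i)/Q(i)) + Q(i) log(Q(i)/P(i)) ]

maps to the KL-based similarity x_PQ = exp(−D(P,Q)) ∈ (0, 1]. Collecting all
pairs gives the subject's M×M symmetric matrix X with unit diagonal
(M = 108 for a 116-region SRI24-style atlas after excluding the eight
cerebellar Vermis labels 108–115). Rows X_p are region feature vectors fed
to a stack of dot-product self-attention layers

    α_pq = softmax_q(Q_p·K_q / √d_K),   X¹_p = Σ_q α_pq V_q

with Leaky ReLU + layer-norm after each layer, mean-pooling over regions,
and a small batch-normed linear head ending in a sigmoid probability of ASD.
The coefficient α_pq is the weight with which region q's values enter region
p's output, so fused attention maps (averaged over layers and over correctly
classified subjects) with a mean+3 SD threshold nominate biomarker regions.
The classifier runs on a compact numpy reverse-mode autodiff engine included
in the package; no deep-learning framework is required.

## Worked example

```python
import morphattn as m
from morphattn.io import sampleset_from_cohort_subject

effect = m.EffectSpec(effect_regions=frozenset({2, 5, 9}), mean_shift=0.1)
cohort = m.simulate_cohort(20, 20, 20, effect, voxels_per_region=200, seed=42)
networks = [m.build_network(sampleset_from_cohort_subject(s), n_points=128)
            for s in cohort.subjects]
print(networks[0].X.shape)

config = m.ModelConfig(learning_rate=1e-2, weight_decay=0.0, max_epochs=150)
cv = m.stratified_cross_validate(networks, cohort.labels, config,
                                 k_folds=5, seed=1)
print(round(cv.mean_accuracy, 3), round(cv.auc, 3))
```

prints

```
(20, 20)
1.0 1.0
```

— each subject yields a 20×20 similarity matrix, and with a
1-standard-deviation mean shift injected into three regions the 5-fold
cross-validated accuracy and AUC on this 40-subject cohort are both 1.0
(the effect is strongly separable at this size). `ModelConfig()` defaults
instead reproduce the full-scale training recipe (Adam at 6e-6, batch 32,
weight decay 0.01, two single-head 32-dim attention layers), which is
appropriate for cohorts of ~1000 subjects, not for this toy size.

The same flow is available from the shell:

```
morphattn simulate --n-case 20 --n-control 20 --n-regions 20 \
    --effect-regions 2,5,9 --shift 0.1 --seed 42 --out-dir cohort/
morphattn run --config pipeline.yaml
```

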