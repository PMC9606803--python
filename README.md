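# assomap

Voxel-level **association (Asso) mapping** of resting-state fMRI, built as a
complete, tested analysis pipeline: temporal preprocessing, per-voxel graph
statistics, seed-based functional connectivity, covariate-adjusted group
inference with cluster-level permutation correction, SVM biomarker
evaluation and brain–behaviour correlation — together with a synthetic
two-group cohort generator that provides a ground-truth surface for
validating every stage.

## The statistic

Degree centrality (functional connectivity strength, FCS) counts how many
voxels a seed voxel is connected to, but ignores whether those neighbours
are also connected to each other — and a voxel whose neighbours all talk to
each other directly is not much of a hub.  The association index fixes this.
For voxel *i*, build the whole-brain graph with an edge between two voxels
whenever their Pearson correlation exceeds *r* = 0.25, and let

- *N* = number of neighbours of *i* (its degree; this is FCS), and
- *K* = number of edges among those *N* neighbours.

Then

```
Asso_i = ( N (N − 1) − 2 K ) / 2  =  C(N, 2) − K
```

is the number of neighbour pairs that are **not** directly interconnected —
pairs for which voxel *i* is a potential mediator.  High Asso marks genuine
integration hubs; a voxel inside a densely interconnected block has high FCS
but Asso near zero.

The pipeline applies this per subject (Asso map → z-transform → 6 mm FWHM
Gaussian smoothing), compares groups voxelwise with an OLS model
(`map ~ group + age + sex + education`), corrects clusters formed at voxel
p < 0.001 by a group-label permutation max-cluster-extent null (cluster
p < 0.05), uses the group-difference cluster as the seed for a Fisher-z
whole-brain FC analysis on a separately preprocessed (pre-smoothed) branch,
and finally evaluates the cluster-mean features as diagnostic biomarkers
with a leave-one-out linear SVM and Pearson/FDR-BH brain–behaviour
correlations against MMSE and MoCA.

Because no patient data are distributed, the package ships a synthetic
cohort generator (`assomap.synthetic_cohort`) that plants, in a
"patient" group: a hub whose neighbour graph collapses (the Asso deficit),
an increase in hub→DMN coupling (from anticorrelated toward positive), and
cognitive scores that decline linearly with each subject's planted severity.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (20 patients + 20 controls, 12³ grid, 120 frames at
TR = 2 s); each writes its tables under `results/` and bulky volumes under
`scratch/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_asso_mapping.py
python analysis/04_seed_fc.py
python analysis/05_classify.py
python analysis/06_correlate.py
```

The association group comparison prints (df = 35, cluster-forming
|t| ≥ 3.59):

```
 cluster_id tail  extent  peak_x_mm  peak_y_mm  peak_z_mm  peak_t  corrected_p
          1  neg      34      -13.5      -13.5      -10.5  -5.346        0.001
          2  neg       1       13.5        1.5      -10.5  -3.779        0.389
```

— a 34-voxel cluster of reduced Asso in patients sitting on the planted hub
region (corrected p = 0.001); it becomes the seed for the FC analysis, which
recovers a 49-voxel cluster of increased patient coupling over the planted
DMN stand-in (peak t = 7.74).  The biomarker stage then reports

```
accuracy    85.00%    sensitivity 85.00%    specificity 85.00%    AUC 0.948
nested (fold-wise cluster definition): accuracy 85.00%   AUC 0.948
```

and the correlation stage finds exactly the planted directions — hub Asso
correlates positively with cognition, hub→DMN FC negatively — all four
surviving FDR (e.g. Asso vs MMSE r = 0.63, FC vs MoCA r = −0.75, q < 0.05).

The same pipeline is scriptable from one config via the CLI:

```bash
assomap run-all --out runs/demo        # or: assomap simulate / preprocess /
                                       # asso / fc / stats / classify / correlate
```

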