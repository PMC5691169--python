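# fracnet

Functional brain-network construction and group comparison with a
**box-counting fractal dimension (BCFD)** edge measure, alongside the
standard linear-correlation (LC) and mutual-information (MI) measures.

Resting-state fMRI network studies represent each brain region (ROI)
as a node and score every pair of regional BOLD time series with a
dependence measure to define edges. Pearson correlation only captures
linear coupling; histogram mutual information captures nonlinear
shared information but is length-sensitive. The BCFD measure instead
rasterizes the joint phase portrait of two series x, y into an M x M
gray-level image (cell occupancy -> gray level z in 1..G) and
estimates the fractal dimension of that surface by differential box
counting: at scale r = s/M the image plane is tiled by s x s blocks,
each block spanning gray levels [g_min, g_max] costs

    n_r(i, j) = ceil(g_max / s') - ceil(g_min / s') + 1,   s' = ceil(sG/M)

boxes, N_r = sum over blocks, and

    D = slope of log N_r vs log(1/r)

by least squares. A flat surface gives D = 2 exactly; a binary
point-set variant (occupied blocks only, D in [0, 2]) is also
provided. Downstream, weighted matrices are proportionally
thresholded (keeping the strongest 10%...50% of connections), and the
binary graphs are summarized by clustering coefficient (CC),
characteristic path length (CPL), global efficiency (GE) and
small-worldness sigma = (CC/C_rand)/(CPL/L_rand) against
degree-preserving rewired null ensembles. Two groups of subjects are
compared per (measure, metric, density) cell with label-permutation
tests (1000 permutations, two-sided, add-one p-values).

The package is aimed at researchers who want to benchmark
edge-definition measures on surrogate data with known structure
(logistic-map orbit pairs of increasing complexity; noise-mixture
pairs of decaying similarity) and to exercise the full
connectivity -> graph -> statistics pipeline on synthetic two-group
cohorts before touching real data. See `docs/methods.md` for the
model details, parameter defaults and known limitations.

## Worked example

```python
import fracnet as fn

# three edge measures on a noisy linear pair (230 samples)
x, y = fn.paired_fixture("noisy-linear", seed=7, length=230)
print("lc   =", round(fn.pearson_correlation(x, y), 4))
print("mi   =", round(fn.mutual_information(x, y), 4), "bits")
print("bcfd =", round(fn.bcfd(x, y), 4))

# synthetic two-group cohort -> connectivity -> graphs -> permutation report
spec = fn.CohortSpec(n_subjects=(8, 8), coupling=(0.6, 0.3), n_roi=30,
                     n_time=230, n_modules=3, seed=42)
cohort = fn.generate_cohort(spec)
report = fn.compare_cohorts(cohort, measures=("lc",), densities=(0.2, 0.3),
                            n_perm=1000, seed=1)
print(report.round(4).to_string(index=False))
```

Output:

```
lc   = 0.8745
mi   = 1.24 bits
bcfd = 1.882
measure metric  density  mean_a  mean_b  observed_diff  p_value  significant
     lc     cc      0.2  0.7247  0.7367        -0.0120   0.6553        False
     lc    cpl      0.2  1.3663  1.3743        -0.0080   0.5425        False
     lc     ge      0.2  0.2501  0.2526        -0.0025   0.5544        False
     lc     cc      0.3  0.9728  0.9491         0.0237   0.0190         True
     lc    cpl      0.3  1.0296  1.4666        -0.4370   0.0719        False
     lc     ge      0.3  0.3057  0.3694        -0.0637   0.0659        False
```

The pair is strongly linearly coupled (lc ~ 0.87), carries ~1.2 bits
of binned shared information, and its phase portrait has a
differential box dimension of ~1.88 (a sparse, spike-dominated
surface; a flat surface would give exactly 2). In the small cohort
comparison, only clustering at density 0.3 separates the
strong-coupling group A from the weak-coupling group B at p < 0.05
(`observed_diff` is mean A minus mean B); at this cohort size the
efficiency and path-length cells do not reach significance.

## Command line

The same stages are available as a CLI for shell pipelines:

```sh
fracnet simulate --out sim --seed 5                # synthetic cohort (TSV + manifest)
fracnet extract --func f.nii.gz --atlas aal.nii.gz --out ts   # NIfTI -> ROI series
fracnet connect sim/A01_timeseries.tsv --measure bcfd --out conn
fracnet graph conn/*.tsv --densities 0.1:0.5:0.1 --out met --measure bcfd
fracnet compare --metrics-a metA.tsv --metrics-b metB.tsv --out cmp --seed 1
fracnet bench-surrogate --out bench --seed 2       # complexity benchmark table
```

Every stage writes its resolved parameters to `run_config.yaml` next
to its outputs; `fracnet rerun <config> --out <dir>` replays a stage
bit-for-bit.

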