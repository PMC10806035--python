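# mbsoc

Rate-based circuit models of first- and second-order conditioning in the
insect mushroom body, with an optimal-learner grid screen and robustness
analyses.

## The scientific problem

In first-order conditioning (FOC) an odor paired with a reward acquires a
positive valence. In second-order conditioning (SOC) a *new* odor paired with
the already-trained odor — without any reward — acquires that valence too,
which requires the trained odor itself to drive the reward-signaling
dopaminergic neuron (DAN). `mbsoc` is for computational neuroscientists who
want to compare minimal mushroom-body circuit motifs that could implement
this internal DAN drive, and to quantify how robust each motif is to
parameter variation.

The common backbone is a population of 2000 Kenyon cells (KCs), of which a
sparse 10% fire at 3 Hz per odor, feeding an approach neuron MBON⁺ and an
avoidance neuron MBON⁻ through uniform initial weights (0.083):

```
R_MBON± = R_KC · w_KC>MBON±            (inner products)
R_DAN   = Ip_ext + Ip_int              (external reward + circuit pathway)
```

Learning is a two-factor, dopamine-gated depression of the KC>MBON⁻ synapses
of odor-active cells, clamped at zero:

```
w_KC>MBON⁻ ← max(0, w_KC>MBON⁻ − α·R_DAN)    for cells with R_KC > 0
```

Behavioral valence is read out as the approach bias
`B = (R_MBON⁺ − R_MBON⁻)/(R_MBON⁺ + R_MBON⁻) ∈ [−1, 1]`.

Five motifs supply `Ip_int`: fixed KC>DAN input with Hebbian KC>KC recurrence
(model 1), plastic KC>DAN synapses (model 2), excitatory-minus-inhibitory
MBON>DAN feedback (model 3), a tonically active DAN under MBON⁻ inhibition
(model 4), and a plastic excitatory MBON⁺>DAN synapse (model 5). The
conditioning schedule is 3 rewarded trials of odor 1, a test, 3 unrewarded
trials of the odor-1+odor-2 compound (a 50% subsample of each parent, so the
compound drives 200 cells like a single odor), and a second test; a novel
disjoint odor 3 monitors unwanted generalization.

On top of the simulator the package implements the screening pipeline:
exhaustive grid search over each motif's four free parameters, filtering by
the *optimal-learner* criteria (perfect and persistent odor-1 learning, no
odor-2/odor-3 bias where none is due, DAN ≤ 20 Hz and MBON ≤ 50 Hz at every
step, maximal SOC performance), selection of the *most central* optimal
learner in z-standardized parameter space, hypersphere-surface sampling of
growing radius around that center, and connectivity / initial-weight /
learning-rate perturbation experiments.

## Worked example

```
$ mbsoc simulate --model m4 --out results/m4
{
 "post_FOC/odor1": 1.0,
 "post_FOC/odor2": 0.0,
 "post_FOC/odor3": 0.0,
 "post_SOC/odor1": 1.0,
 "post_SOC/odor2": 0.33,
 "post_SOC/odor3": 0.0
}
```

Model 4 at its reference parameters learns odor 1 perfectly during FOC
(bias 1.0), keeps that association through SOC, acquires the maximal possible
second-order bias for odor 2 (0.33 — only half of odor 2's avoidance
synapses are active in the compound, so `(49.8 − 24.9)/(49.8 + 24.9) = 1/3`
is the ceiling), and never generalizes to the novel odor 3 (0.0). The same
library call from Python:

```python
from mbsoc import generate_odor_library, make_params, run_foc_soc_protocol

library = generate_odor_library(seed=999)          # three disjoint 200-KC odors
result = run_foc_soc_protocol(make_params("m4"), library)
print(result.bias("post_SOC", 2))                  # 0.3333...
```

A desk-scale screen (8 grid points per axis instead of 100) of the same
motif:

```
$ mbsoc grid --model m4 --grid-points 8 --out results/grid_m4
{
 "central_learner": {
  "alpha_kc_mbon_minus": 0.003142857142857143,
  "dan_activation": 3.5714285714285716,
  "init_mbon_minus_dan": 0.14285714285714285,
  "r_dan_baseline": 12.857142857142858
 },
 "n_members": 174,
 "optimal_fraction_percent": 4.248046875
}
```

i.e. 4.2% of the 8⁴ combinations are optimal learners, and the most central
one sits close to the motif's reference optimum (tonic DAN rate ≈ 12.9 Hz vs
11.2 Hz). `mbsoc robustness --model m4 --perturb connectivity ...` runs the
hypersphere sweep and perturbation experiments; see `--help` for flags.

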