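# vulvascape

Data-fitted Waddington-landscape modeling of vulval cell-fate patterning in
*C. elegans*.

During vulval induction, three precursor cells (P4.p, P5.p, P6.p; the
pattern is symmetric about the anchor cell) each adopt one of three fates —
primary (1°), secondary (2°) or tertiary (3°, non-vulval) — under the
control of an EGF gradient from the anchor cell and lateral Notch signaling
between neighbors.  `vulvascape` implements a catastrophe-theory model of
this decision: a **fold** bifurcation controls the existence of the
tertiary (default) attractor, a **cusp** controls the primary/secondary
pair, and the two normal forms are merged into a single two-dimensional
flow

```
x' = τ [ H(-y) f_cusp(x, a, b) − (1 − H(-y)) x ],   f_cusp = −4x³ − 2ax − b
y' = τ [ y f_fold(y − M, c) ],                       f_fold(u, c) = −u² − c
```

whose control point `(a, b, c)` is an affine function of the EGF and Notch
levels `(θ_E, θ_N)` received by each cell.  Cells are simulated as coupled
stochastic differential equations over the competence window; a cell's fate
is the basin of attraction it ends in.  The 22 free parameters (one rate
constant, ten map/landscape parameters, eleven signaling parameters) are
fitted to published fate-proportion tables for 21 experimental conditions
by ABC SMC — sequential likelihood-free inference with an adaptive
0.3-quantile threshold schedule and an optimal-local-covariance (OLCM)
Gaussian perturbation kernel.

The model's structural claim is irreversibility: once a cell has left the
tertiary basin it cannot return for any signal history, unlike symmetric
three-attractor landscapes.  The package includes the isolated-cell pulse
protocols that discriminate the two pictures.

Intended users: systems biologists and modelers studying cell-fate
decisions as dynamical landscapes, and anyone who wants a worked,
reproducible example of fitting a landscape model to phenotype tables with
likelihood-free inference.

## Worked example

```python
import vulvascape as vs

# the 21-condition reference table (fate proportions per cell)
conditions = {c.id: c for c in vs.builtin_reference_conditions()}

# bundled parameter vector from the package's own desk-scale fit
theta = vs.reference_particle()

out = vs.estimate_outcome(conditions["WT"], theta, n_reps=150, seed=0)
print(out.as_frame().round(2))
```

```
       p1   p2   p3  p_unassigned
P4.p  0.0  0.0  1.0           0.0
P5.p  0.0  1.0  0.0           0.0
P6.p  1.0  0.0  0.0           0.0
```

The wild-type pattern 3°–2°–1° emerges from the signal dynamics: P6.p is
driven across the fold by EGF and commits to the primary basin, its Notch
output pushes P5.p to the secondary side of the cusp, and P4.p never
leaves the tertiary basin.  Simulating the Notch-null condition instead
(`conditions["Notch null"]`) yields 3°–3°–1°, and ablating the anchor cell
at the earliest stage (`conditions["ablation L2 lethargus"]`) leaves all
cells tertiary.

A command-line interface mirrors the library:

```sh
vulvascape simulate --out outcomes.csv        # all 21 conditions
vulvascape fatemap --out fatemap.csv          # signal-space region grid
vulvascape predict                            # isolated-cell pulse protocols
vulvascape fit --particles 512 --generations 14 --out-dir runs/fit0
vulvascape validate --out validation.csv
```

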