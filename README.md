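# vigilnet

Directed EEG connectivity under sustained attention: multivariate
autoregressive (MVAR) modelling, partial directed coherence (PDC),
weighted directed graph-theory indices, hemispheric information flow,
and the group statistics that contrast *vigilance decrement* (coupling
that weakens with time-on-task) against *vigilance enhancement*
(coupling maintained, e.g. under audio stimulation).

The package is written for researchers who want to quantify how a
sustained-attention task reshapes the brain's directed functional
network over a one-hour session, and who need every stage — from raw
multichannel epochs to Holm-corrected group contrasts — as tested,
scriptable building blocks. Because no public recordings accompany this
protocol, a first-class synthetic session generator produces
MVAR-based surrogate EEG with *known* block-varying directed coupling,
so every downstream estimate can be validated against ground truth.

## The model

An m-channel EEG epoch is modelled as an MVAR process of order p,

```
x(t) = Σ_{r=1..p} A(r) x(t−r) + e(t),      e(t) ~ N(0, Σ)
```

with frequency-domain coefficient matrix
`Ā(f) = I − Σ_r A(r) e^{−i2πfr/fs}`. The partial directed coherence
from channel j to channel i,

```
PDC_ij(f) = |Ā_ij(f)| / sqrt( ā_j(f)^H ā_j(f) ),
```

is column-normalized (Σ_i PDC_ij(f)² = 1) and lies in [0, 1]. Averaging
|PDC| over the 0.5–30 Hz band, one weighted directed network
(entry (i, j) = flow j→i) is obtained per 1200 ms epoch and averaged
within each 20-min time-on-task block.

Each block's network is thresholded — at absolute values
{0, 0.1, 0.15, 0.2, 0.25, 0.3} or proportionally at sparsities 10–30 %
(step 5 %) — and summarized by nodal in/out/total degree `d_i`, nodal
strength `NS_i = Σ_j w_ij + Σ_j w_ji`, Fagiolo's weighted directed
clustering coefficient

```
C_i = [(W^{1/3} + (Wᵀ)^{1/3})³]_ii / (2 [d_i^tot (d_i^tot − 1) − 2 d_i^↔]),
```

the characteristic path length PL (mean directed shortest-path cost
with edge length 1/w, finite pairs only), and trapezoidal integrals of
CC and PL over the sparsity range. Hemispheric information flow splits
the lateralized electrodes into four sub-networks (LH→LH, LH→RH,
RH→RH, RH→LH); the laterality index is (LH − RH)/(LH + RH). Group
comparisons use paired t-tests within a cohort across time-on-task
levels, Welch t-tests between cohorts, Bonferroni–Holm correction, and
electrode t-maps with an |t| ≥ 2.5 significance criterion. The
brain–behavior stage correlates one-vs-all Δdegree contrasts with ΔRT.

## Worked example

```python
from vigilnet.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig.desk_scale(seed=0))
print(report["summary"].groupby(["group", "block"])[
    ["norm_degree", "cc_integral", "pl_integral"]].mean().round(4))
```

```
                   norm_degree  cc_integral  pl_integral
group       block
enhancement 1           0.2770       0.0194       2.1100
            2           0.2745       0.0190       2.2476
            3           0.2764       0.0194       2.2791
vigilance   1           0.2803       0.0196       2.2123
            2           0.2433       0.0121       2.6947
            3           0.1957       0.0060       3.1734
```

Twelve vigilance subjects (ground-truth coupling scaled 1.0 / 0.7 / 0.4
across blocks) versus twelve enhancement subjects (1.0 / 1.0 / 0.95) at
the 16-channel desk scale: in the vigilance cohort the mean normalized
degree falls 30 % and the clustering-coefficient integral 69 % from
block 1 to block 3 while the path-length integral rises 43 % — the
network disintegrates with time-on-task. The enhancement cohort's
indices stay flat (degree −0.2 %). `report["contrasts"]` shows every
within-vigilance level contrast and every V2/V3-versus-E2/E3 group
contrast Holm-significant, and no significant decline within the
enhancement cohort.

The numbered drivers under `analysis/` walk the same study end to end
(simulation → pipeline → graph trends → hemispheric flow → group
statistics → brain–behavior correlation) and write their tables to
`results/`.

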