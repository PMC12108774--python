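# retrogate

Retrospectively gated, cardiac phase-resolved T2\* mapping for small-animal
MRI — simulation, k-space binning reconstruction, mono-exponential fitting,
and method-agreement statistics.

## The problem

Myocardial T2\* (the effective transverse relaxation time governing
gradient-echo signal decay) is sensitive to oxygenation, blood volume and
iron, and it fluctuates over the cardiac cycle. Prospective ECG triggering
breaks down at ultrahigh field and at mouse heart rates (R-R intervals of
80–160 ms), so a practical alternative is *retrospective gating*: acquire
multi-gradient-echo (MGE) k-space continuously, record a pulse-oximetry
trigger trace and the scanner's TTL measurement markers alongside, and sort
the k-space lines into cardiac phases after the fact. Each phase bin is
complex-averaged and Fourier-reconstructed into a 7-echo image series, and a
T2\* map is fitted per phase from the mono-exponential decay

    S(TE) = S0 · exp(−TE / T2*).

This package implements that entire chain, together with a digital-phantom
simulator that emulates the validation experiment used to establish the
method: a six-vial phantom spanning T2\* = 4–20 ms, scanned with TR 14 ms,
7 echoes (TE = 1.5–11.1 ms in 1.6 ms steps), a 128×128 matrix and 300
continuous measurements under simulated mouse heartbeats, reconstructed both
conventionally (reference) and by retrospective binning into 10 cardiac
phases.

It is intended for preclinical MRI researchers who want to prototype or
validate retrospective-gating reconstructions without scanner time, and as a
reference implementation of the gating → binning → fitting → agreement
pipeline for user-supplied k-space data (HDF5 container + physio CSVs).

## What's inside

| module | role |
|---|---|
| `retrogate.physio` | trigger detection, R-R outlier filtering (>5% from the 10-beat moving median), phase assignment, systole phase-shift |
| `retrogate.phantom` | digital phantoms, heartbeat/pulse-ox/TTL simulation, MGE k-space synthesis |
| `retrogate.recon` | zero/first-order phase correction, per-phase complex averaging, centered orthonormal FFT reconstruction, ungated reference |
| `retrogate.fitting` | pixelwise bounded mono-exponential fits, maps, ROI phase profiles |
| `retrogate.metrics` | NEMA single-image SNR, regression/R², ICC(2,1), Bland–Altman, Friedman/Wilcoxon–Holm/Mann-Whitney/Spearman |
| `retrogate.cli` | `simulate`, `recon`, `fit`, `validate`, `phase-profile` subcommands over YAML configs |

## Worked example

Run the full phantom validation (simulate → gate → reconstruct both ways →
fit → agreement) from the library:

```python
from retrogate.config import RunConfig
from retrogate.pipeline import run_validation

result = run_validation(RunConfig(seed=7))
print(result.per_vial)
print(f"R^2 = {result.agreement.r2:.6f}, ICC = {result.agreement.icc:.6f}")
```

which prints

```
   vial  t2star_true  t2star_reference  t2star_binned
0     0          4.0               4.0            4.0
1     1          6.0               6.0            6.0
2     2          9.0               9.0            9.0
3     3         12.0              12.0           12.0
4     4         16.0              16.0           16.0
5     5         20.0              20.0           20.0
R^2 = 1.000000, ICC = 1.000000
```

Each row is one vial: the ground-truth T2\* (ms), the mean fitted T2\* over
the vial ROI from the conventional reference reconstruction, and the
cycle-averaged mean from the 10-phase retrospectively binned reconstruction.
For a noiseless static phantom the binned images are identical to the
reference, so regression R² and the intraclass correlation coefficient both
equal 1 — the binning chain introduces no bias of its own.

The same recipe is available from the shell:

```bash
retrogate validate --seed 7 --out runs/validation
# R^2 = 1.000000  ICC = 1.000000  bias = 6.291e-15 ms  LoA = [-6.267e-15, 1.885e-14] ms
```

which also writes per-vial CSVs, per-phase T2\*/S0/gof NIfTI maps, the
agreement JSON, and the resolved config for reproducibility. A dynamic
experiment (T2\* modulated ±20% over the cycle) runs via
`retrogate phase-profile` with `modulation: {kind: sinusoid, amplitude: 0.2}`
in the config.

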