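# t2relax

Quantitative T2 mapping from multi-echo spin-echo magnitude data, with an
emphasis on what happens at low signal-to-noise ratio (SNR). The package
provides:

- a **simulator** for mono-exponential T2 decays corrupted by Rician magnitude
  noise, with calibrated priors over tissue and acquisition parameters;
- three **least-squares estimators** — the traditional bounded fit (LSE), an
  offset fit (OLSE), and a Rician-noise-corrected fit (NCLSE);
- a **neural-network estimator** (a ~1M-parameter fully connected network,
  implemented in NumPy) trained *only* on synthetic data;
- an **evaluation harness** (relative-error summaries, Mood's median test) and
  an **image pipeline** (voxel-wise map fitting, NIfTI I/O, a synthetic
  cartilage-like phantom).

## Why

Magnitude MR data are Rice-distributed, so at low SNR the measured signal sits
systematically *above* the true decay. A plain exponential fit then
overestimates T2; adding a constant offset to soak up the noise floor
overshoots and underestimates it. Fitting the *expected Rician magnitude* of
the decay removes the bias but needs the noise level σ, and a network trained
on realistically corrupted synthetic decays learns the correction without
being told σ. This package implements and quantifies all four approaches on a
common synthetic benchmark. See [docs/methods.md](docs/methods.md) for the
model, priors, and design decisions.

## Worked example

One noisy decay at SNR 5 (true S0 = 400, T2 = 45 ms, σ = 80, 7 echoes at
10–70 ms):

```python
import numpy as np
from t2relax import (DecayParams, EchoTrain, add_rician_noise,
                     fit_lse, fit_nclse, fit_olse, mono_exp_signal)

te = np.arange(10.0, 80.0, 10.0)            # 7 echoes, 10..70 ms
truth = DecayParams(s0=400.0, t2=45.0)
clean = mono_exp_signal(truth, te)
sigma = 80.0                                 # SNR = S0/sigma = 5
noisy = add_rician_noise(clean, sigma, rng=np.random.default_rng(0))
train = EchoTrain(te, noisy)

for name, r in [("LSE", fit_lse(train)),
                ("OLSE", fit_olse(train)),
                ("NCLSE", fit_nclse(train, sigma))]:
    print(f"{name:>5}: S0 = {r.s0_hat:7.1f}   T2 = {r.t2_hat:6.2f} ms")
```

Output:

```
  LSE: S0 =   353.5   T2 =  80.17 ms
 OLSE: S0 =   313.6   T2 =  16.91 ms
NCLSE: S0 =   365.0   T2 =  61.52 ms
```

One draw, but it shows the systematic pattern: the plain fit lands far above
the true 45 ms, the offset fit collapses below it, and the noise-corrected fit
is closest.

## Benchmark numbers

`scripts/acceptance.py` regenerates the headline quantities from scratch
(fixed-SNR test sets of 10,000 samples each, drawn from the calibrated
priors):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

With seed 1 this prints (median errors of the T2 estimate, in %; ~3 minutes
on one CPU):

| quantity | value |
|---|---|
| t1 — LSE median ARQE, SNR 5 | 42.2 |
| t2 — OLSE median ARQE, SNR 5 | 61.2 |
| t3 — NCLSE median ARQE, SNR 5 (true σ) | 34.8 |
| t4 — LSE median ARQE, SNR 10 | 18.9 |
| t5 — LSE median ARQE, SNR 30 | 5.6 |
| t6 — LSE median signed RQE, SNR 5 | +29.8 |
| t7 — OLSE median signed RQE, SNR 5 | −34.1 |
| t8 — OLSE median signed RQE, SNR 30 | −7.8 |
| t11 — prior mass P(T2 < 500 ms), % | 99.86 |
| t12 — prior mass P(S0 ≤ 2500), % | 98.92 |

ARQE is the absolute relative T2 error, RQE its signed counterpart
(`|T2̂ − T2|/T2` and `(T2̂ − T2)/T2`, in percent). The signed values show the
bias directions discussed above: LSE up, OLSE down, shrinking with SNR.

The network, trained at the package's standard budget (400k synthetic
samples, 8 epochs, seeded — exactly the configuration used by the test
suite), reaches a median ARQE of 28.2% at SNR 5 (median signed RQE −1.9%) —
better than any of the least-squares fits, and without being given σ — and
9.4% at SNR 30, where the simpler LSE is already accurate. These bands are
asserted (with Monte-Carlo tolerances) in `tests/test_acceptance.py`; larger
training budgets narrow the high-SNR gap further.

## Image-domain usage

```python
from t2relax import make_phantom, fit_map, compare_to_reference

truth, observed = make_phantom((64, 64), sigma=25.0, rng=0)   # SNR 20
fitted = fit_map(observed, method="nclse", sigma=25.0)
table = compare_to_reference(fitted, truth)
print(table.to_markdown())
```

which prints the median ARQE (%) with its [2.5, 97.5] percentile range over
the masked voxels:

```
| method | SNR = 0 |
|---|---|
| nclse | 8 [0, 28] |
```

(the column is labelled 0 because no nominal SNR was attached to the
comparison). Real acquisitions enter through NIfTI: `read_stack(stack.nii.gz, tes.json,
mask.nii.gz)` and `write_quantmap(fitted, outdir)`. The same operations are
available on the command line:

```bash
t2relax simulate --counts 1000,100,100 --seed 0 --out data
t2relax train --data data --epochs 4 --seed 0 --out model.npz
t2relax fit-signals --data data --model model.npz --out preds.csv
t2relax fit-map --stack stack.nii.gz --tes tes.json --mask mask.nii.gz \
    --method nclse --sigma 12 --out outdir/
```

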