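# gsam — generalized sparse additive models

`gsam` fits additive models

&nbsp;&nbsp;&nbsp;&nbsp;g(E[y | x]) = β + Σⱼ fⱼ(xⱼ)

in moderate-to-high dimension, where most fitted component functions are
*exactly zero* and the remaining ones are flexibly shaped by a structural
penalty of your choice.  It solves

&nbsp;&nbsp;&nbsp;&nbsp;min&nbsp; −Pₙℓ(β + Σⱼ fⱼ) + λ² Σⱼ Pst(fⱼ) + λ Σⱼ ‖fⱼ‖ₙ

with an exponential-family loss ℓ (gaussian, binomial, poisson), a
structural semi-norm Pst per component — discrete total variation of the
k-th derivative (trend filtering, k = 0, 1, 2), a smoothing-spline-type
Sobolev semi-norm, a linear-subspace indicator (basis-expansion models,
including the plain lasso), or a monotonicity constraint — and the
empirical-norm sparsity penalty ‖fⱼ‖ₙ = √(n⁻¹ Σᵢ fⱼ(xᵢⱼ)²) that zeroes
whole components, group-lasso style.  Structure and sparsity weights are
coupled as (λ², λ), so there is a single tuning parameter.

The optimizer is accelerated proximal gradient descent whose inner step
is a fast univariate penalized smoother followed by a multiplicative
soft-scaling; squared loss additionally gets a block coordinate descent
path fitter.  Intended users: statisticians and computational biologists
who want interpretable, sparse, shape-constrained regression on tabular
data (dozens to hundreds of features) without committing to a basis
expansion up front.

## Worked example

Fit a mixed-signal synthetic problem — one step function, one linear,
one sine, one cubic component plus 16 pure-noise features — and ask
which features the model keeps:

```python
import numpy as np
from gsam import (PenaltySpec, ScenarioSpec, gen_design, gen_response,
                  lambda_max, make_path, fit_path, predict)

X = gen_design(n=400, p=20, seed=1)                 # U(-2.5, 2.5) design
y, f0 = gen_response(X, ScenarioSpec(4, 400, 20, seed=2))

path = make_path(lambda_max(y), n_lambda=50)        # lambda_max = ||y - ybar||_n
models = fit_path(X, y, path, PenaltySpec("tv", k=1))

Xt = gen_design(200, 20, seed=3)                    # independent test set
yt, _ = gen_response(Xt, ScenarioSpec(4, 200, 20, seed=4))
test_err = [np.mean((yt - predict(m, Xt)["link"])**2) for m in models]
best = models[int(np.argmin(test_err))]

print("lambda* =", round(best.lam, 4))
print("active features:", best.active_set)
print("in-sample MSE vs truth:",
      round(float(np.mean((predict(best, X)["link"] - f0)**2)), 4))
```

Output:

```
lambda* = 0.0708
active features: [0, 1, 2, 3, 4, 7, 8, 9, 11, 13, 14, 17, 18]
in-sample MSE vs truth: 0.1589
```

All four signal features (0–3) are recovered; the truth is explained to
within 4% of its variance (the null model's MSE is 4.0).  The handful of
noise features that slip in at the prediction-optimal λ carry component
norms 20–200× smaller than the signals — prediction-optimal tuning
over-selects, exactly as for the lasso.  For support-faithful selection
use cross-validation with the one-standard-error rule
(`gsam.kfold_cv`), which keeps the four signals and drops the rest.

The same workflow is available from the shell:

```sh
gsam simulate --scenario 4 --n 400 --p 20 --reps 2 --seed 7 --out results.csv
gsam cv  --data train.csv --response y --penalty tv1 --out model.json
gsam predict --model model.json --data new.csv --out predictions.csv
```

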