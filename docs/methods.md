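# Methods

## The model

The package studies a linear three-compartment ODE for language
acquisition.  A learner's knowledge of a language is divided into
proportions `u` (unknown), `f` (familiar) and `m` (mastered), with
`u + f + m = 1`.  Knowledge is acquired along the chain
unknown → familiar → mastered at a learning rate `α` and decays backwards
(familiar → unknown, mastered → familiar) at rates `β/(1+2α)` and
`β/(2+4α)` respectively:

```
du/dx = β f/(1+2α) − α u
df/dx = −α f − β f/(1+2α) + α u + β m/(2+4α)
dm/dx = α f − β m/(2+4α)
```

Both constants live in the open interval (0, 1); boundary values are
rejected because `β = 0` or `α = 0` degenerates the chain (and the
backward rates vanish).  `x` is a dimensionless, time-like independent
variable; the default experiments run on `x ∈ [0, 1]` from the initial
state `(u, f, m)(0) = (1, 0, 0)` — everything starts unknown.

The system is `dy/dx = A y` with a constant rate matrix `A` whose columns
sum to zero (mass conservation) and whose off-diagonal entries are
nonnegative (Metzler structure, so the simplex is forward-invariant).
This structure buys three exact diagnostics used throughout the tests:

* the matrix exponential `y(x) = expm(A x) y(0)` (SciPy's `expm`, Padé
  with scaling and squaring) is an oracle accurate to better than 1e-12
  per component on the unit interval;
* the equilibrium is the null-space direction of `A`, available in closed
  form from detailed balance of the chain
  (`u* = (β/(α(1+2α))) f*`, `m* = (α(2+4α)/β) f*`, normalized to sum 1);
* `u + f + m` must remain 1 along every trajectory, to 1e-12 (analytic)
  and 1e-10 (multistep solver).

One floating-point caveat: with the natural coefficient expressions the
`u` and `m` columns of `A` cancel exactly in IEEE double, but the `f`
column holds three independent terms and its sum can carry one rounding
error (≤ 2.3e-16).  Tests assert exact zeros where exactness is
representable and one ulp where it is not.

The three standard parameter cases are `α = 0.5` with
`β = 0.1, 0.5, 0.9` (cases 1–3).

## Reference solver

Training data come from a 4th-order Adams–Bashforth–Moulton
predictor–corrector (PECE: one AM4 correction per step), started with
three classical Runge–Kutta steps, on the uniform grid with step
`h = 0.01` (101 points on [0, 1]).  The method choice is deliberate: at
h = 0.01 its global error against the matrix-exponential oracle is
~1.3e-10, two orders below the contract of 1e-8 and far below the trained
network's error scale, so the surrogate is effectively trained on the
exact solution.  Order-4 convergence is verified empirically (halving h
shrinks the error ≈16×).  Grids with fewer than five points cannot seed
the multistep history and fall back to pure Runge–Kutta; this is
documented behaviour, not an error.  No adaptive stepping or stiff
machinery: at these parameters the spectrum of `A` is mild
(one zero eigenvalue, two modest negative ones).

## Dataset, split, normalization

Each grid point is one supervised sample `x → (u, f, m)`.  Samples are
assigned uniformly at random (seeded generator, recorded seed) to
training/validation/test subsets in the ratio 75 / 13 / 12 %.  Non-integer
counts are resolved by largest-remainder apportionment, the integer
partition closest to the stated ratios: the default 101-point grid splits
76 / 13 / 12.  Inputs and each target channel are affinely mapped to
[−1, 1] (min–max over the full dataset) for training only; the map's
round-trip error is below 1e-14.  All reported MSE and absolute-error
values are on the original scale of the proportions (order 1), so they are
comparable across channels and runs; the gradient norm and its stopping
threshold refer to the normalized objective actually minimized.

## Network and trainer

The surrogate is a single-hidden-layer perceptron, 1 input → 12
log-sigmoid hidden units → 3 linear outputs (63 parameters).  The hidden
count follows the study design; fewer units underfit and more add
complexity without accuracy on these smooth targets.  Weights are
initialized Nguyen–Widrow style per seed: hidden weight vectors scaled to
norm `0.7·12`, biases spreading the sigmoid centres across the input
range, small uniform output weights.  The log-sigmoid branches on the
argument's sign so `exp` never overflows; at |z| ≥ ~37 its value rounds
to the nearest representable of 0 or 1, which is the correctly rounded
result.  The loss is the MSE averaged over samples × channels, with exact
backpropagation gradients (validated against central finite differences
at relative error ≤ 1e-6 on 100 random draws; coordinates whose
finite-difference magnitude falls below 1e-3 are compared with that floor
in the denominator, since the difference quotient itself is only accurate
to ~1e-10 absolute).

Training is Møller's scaled conjugate gradient, full batch.  Curvature
along the search direction `p` is a one-sided gradient difference at
displacement `σ/|p|` (σ = 5e-5; 7e-5 is a documented alternative),
regularized by a scale parameter λ (initial 5e-7) raised whenever the
local quadratic model is untrustworthy (comparison ratio Δ < 0.25 → λ×4,
capped at 1e15) and lowered when it is good (Δ ≥ 0.75 → λ×0.5); steps are
accepted only when the loss does not increase, and the direction restarts
to steepest descent every 63 accepted steps.  Møller's original
proportional λ increase was benchmarked against this multiplicative
schedule and performed identically on these problems.  Stopping rules,
checked per epoch: 1000 epochs maximum, loss goal 0, gradient norm below
1e-7, or six consecutive epochs without a new best validation MSE; the
weights returned are always from the best-validation epoch.  Multi-restart
training (default 20 seeded restarts) returns the restart with the lowest
best-validation MSE; every stage is deterministic given its seed, so the
end-to-end pipeline is reproducible byte for byte.

## Evaluation surfaces

* Per-split MSE at the returned weights, original units.
* Absolute-error (AE) curves `|surrogate − reference|` per compartment on
  the full 101-point grid against the Adams reference (not just the test
  subset), plus their max and mean.
* A 20-bin equal-width histogram of signed errors (target − output
  convention) pooled over all samples and channels, reporting the centre
  of the bin nearest zero.
* Ordinary least-squares regression of outputs on targets per compartment
  and pooled: slope, intercept, Pearson R and R².  Zero target variance
  yields NaN (undefined correlation) rather than an exception.
* As an internal ordering check, the analytic solution evaluated against
  the Adams reference gives max AE ≤ 1e-8, strictly below any trained
  network's error — the solver is never the accuracy bottleneck.

## What the experiments show, and a known limitation

With the default conditions (101-point Adams dataset, 75/13/12 split,
20 restarts, the stopping rules above) the trained surrogate reaches
best-validation MSE of order 1e-7 to 1e-8, maximum absolute errors of
order 1e-3 to 1e-4 per compartment, and pooled R² ≈ 0.9999994, which
rounds to 1.000 at three decimals.  Runs typically end by validation
early-stopping near epoch 60–100.

Validation MSEs of order 1e-13 to 1e-11 for this architecture are
attainable on this dataset, but in our experiments only by
Gauss–Newton/Levenberg–Marquardt-class optimizers (a damped least-squares
fit of the same network reaches ~1e-14 in tens of iterations); under the
scaled-conjugate-gradient trainer with the stated epoch budget and
early-stopping rules, first-order/CG-class methods (this implementation,
nonlinear CG, L-BFGS) all plateau four to five orders higher.  The
acceptance suite therefore reports the deep-MSE and AE-band reproduction
checks honestly as failing while the structural, solver, conservation,
regression and determinism checks pass.

These are function-approximation experiments on noiseless, smooth
reference data; passing them shows the solver, trainer and metrics are
correct and reproducible, not that the surrogate generalizes beyond
[0, 1], to other initial states, or to data with observation noise.

## Numerical choices and degenerate inputs

* Parameters at the interval boundary (α or β ∈ {0, 1}) are rejected.
* Split ratios must be positive and sum to 1 within 1e-9; constant
  normalization channels raise an error naming the channel.
* Apportionment ties hand leftover samples to the largest fractional
  remainders, train first, for determinism.
* Histogram of identical errors widens the range by ±0.5 to keep bins
  well-defined.
* The trainer aborts with a diagnostic stop reason on a non-finite loss;
  multi-restart simply moves to the next seed.
* All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; there is no hidden global RNG state.
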