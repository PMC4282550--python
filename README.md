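# augbin — augmented binary inference for composite tumour-response endpoints

Phase II cancer trials usually report tumour response as a binary composite:
a patient is a *success* if the sum of target-lesion diameters shrinks past a
threshold (e.g. >30% for an ORR-like endpoint) **and** no non-shrinkage
failure occurs (new lesions, non-target lesion growth, serious toxicity,
death).  The conventional analysis dichotomises the continuous shrinkage and
reports a proportion, discarding most of the information in the measured
tumour sizes.

`augbin` implements the **augmented binary** method: it models the continuous
log tumour-size ratios jointly with the binary failure process and recovers
the *same* composite success probability with a markedly narrower confidence
interval, and with higher power for two-arm comparisons.  The package is
aimed at trial statisticians evaluating or applying composite
binary–continuous endpoints, and at methodologists studying their operating
characteristics.

## The model

For patient *i* with baseline size *z*₀ᵢ (cm), let *y*ₖᵢ = log(*z*ₖᵢ/*z*₀ᵢ)
be the log size ratio at the interim (*k*=1) and final (*k*=2) visits, and
*D*₁ᵢ, *D*₂ᵢ indicate non-shrinkage failure in the two intervals.

* Shrinkage: (*y*₁, *y*₂) ~ BVN(μ₁ᵢ, μ₂ᵢ; Σ) with μ₁ᵢ = α + γ*z*₀ᵢ,
  μ₂ᵢ = β + γ*z*₀ᵢ (treatment terms added in two-arm trials) and
  unstructured Σ, fitted by direct maximum likelihood under MAR — a patient
  with only an interim ratio contributes the univariate marginal.
* Failure: logistic models for P(*D*₁=1) on baseline size and for
  P(*D*₂=1 | *D*₁=0) on the interim size.
* Success probability for a patient with baseline *z*₀, threshold ratio *c*:

      p(z0) = (1 − π₁(z0)) ∫ φ(y1; μ1, Σ11) (1 − π₂(z0·e^{y1}))
                             Φ((log c − μ_{2|1}(y1)) / σ_{2|1}) dy1

  evaluated by quadrature (the final-ratio dimension closes analytically via
  the conditional normal CDF).  The trial estimate averages p(*z*₀ᵢ) over the
  observed baseline sizes; its CI comes from the delta method on the logit
  scale, using the block-diagonal covariance of the three model fits.  The
  two-arm analysis tests the baseline-adjusted mean difference
  m(θ) = mean[p(z0, t=1) − p(z0, t=0)] with a Wald test.

Comparators included: complete-case proportion with Wilson score interval,
logistic regression of the success label on baseline size and treatment, and
the Karrison-style worst-value Wilcoxon rank-sum test on final log ratios.

## Worked example

```python
import augbin

scenario = augbin.Scenario(n_per_arm=75, delta1=-0.356)   # baseline design
trial = augbin.simulate_trial(scenario, rng=42)

aug = augbin.AugmentedBinarySuccess(final_threshold=0.7).fit(trial)
binary = augbin.BinarySuccess(final_threshold=0.7).fit(trial)
print(f"augmented binary: {aug.p_hat_:.3f}  CI ({aug.ci_[0]:.3f}, {aug.ci_[1]:.3f})")
print(f"binary (Wilson):  {binary.p_hat_:.3f}  CI ({binary.ci_[0]:.3f}, {binary.ci_[1]:.3f})")
print(f"true value:       {augbin.true_success_prob(scenario):.3f}")
```

prints

```
augmented binary: 0.376  CI (0.288, 0.473)
binary (Wilson):  0.347  CI (0.249, 0.459)
true value:       0.334
```

Both estimators target the same composite success probability (truth 0.334
for this generating model); the augmented binary interval is ~12% narrower
on this dataset because it uses the undiscretised final ratios.  The same
estimators run from the shell:

```bash
augbin simulate --scenario scenario.yaml --out trial.csv --seed 1
augbin estimate --input trial.csv --threshold 0.7
augbin compare  --input trial.csv --method karrison
augbin oc --scenario scenario.yaml --methods augbin,binary --reps 1000 --seed 1
```

All estimators follow scikit-learn conventions (`fit`, trailing-underscore
attributes, `get_params`), and thin functional wrappers
(`estimate_with_ci`, `compare_arms`, `binary_method`, ...) are available.

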