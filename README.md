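# isopop

Confidence-level isoboles for two-drug combination-therapy dose finding
under inter-individual variability (IIV) and parameter uncertainty.

## The problem

Population PK/PD models predict, for a dose pair (AMT₁, AMT₂), the success
rate *y* = *f*(AMT₁, AMT₂) — the fraction of subjects meeting a clinical
endpoint (e.g. parasitemia below the limit of quantification at day 28).
Dose selection asks for the *effective isobole*: the curve of minimum dose
combinations reaching a prespecified efficacy target ŷ (say a 95% success
rate). Because the population parameters are estimates, an ensemble of
population realizations drawn from the parameter-uncertainty distribution
yields a distribution of effective isoboles; the fraction of realizations
meeting ŷ at a dose pair is that pair's *confidence level*, and contours
of the confidence-level response surface — e.g. the doses with a 95%
chance of reaching a 95% success rate — are the quantity of clinical
interest.

Brute-force scanning needs one population simulation per lattice node per
realization (129² ≈ 17 000 at a useful resolution). `isopop` instead:

1. traces each realization's isobole by **adaptive dyadic grid
   refinement** — a 2D generalization of bisection that doubles the grid
   each iteration but simulates only within one grid spacing of the
   current isobole estimate (discrete Fréchet distance between successive
   estimates as the convergence metric), typically cutting simulations
   ~10-fold at 65×65 resolution;
2. **aggregates** the isobole ensemble by closing each curve into its
   failure polygon through the origin, classifying a fine grid against it
   (success = target achieved or exceeded), and averaging the binary
   fields into the confidence surface.

The package ships a hierarchical two-level Monte-Carlo population
simulator (log-normal IIV nested in a multivariate-normal uncertainty
distribution on the log scale), a malaria-like two-compartment PK /
exponential-growth PD combination testbed with a modified Bliss
interaction, analytic fixture surfaces with closed-form isoboles, a
monotonicity pre-checker, and a parameter-influence ranking.

## Worked example

```python
from isopop.cli import default_malaria_config, run_pipeline
from isopop.aggregate import confidence_isobole

cfg = default_malaria_config(n_pop=20, n_subj=200, max_iter=5, seed=1)
isos, surface, manifest = run_pipeline(cfg, "runs/demo")
print(manifest["total_evaluations"], manifest["savings_ratio"])

for level in (0.5, 0.95):
    ci = confidence_isobole(surface, level)
    print(level, ci.points[0].round(1), ci.points[-1].round(1))
```

prints

```
4491 4.849699398797595
0.5 [191.7 800. ] [643.8   0. ]
0.95 [312.5 800. ] [800.   12.5]
```

Reading: 20 population realizations (200 subjects each) were traced at
search depth j = 5 (33×33 lattice) using 4 491 success-rate simulations —
4.8× fewer than the 21 780 a full-grid scan would need. The 50%-confidence
isobole runs from (192 mg drug 1, 800 mg drug 2) down to a 644 mg
mono-dose of drug 1; the 95%-confidence isobole lies further out — at the
hypothetical 800 mg dose caps, roughly 312 mg of drug 1 is needed even
with maximal drug 2, telling you which dose pairs reach the 95% success
target with 95% confidence under the stated uncertainty.

The same run from the shell:

```bash
isopop pipeline --config run.yaml --out runs/demo --seed 1
isopop check-monotonicity --config run.yaml
isopop influence --config run.yaml --out runs/influence
```

Outputs are plain CSV with provenance headers (per-population isobole
polylines, per-iteration evaluation logs, the confidence surface in long
format, confidence-level isoboles) plus a JSON manifest with evaluation
totals and the achieved savings ratio; identical seeds reproduce every
file byte-for-byte.

See `docs/methods.md` for the model, algorithms, defaults and their
rationale.

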