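# clskinetics

Equilibrium kinetic modelling and inference for gene regulation governed by
a **concentration-limited step (CLS)** — the steady-state analogue of a
rate-limiting step in a chain of complex-building reactions
`Y_{i-1} + X_i <-> Y_i`.

When one accelerator is limited with respect to its binding affinity and
every accelerator downstream of it is in excess, the dose-response of gene
activity is an exact **linear-fractional** (first-order Hill) function of
the inducer. Factors act either as *accelerators* (enzymatic-activator-like)
or as one of six *decelerator* types (competitive/uncompetitive/
noncompetitive x linear/partial), and a steroid receptor entering as
`G*S/(K+S)` turns an induction chain into a repression dose-response

```
A(S) = (A_max + A_min*S/IC50) / (1 + S/IC50)
```

whose parameters — A_max, A_min, IC50 and the combination
A_max·IC50/A_min — are themselves linear-fractional in any competing
cofactor's amount. The shapes of those four parameter plots identify the
mechanism and position of the cofactor and of the receptor relative to the
CLS.

## What is in the package

| module | role |
| --- | --- |
| `kinetic_core` | forward model: closed-form dose-response by linear-fractional composition, brute-force numeric equilibrium oracle (no CLS approximation), CLS regime checks, Hill fits, irreversible "hit-and-run" equivalence, oligomeric accelerators |
| `config_formulas` | symbolic derivation (sympy) of `A = T(S)/U(S)` for all 18 admissible receptor+cofactor configurations on a canonical 5-step scaffold; the four parameter-plot forms and their compatibility conditions; qualitative shape classification |
| `dose_response_fit` | two-stage per-cell dose-response fitting, Western-blot linearization, normalized parameter-plot construction, weighted linear-fractional plot fits, qualitative signature extraction |
| `classification` | 22-entry qualitative rule table (shipped as `data/plot_rules.yaml`), analytic + stochastic feasibility scans of sign patterns per configuration, receptor localization by feasibility intersection |
| `bayes_compare` | Metropolis-Hastings fitting (numba-compiled) of the predicted / permuted / unconstrained parameter-plot models, chi-squared, BIC ranking, posterior half-max ordering probabilities |
| `synthetic_data` | ground-truth competition-assay, parameter-plot and Western generators for every configuration |
| `cli` | `clskin` command: simulate / fit / classify / compare / report, or `all` |

## Command-line pipeline

```bash
# simulate a coactivator-like competition assay (4x4 grid, 4 steroid
# doses, triplicates), analyze it, and localize the receptor:
clskin all --seed 3 --outdir run

cat run/report.txt
#   surviving configurations:
#     - factor: accelerator after CLS; GR: accelerator after CLS, after the factor
#   model comparison (BIC):
#     predicted: ...   (lowest)
```

Individual stages (`clskin simulate|fit|classify|compare|report`) read and
write CSV/JSON under the run directory; every run records its resolved
configuration and is byte-reproducible for a fixed seed.

## Notes on scope

Steady states only (the single ODE integration verifies the irreversible
hit-and-run equivalence); no stochastic transcription-bursting models; at
most two simultaneously varied cofactors. Units are arbitrary but
consistent — dose axes are ng-equivalents with an explicit conversion knob
in the generators.
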