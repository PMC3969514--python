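# focelin

**Fast screening of stochastic model components in population PK models
by FOCE-I linearization.**

Developing the random-effects side of a nonlinear mixed-effects (NLME)
pharmacokinetic model — between-subject variability (BSV), between-occasion
variability (BOV), residual-error (RV) structure, covariance blocks — is
laborious because every candidate structure traditionally requires a full
nonlinear re-estimation, and diagnostics based on empirical Bayes
estimates (EBEs) are distorted by shrinkage when individual data are
sparse. `focelin` implements a likelihood-based alternative: fit the base
model once with the first-order conditional estimation method with
interaction (FOCE-I), extract each observation's prediction and partial
derivatives at the expansion point `Q0 = (eps = 0, eta = eta_hat)`, and
estimate extended random-effects structures on the resulting **linearized
model**

    y_ij ≈ f|Q0 + Σ_l ∂f/∂η_l|Q0 (η*_l − η̂_l)
         + Σ_v [ ∂h/∂ε_v|Q0 + Σ_l ∂²h/∂η_l∂ε_v|Q0 (η*_l − η̂_l) ] ε*_v ,

which involves **no structural-model evaluations at all** (an instrumented
call counter proves it). An extension is declared a significant
improvement when ΔOFV = OFV_base − OFV_extended exceeds the chi-square
critical value (α = 0.05, df = number of added parameters), and the
package's validation studies show the linearized call agrees with the
full nonlinear refit's call on essentially every screened extension. The
known failure mode of the approach — inner local minima created by the
ε–η interaction under proportional/combined error — is reproduced,
detected (per-subject iOFV deviation report) and repaired (MCETA
multi-start over random initial η vectors) within the package.

Audience: pharmacometricians and statisticians who want a transparent,
pure-Python reference implementation of linearization-based stochastic
model building — for method study, teaching, or simulation work — with a
self-contained synthetic-data module so nothing external is required.

## Worked example

`examples/03_screen_extensions.py` simulates the oral/additive preset
(74 subjects, 1,022 observations), fits the base model, and screens four
extensions both ways:

```
             extension  df  dofv_nonlinear  dofv_linearized  significant_nonlinear  significant_linearized  agreement
              rv_power   1           1.289            1.291                  False                   False       True
          rv_time_step   1           5.816            5.758                   True                    True       True
           add_bsv(KA)   1           0.114            0.136                  False                   False       True
covariance_block(CL,V)   1           0.351            0.352                  False                   False       True

agreement: 100% of 4 extensions
structural-model calls while fitting extensions on the linearized model: 0
```

The data were simulated under the base model, so most ΔOFV sit far below
the 3.84 critical value; in this realization one entry (`rv_time_step`)
crosses it by chance — and both arms agree on it, which is precisely what
the method promises: the linearized ΔOFV mirrors the nonlinear one at a
fraction of the cost and with zero structural-model calls. The script is
seeded, so rerunning it reproduces the table exactly.

Other examples: `01_simulate_and_fit.py` (simulation + FOCE-I parameter
recovery), `02_linearize_base_model.py` (the OFV identity and the
MCETA repair of inner local minima).

## Command line

The same workflow is scriptable from the shell, driven by one YAML
config:

```bash
focelin simulate  -c run.yaml --out out/    # dataset + truth sidecar
focelin fit       -c run.yaml --out out/    # FOCE-I base fit report
focelin linearize -c run.yaml --out out/    # derivative table + OFV check
focelin screen    -c run.yaml --out out/    # extension battery, both arms
focelin compare   --base out/fit.json --extended out/ext.json --df 1
```

## Library layout

| module        | contents                                                          |
|---------------|-------------------------------------------------------------------|
| `model`       | structural/parameter/random-effect/residual model types           |
| `dataset`     | NONMEM-style CSV reader/writer (ID, TIME, AMT, RATE, DV, EVID, MDV, OCC) |
| `simulate`    | exact simulation under the model; the three preset study designs  |
| `foce`        | FOCE-I engine: inner MAP (EBEs, MCETA), OFV/iOFV, outer ML fit    |
| `linearize`   | linearization table, affine surrogate model, linearized fits      |
| `extensions`  | the extension catalogue (BSV/BOV/covariance/4 RV kinds), nesting  |
| `diagnostics` | ΔOFV classification, iOFV deviation report, screening comparison  |
| `workflows`   | end-to-end battery and power studies                              |

See `docs/methods.md` for the estimation theory, the linearization, all
default parameter choices and the known limitations.

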