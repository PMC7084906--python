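# pkbridge

Population pharmacokinetics of duloxetine (DLX) and its major metabolite
4-hydroxy duloxetine (4-HD), with a propolis (PPL) drug-interaction
covariate, rat-to-human extrapolation, and human exposure simulation.

## The problem

Duloxetine is cleared almost entirely by hepatic CYP metabolism (mainly
CYP1A2), and propolis — a very widely used bee-product supplement — inhibits
CYP1A2. Co-administration is therefore likely in practice and may raise
duloxetine exposure. Because no clinical interaction data exist, the
question is answered indirectly: quantify the interaction in rats with a
population PK model, translate the rat parameters to a human adult, and
simulate the human dosing scenarios of interest.

`pkbridge` implements that whole chain as a tested Python library for
pharmacometricians: a parent–metabolite structural model, a nonlinear
mixed-effects estimation layer, model qualification (bootstrap, VPC,
goodness of fit), interspecies extrapolation, and Monte-Carlo scenario
simulation. Because the underlying rat concentration data are not public,
the package ships a synthetic-study generator with the reference estimates
as its default truth, so every stage is testable end to end.

## The model

Disposition is a one-compartment oral model for each analyte, linked by two
metabolic routes. A fraction *F*<sub>pm</sub> of each oral dose is converted
pre-systemically (first pass) to 4-HD; the remainder (1 − *F*<sub>pm</sub>)
is absorbed at rate *K*<sub>a</sub> into the parent compartment
(*V*<sub>p</sub>/*F*<sub>p</sub>), which is cleared by
CL<sub>p</sub>/*F*<sub>p</sub> (non-conversion routes) and
CL<sub>pm</sub>/*F*<sub>p</sub> (systemic conversion into the metabolite
compartment, *V*<sub>m</sub>/*F*<sub>m</sub>, cleared by
CL<sub>m</sub>/*F*<sub>m</sub>). All parameters are apparent (/F) scales, as
an oral-only design cannot identify bioavailability separately.

Propolis acts as a static dose covariate through saturable (Michaelis–
Menten / Emax) inhibition on the two conversion routes:

    CLpm = TVCLpm · (1 − Emax_CLpm · D_PPL / (D_PPL + IC50_CLpm))
    Fpm  = TVFpm  · (1 − Emax_Fpm  · D_PPL / (D_PPL + IC50_Fpm))

Inter-individual variability is lognormal, *P*<sub>i</sub> =
*P*<sub>TV</sub>·exp(η<sub>i</sub>), η ~ N(0, ω²); the residual is
proportional per analyte, *C*<sub>obs</sub> = *C*<sub>pred</sub>(1 + ε),
ε ~ N(0, σ²). The marginal likelihood is maximised with a conditional
(Laplace, interaction-aware) approximation; covariates are selected by
stepwise forward addition (p < 0.05) and backward elimination (p < 0.01) on
the −2 log-likelihood (OFV).

Human translation: volumes scale allometrically with exponent 1.0
(V·70 kg), clearances by the liver-blood-flow ratio (21/85 mL/min/kg,
appropriate for a high-hepatic-metabolism drug), the dimensionless
fractions and inhibition constants carry over unchanged, and
*K*<sub>a</sub> is solved from Tmax = (ln *K*<sub>a</sub> − ln
*K*<sub>e</sub>)/(*K*<sub>a</sub> − *K*<sub>e</sub>) with a 2-h
enteric-coating lag.

## Worked example

```python
import pkbridge as pk

# 1. a synthetic rat study at the reference truth (3 groups x 6 rats,
#    DLX 40 mg/kg, PPL 0/500/1500 mg/kg)
truth = pk.rat_final_model()
data = pk.generate_study(truth, seed=42)

# 2. fit the population model
res = pk.PopPKModel(data, truth).fit(presolve=True, compute_se=False)
print(f"OFV {res.ofv:.1f}; fpm {res.params.structural.fpm:.3f}")

# 3. translate to a 70-kg human and tabulate the interaction scenarios
human = pk.extrapolate(truth)          # reference estimates, not the refit
print(human.to_frame().to_string(index=False))
tab = pk.scenario_table(human, typical=True, doses=(40.0,))
t = tab.set_index(["frequency", "metric"])
print(f"Cmax,ss 40 mg qd: {t.loc[('qd','cmax_ss'),'ppl0_mean']:.1f} ng/mL "
      f"(+{t.loc[('qd','cmax_ss'),'ppl15000_pct_diff']:.1f}% with "
      f"PPL 15 g/day)")
```

prints (abridged):

```
OFV 2871.9; fpm 0.612
 parameter unit   predicted
        Ka  1/h    0.687738
    CLp/Fp  L/h   34.069412
   CLpm/Fp  L/h   21.790588
     Vp/Fp    L 1022.000000
       Kep  1/h    0.054658
    CLm/Fm  L/h  212.717647
     Vm/Fm    L 5894.000000
CLDLX/FDLX  L/h  135.912409
 VDLX/FDLX    L 2486.618005
      t1/2    h   12.681640
Cmax,ss 40 mg qd: 18.2 ng/mL (+20.2% with PPL 15 g/day)
```

Reading the output: the human apparent clearance (136 L/h) and volume
(2487 L) fall inside published clinical ranges (two-fold check against
101 L/h and 1640 L passes), the typical steady-state Cmax of 40 mg once
daily is 18.2 ng/mL, and the maximum propolis dose (15 g/day) raises it by
about 20% — a measurable but moderate interaction.

A command-line interface mirrors the library (`pkbridge make-rat-study`,
`fit`, `covsearch`, `bootstrap`, `vpc`, `extrapolate`, `simulate-human`,
`run-all`); see `pkbridge --help`.

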