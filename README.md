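# toxinwars

Eco-evolutionary modelling of regulated toxin warfare between bacterial
strains.

Bacteria attack competitors with bacteriocins and antibiotics, and these
attacks are usually under tight regulatory control — quorum sensing,
nutrient stress responses, damage sensing. `toxinwars` asks which control
strategies natural selection favours. It couples two layers:

1. **Ecology.** A pairwise competition in a well-mixed patch: strains A
   and B grow on a shared nutrient pool N with Monod kinetics and each
   produces a toxin that kills only the other strain,

       dC_A/dt = (1 - f_A) mu_max N/(N+K_N) C_A - k T_B C_A
       dT_A/dt = f_A N/(N+K_N) C_A - l_T T_A
       dN/dt   = -N/(N+K_N) (C_A + C_B)

   (and symmetrically for B), where f is the fraction of uptake invested
   into toxin rather than growth. f can be a constant (constitutive
   production) or switch between `f_initial` and `f_induced` when a sensed
   signal — nutrient depletion, the opponent's toxin, or the strain's own
   density — crosses a threshold.

2. **Evolution.** Patch outcomes feed metapopulation game theory: the
   invasion index `I_inv = w(f_inv|f_res) / w(f_res|f_res)` compares a
   rare mutant's productivity against the resident with the resident's
   productivity against itself. On top of this sit pairwise invasibility
   analysis and ESS search for constitutive producers, deterministic grid
   tournaments over the sensing-strategy space, optimisation against
   standing opponent diversity with a fitness regression, and a genetic
   algorithm in which sensing strategies coevolve in round-robin
   tournaments.

The package is aimed at theorists of microbial social evolution who want
to reproduce, probe or extend this class of warfare models: every
experiment is configurable, seeded and runs from a laptop-scale grid up to
the full-resolution grids.

## Worked example

A constitutive duel — an aggressive producer (f = 0.3) against a weak one
(f = 0.1):

```yaml
# duel.yaml
strategy_A: {mode: constitutive, f: 0.3}
strategy_B: {mode: constitutive, f: 0.1}
```

```
$ toxinwars simulate --config duel.yaml --out duel_run
winner: A
$ cat duel_run/outcome.json
{
  "final_biomass_A": 0.19079533993814377,
  "final_biomass_B": 0.0,
  "extinct_A": false,
  "extinct_B": true,
  "local_winner": "A"
}
```

The heavier investor drives its competitor extinct (B's biomass fell
below the stochastic-extinction threshold 1e-6 gC) and ends the 24 h
competition with 0.19 gC of biomass — note how little that is compared
with the 5.1 gC a *pair of non-producers* would each harvest from the same
patch: warfare is expensive, which is exactly why the metapopulation layer
matters. `duel_run/trajectory.csv` holds the full time series
(`t,C_A,C_B,T_A,T_B,N,f_A,f_B`), and `resolved_config.yaml` plus `run.log`
make the run reproducible.

The same from Python, plus the evolutionary layer:

```python
from toxinwars import EcologicalParams, constitutive, find_ess, simulate_competition

out = simulate_competition(constitutive(0.3), constitutive(0.1))
print(out.local_winner, out.final_biomass_A)   # A 0.19079533993814377

result = find_ess(EcologicalParams(), grid_step=0.01)
print(result.f_opt)                            # 0.31
```

`find_ess` builds the full 101x101 invasion matrix (5,151 competitions,
about half a minute) and reports the optimal constitutive investment: the
strategy no other grid strategy can invade and that invades all 100
others. (The strict two-sided ESS quantifier is blocked by the passive
f = 0 resident, which nothing out-produces globally; see
`docs/methods.md`.)

Other entry points: `toxinwars pip / ess / invasion-map / diversity / ga /
sweep`, each writing CSV/JSON results plus its resolved config. The
library surface mirrors these (`pairwise_invasibility`, `invasion_map`,
`diversity_tournament`, `fit_fitness_regression`, `run_ga`, `sweep_ess`).

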