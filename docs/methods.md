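# Methods

## Scope

`pkdistill` demonstrates that a mechanistic oral-PK simulator can be
distilled into per-metric random-forest surrogates with high fidelity *to
the simulator*. Everything the surrogates learn is generated in-package;
no external data are required. Agreement with the simulator says nothing
by itself about agreement with clinical PK data — that depends entirely on
the realism of the PBPK model and of the sampled property ranges.

## Virtual-drug generation

Each virtual drug is an independent uniform draw from a box of 13
quantities (20 features once FuPC is expanded per tissue). Sampling is
uniform on the **linear** scale for every quantity, including solubility
(0.001–1000 mg/ml) and V_max (1e-6–1e-2 µmol/min/mg), which span 5–6
decades; a log-uniform switch exists but is off by default because the
reference study conditions are linear-uniform. Consequences worth knowing:
half of all sampled solubilities exceed ~500 mg/ml, and "low-solubility"
drugs (below a few mg/ml) are rare relative to a log-uniform design.

Two unit conventions are interpretations rather than transcriptions of the
source ranges:

* **Effective permeability** is stored in multiples of 1e-4 cm/s. Human
  jejunal Peff values measured by perfusion are of order 0.1–10 × 1e-4
  cm/s, so the 0.015–8 range is read on that scale; taking it literally as
  cm/s would make every drug absorb completely within seconds.
* **Molar volume** is treated as ml/gmol (the unit the Hayduk–Laudie
  diffusion correlation requires), not the mass unit printed alongside it
  in the source table.

The drug-density range 0.1–0.7 g/ml is unusually low for solid drug
particles but is reproduced as given.

**BCS thresholds.** The classification uses solubility > 250 mg/ml and
Peff > 3.5 (in 1e-4 cm/s) as "high", with values exactly at a threshold
counted "low" (immaterial under continuous sampling). These cut points are
not physiological dose-number criteria; they were chosen so that uniform
sampling reproduces the reference library's class composition
(expected fractions 0.423/0.141/0.327/0.109 for I/II/III/IV) within
binomial noise. Both thresholds are config-exposed.

**Real-drug matching.** A virtual drug matches a real one at tolerance t
when all six of molecular mass, density, molar volume, pKa, solubility and
Peff lie within t·(real value); 15% defines "close", 50% "moderate". The
40-drug reference panel is not shipped (it is user-supplied), so the
match fractions themselves are not asserted by tests.

## The CAT PBPK model

The ODE system follows the compartmental-absorption-and-transit
convention. Design choices, all config-exposed:

* **Lumen chain**: stomach (gastric-emptying half-time 0.25 h), duodenum,
  jejunum ×2, ileum ×3 (small-intestinal mean transit 3.32 h split evenly
  over the six segments, i.e. k_t = 6/3.32 h⁻¹ each), colon (residence
  13.5 h). Segment radii 10/1.6/1.5/1.5/1.2/1.2/1.2/2.5 cm and luminal pH
  1.7/6.0/6.2/6.4/6.8/7.0/7.4/6.8.
* **States**: an unreleased pool with first-order release (default
  100 h⁻¹ ≈ immediate release; no release parameter is sampled),
  an undissolved pool, and a dissolved pool per segment.
* **Dissolution**: Noyes–Whitney,
  `rate = 3D/(ρ_molar r²) · M · (S_eff − C)`, with the diffusion-layer
  thickness equal to the particle radius and D from Hayduk–Laudie on the
  molar volume (water viscosity 0.8904 cP at 37 °C). In the integrator the
  term is kept linear in M through zero (small negative excursions are
  pulled back smoothly) and is switched off under supersaturation, where a
  separate first-order precipitation term (the drug's sampled rate
  constant, acting on the excess `max(0, C − S_eff)·V`) returns drug to
  the undissolved pool — the two terms never double-count.
* **Ionization**: Henderson–Hasselbalch with the sampled pKa treated as an
  acidic dissociation constant (only that type is sampled); the
  solubility boost is capped at 1000× to keep strongly ionized acids
  finite. The cap and ionization type are settings.
* **Absorption**: `k_a = 2·Peff/R` from every intestinal and colonic
  segment; gastric absorption is off by default.
* **Distribution**: perfusion-limited tissues (stomach, duodenum, jejunum,
  ileum and colon walls, liver, kidney, rest-of-body) with venous
  concentration `C_i·FuPC_i`; gut walls drain via the portal vein into the
  liver. Reference volumes and flow fractions are textbook human values at
  70 kg; volumes scale linearly with body mass, cardiac output as
  (BW/70)^0.75 with fixed flow fractions, so flows always sum to cardiac
  output.
* **Elimination**: hepatic Michaelis–Menten metabolism only, driven by the
  unbound liver concentration `C_liver·FuPC_liver`, with capacity
  `V_max · MPPGL (40 mg/g) · liver mass (2.6% BW) · 60 min/h`, plus fecal
  escape from the colon. No renal or biliary clearance is modelled because
  no such parameters are sampled; the kidney is a distribution compartment
  only.

**Numerics.** LSODA (via `scipy.integrate.odeint`) with rtol 1e-8 and
atol 1e-12·dose, output on a uniform 0.05-h grid to 48 h. The
right-hand side is compiled with numba when available (≈40 ms per
simulation; a pure-Python fallback gives identical results). These
tolerances hold the mass-balance defect below ~1e-12 relative and negative
solver excursions below ~1e-10·dose; a convergence test checks that
halving the step and tightening tolerances moves Cmax by <0.1%. Simulation
failures are skipped and logged, and the batch aborts if more than 1% fail
(in practice none do).

The 48-h window truncates AUC for slowly cleared drugs (low
FuPC_liver·V_max): a diagnostic warns whenever `C(t_end)·t_end` exceeds 5%
of AUC. Many virtual drugs are still accumulating at 48 h, which also
places their tmax exactly at the window end — a real feature of the
sampled parameter space, not an artifact.

## Summary metrics and dataset

Cmax is the grid maximum, tmax the earliest time attaining it (ties break
early), AUC the trapezoid over the full grid with no extrapolation to
infinity; Cmax and AUC are divided by dose. Min–max scaling is fit on the
**complete** dataset before the 80/20 split — this mirrors the reference
workflow's order of operations and leaks only the two extrema. Degenerate
(all-zero or failed) simulations are dropped with a logged count before
normalization.

## Surrogates

One `RandomForestRegressor` per normalized metric, always 150 trees;
per-label models consistently beat a single multi-output model on held-out
adjusted R², so that is the only mode. The tuning grid is a design default
(max depth {10, 20, ∞} × min samples per leaf {1, 2, 5} × features per
split {all, √k, k/3}, 5-fold CV, R² scoring); the acceptance script uses a
2×2×2 subgrid with 3-fold CV, which selects the same region of the grid at
a third of the cost at its problem size (3,000 drugs). A gradient-boosting
alternative sits behind a config switch for comparison; random forest is
the default. Training is fully seeded and byte-reproducible; a training
fingerprint (hash of the training features) makes test-set isolation
checkable.

## Evaluation and feature reduction

Adjusted R² uses k = the number of features actually in the scored model.
Relative errors are computed on the normalized metrics,
`100·(pred − ref)/ref`; normalized references can sit near zero, so rows
with |ref| < 1e-6 are excluded and counted in the report (exclusions are
rare — at most a handful per split). Histogram bins are 5 percentage
points wide, symmetric about zero.

The reduced-feature-set search aggregates importance as the mean rank of
each feature across the three per-metric forests (impurity-based scores,
each summing to 1), then retrains all three models on every nested prefix
of that ranking, reusing each metric's tuned hyperparameters rather than
re-running the grid search at every size. The optimal set maximizes the
**mean** test adjusted R² across the three metrics — the reference
procedure reports one shared optimal set, which implies a joint criterion.
Scored per metric, the winning subset can in principle sit ~0.01 below the
per-metric optimum; the dominance test tolerates exactly that.

## What the synthetic conditions do and do not show

The generator reproduces the study conditions (ranges, uniform sampling,
15,000-drug default library, 80/20 split, 150 trees). Fidelity numbers in
the acceptance script use a 3,000-drug library — large enough for stable
forest training while keeping the end-to-end run in minutes; surrogate
accuracy at 3,000 is systematically a few points below the 15,000-drug
regime, most visibly for tmax, whose normalized distribution is bimodal
(early peaks vs. window-end accumulation). Passing tests demonstrate
faithful distillation of *this* simulator under *these* sampling
assumptions; they do not validate the PBPK model against human data, and
unrealistic property combinations (e.g. high-dose, near-zero-density
particles) are sampled and simulated without rejection.
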