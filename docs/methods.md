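# Methods

## Occupancy model

Transcription initiation is modelled as thermodynamic equilibrium binding
of σ70 (carrying RNA polymerase) to the −10/−35 promoter hexamers,
modulated by one ligand-inducible activator and zero or more repressors.
Microstates are subsets of {σ, A, R₁, …, Rₘ} with Boltzmann weights
relative to the empty promoter (weight 1):

- σ contributes `K_eq = exp(−(ΔG−10 + ΔG−35))`, energies in k_BT,
  natural logarithms throughout;
- the active activator contributes `q_A = a(c)·K_A` and, when
  co-occupying with σ, an extra recruitment factor ω (ω ≥ 1 means
  activation);
- each active repressor contributes `q_R = ρ(c)·K_R`; any state
  containing σ together with a repressor is excluded (steric occlusion of
  the core promoter by a spacer/+1-bound repressor). Repressors are
  mutually compatible and independent of the activator.

Summing the allowed states gives the closed form

```
P(σ bound) = K_eq (1 + q_A ω) / [ (1 + q_A) ∏_j (1 + q_Rj) + K_eq (1 + q_A ω) ]
```

which the test suite checks against explicit state enumeration to 1e−12
over random parameters. The observable is `r = α·P + b` (RPU). The
additive background b (autofluorescence plus reporter leak) is what makes
fold change converge to 1 in *both* K_eq limits: without it an
arbitrarily weak promoter would still show full fold induction. The model
deliberately excludes DNA looping, promoter escape/elongation kinetics,
σ-factor competition and an explicit RNAP concentration (absorbed into
K_eq and α). A promoter bearing two operator copies for the same
repressor (e.g. TetR at +1 and ~−400) is modelled as a single effective
repressor weight.

Ligand response is a Hill function: activators `a(c) = cⁿ/(cⁿ+hⁿ)`,
repressors `ρ(c) = hⁿ/(cⁿ+hⁿ)` (the ligand deactivates the repressor).
Defaults are n = 2 and half-maximal concentrations at one tenth of the
standard working concentrations (arabinose 5 mM → EC50 0.5 mM; IPTG
1 mM → 0.1 mM; aTc 100 ng/mL → 10 ng/mL), so the ON state sits near but
not at saturation — a realistic regime in which residual repressor
activity at full induction is visible in three-input gates. An
alternative two-rate model (distinct rates for σ-only and Aσ states) is a
possible extension point; the single-α-plus-background form is used
because it reproduces all qualitative behaviours with one fewer degree of
freedom.

## Parameter defaults

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| α | 1e5 | RPU | matches the maximal expression scale of strong σ70 promoters in RPU-standardised assays |
| b | 10 | RPU | small but non-zero leak/autofluorescence floor |
| ω | 100 | — | activator recruitment strong enough that the Aσ state dominates σ-alone when induced |
| K_A | 50 | — | operator occupancy well above 1 when active |
| K_R (LacI) | 200 | — | ~200-fold repression capacity |
| K_R (TetR) | 500 | — | stronger repression (+1 operator) |
| hill_n | 2 | — | typical inducible-system cooperativity |

Site energies ΔG are relative: the consensus-like anchors ("a" for −35,
"A" for −10) are pinned at 0 k_BT, so only ln K_eq differences are
meaningful.

## Fitting

The loss is least squares on log rates, Σ (ln r_obs − ln r_pred)², which
weights the decades of an RPU measurement equally and matches
multiplicative plate noise. Free parameters: one ΔG per non-anchor −35
and −10 site plus shared globals (α, b, ω, one binding weight per
regulator), all globals in log space for positivity. Sharing globals
across the library encodes the additivity assumption: variants differ
only through their site energies. Regulator Hill exponents and EC50s are
held fixed at configuration values during fitting.

The additive energies have a one-dimensional gauge freedom
(ΔG−35 → ΔG−35 + δ, ΔG−10 → ΔG−10 − δ leaves every ln K_eq unchanged).
`fit_model` removes it by pinning both anchors to 0 inside the optimiser;
`apply_gauge` re-imposes the convention on any result by the single shift
that zeroes the −35 anchor, which exactly restores a shifted fit and is
idempotent. Because only one shift exists, an arbitrary hand-constructed
result can have only one anchor forced to zero; results from `fit_model`
always have both.

Optimisation uses Levenberg–Marquardt (`scipy.optimize.least_squares`)
from a data-driven start plus seeded multistart (default 8 points,
Gaussian perturbations of scale 2 in parameter space; best final loss
wins, so the best-so-far loss is monotone in the number of starts). The
data-driven start matters: α and b start at the observed rate extremes,
site energies at the additive least-squares decomposition of the
occupancies implied by the least-induced condition, and ω at the largest
observed induction ratio. Starting at the data scale keeps the local
optimiser out of the no-induction local minimum (K_A → 0), which is
otherwise attracting when the initial α is orders of magnitude off.
Observed non-positive rates (possible after background subtraction or
noise) are floored at half the smallest positive rate before logging.

With only two conditions (uninduced/induced), K_A and ω are individually
weakly identified — the data constrain q_A = a·K_A and the product q_A·ω
strongly, their split weakly — but every ln K_eq, α, b and the predicted
rates are well determined, and those are the quantities used downstream.
The additive per-site decomposition is the only parameterisation offered:
it is the substantive assumption being tested, and an unconstrained
per-combination K_eq would forfeit the library's statistical sharing for
no gain at this design size.

## Plate assay normalization

Per-OD fluorescence gain is `Fluo = (fluor_4h − fluor_2h) / OD600`, using
the 4 h OD reading (configurable; the 2 h read subtracts pre-induction
fluorescence). RPU standardisation divides by the per-plate mean
reference-well gain and multiplies by the reference's assigned RPU
(default 1.0). RPU is therefore invariant to global instrument gain, and
a plate without reference wells is an error naming the plate. Blank
(autofluorescence) subtraction is available but off by default.

## Synthetic data

The generator emulates the standard plate experiment designs: a
combinatorial 6×8 library under one activator with and without inducer
(288 test wells + reference wells), the same library under
activator+repressor in four conditions, dose–response titrations of
low/mid/high-K_eq exemplars (bD, dE, eG), and truth-table-complete two-
and three-input gate panels. Default true energies — −35 ΔG ∈ {0, 0.7,
1.5, 2.3, 3.2, 4.5}, −10 ΔG ∈ {0, 0.5, 1.0, 1.8, 2.6, 3.5, 4.6, 6.0}
k_BT — were chosen so the 48 ln K_eq values tile the whole
dynamic-range curve from saturated to near-silent promoters; they are
fixture choices, not measurements.

Noise is multiplicative lognormal with mean 1 and coefficient of
variation 0.10 (biological triplicates by default): plate fluorescence
error scales with signal, and a 10% CV is a typical triplicate spread for
this kind of assay. Ground-truth rates are computed by the same
`thermo_model` code path the analysis uses, so generator and model cannot
diverge. What the generator does *not* emulate: growth dynamics, plasmid
copy-number variation, well-position effects, regulator crosstalk, and
any systematic model misspecification — so passing recovery tests shows
the estimator is correct and well-conditioned under the stated noise, not
that the occupancy model is an adequate description of any particular
real promoter. Real repressed promoters at high ln K_eq in particular can
deviate from this model (e.g. through DNA looping), which it does not
attempt to capture.

## Gate analysis

Truth tables enumerate all 2^k on/off ligand combinations, ON levels at
the working concentrations. The AND score is the ratio of the all-on
state's mean rate to the maximum over all other states; a gate is "well
behaved" when the score is ≥ 10 (boundary inclusive) — the threshold is a
configurable operationalisation of a qualitative criterion. Leak/signal
phenotypes are quadrants of the (max-OFF, ON) plane with strictly-below
counting as "low"; default thresholds are the geometric midpoints of the
observed distributions. Combination ranking is descending by the chosen
objective with ties broken by fold change then label, making it
deterministic and row-order independent.

## Numerical choices

- ln K_eq is clipped to ±60 inside the fit residual (occupancy is
  saturated far earlier); log-space global parameters are clipped at
  exp(60) to keep optimizer trial steps finite.
- Zero K_eq (infinite site energy) gives exactly P = 0; fold change with
  a zero OFF rate raises rather than returning infinity.
- Replicate aggregation uses the sample standard deviation (ddof = 1),
  reported as 0 for n = 1.
- Problem sizes: acceptance-level checks use 10,000 random draws for the
  oracle comparison, a 251-point ln K_eq grid over [−25, 25] (wide enough
  that the background-dominated fold-change limits are visible), and 20
  seeded repetitions of the 6×8 library fit; one fit takes well under a
  second, the whole acceptance run a few seconds.

## Known limitations

- At most one activator per promoter (proximal-operator recruitment
  geometry); multi-activator promoters raise an unsupported-architecture
  error.
- Energies are fitted, never predicted from sequence; the sequence
  annotations (consensus mismatches) are descriptive only.
- No uncertainty quantification beyond multistart spread; no model
  selection between alternative state structures.
- Operator base content is symbolic: the model reads operator identity
  and role, never sequence.
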