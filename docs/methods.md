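# Methods

## Rate law

The observed cleavage rate constant of the dimer pool is modeled as the
sum of four parallel pathways:

    k_cl = kH·[H⁺] + kH2O + kcat·c·f([H⁺]) + kOH·KW/[H⁺]
    f([H⁺]) = Ka²/([H⁺]² + Ka·[H⁺] + Ka²)

- `kH` (M⁻¹ s⁻¹): hydronium-ion-catalyzed cleavage, dominant below pH 5
  (log-log slope −1).
- `kH2O` (s⁻¹): pH-independent (water) cleavage, the pH 5–6 plateau of the
  uncatalyzed reaction.
- `kOH` (M⁻¹ s⁻¹): hydroxide-ion-catalyzed cleavage, dominant in base
  (slope +1); [OH⁻] is represented as KW/[H⁺].
- `kcat` (M⁻¹ s⁻¹): second-order catalytic constant of the arylmercury
  complex at concentration `c`, modulated by the speciation fraction `f`.
- `Ka` (M): shared kinetic acid-dissociation constant. Two protolytic
  equilibria shape the catalytic term, but the observed second-order
  dependence on [OH⁻] between pH 5 and 6 forces their constants to be
  nearly equal, so a single `Ka` is fitted (`Ka1 = Ka2`). It is treated
  as a purely kinetic constant: no microscopic site (mercury aqua ligand
  versus adenine) is assigned.
- `KW` (M²): ionic product of water at the working conditions, default
  6.2×10⁻¹³ (90 °C, I = 0.1 M). Configurable, never fitted.

[H⁺] is 10^(−pH) on the concentration scale; activity corrections are
not applied, consistent with quoting KW on the concentration scale for
the same medium. Temperature (90 °C), ionic strength (0.1 M NaNO₃) and
buffer (30 mM) travel as metadata only; buffer catalysis is assumed
absent. The reference constants shipped as `TABLE1_BACKGROUND` and
`TABLE1_CATALYST` are the fitted values for the catalyst-free and 1 mM
catalyst experiments.

Limiting behavior used in validation: `f` is bounded in (0, 1), equals
1/3 exactly at [H⁺] = Ka, and drives the catalytic term's log-log slope
to +2 when [H⁺] ≫ Ka; the slope of the full law is confined to [−1, +2]
for any nonnegative parameter set.

## Reaction network

Isomerization (3′,5′ ⇌ 2′,5′ phosphate migration), cleavage of both
isomers to the 2′,3′-O-methylene nucleoside plus 2′,3′-cAMP, and the
consecutive hydrolyses cAMP → 2′/3′-AMP → adenosine form a linear
first-order system dx/dt = A·x. It is solved with the matrix exponential
(`scipy.linalg.expm`) at each sampling time — an exact solution, not a
stepped integrator — and is cross-checked in the tests against an
independent fixed-step RK4 integrator and against the consecutive-reaction
(Bateman) closed form.

Compositions are mole fractions on a dimer-equivalent basis: each cleaved
dimer contributes one unit to the released nucleoside N6 and one unit to
the cAMP lineage, so both conservation sums

    N4 + N5 + N6 = 1 and N4 + N5 + cAMP + AMP + Ado = 1

hold at every time point (to 10⁻⁹ or better). This mirrors HPLC
peak-area shares under the assumption of equal detector response factors.

## Estimators

**Pool cleavage rate.** The experiment observes the disappearance of the
combined isomer pool, so `observed_cleavage_rate` is the negated slope of
a least-squares line through ln(N4+N5) versus time. Under multiplicative
observation noise with constant relative magnitude the log-scale errors
are homoscedastic, making the unweighted log-linear regression the
correctly weighted estimator. The pool decay is exactly single-exponential
when both isomers cleave at the same rate (the default assumption, since a
single pooled constant is what the experiment resolves); when the two
cleavage rates differ the estimate is the best log-linear approximation
and the residual bias is visible in the regression standard error, not
hidden. An increasing pool is flagged, not silently fitted.

**Isomerization rate.** The within-pool isomer share N5/(N4+N5) relaxes
exponentially toward equilibrium with rate k₄₅ + k₅₄ (exactly, when
cleavage rates are equal); it is fitted as a three-parameter exponential.
A flat share (start at equilibrium) is reported as unidentifiable with a
`no_signal` flag.

**pH-profile fit.** Residuals are taken on log₁₀(k_obs): the observed
constants span more than three decades over pH 3–8.5 and the natural
error model is relative, so log residuals equalize the information per
point and match the log-scale presentation of pH-rate profiles. Reported
standard errors, when present, are propagated to the log scale as
se/(k·ln10); noise-free data get unit weights. All constants are
positive and are fitted as θ = ln p, which removes the need for bound
constraints; the optimizer is Levenberg–Marquardt
(`scipy.optimize.least_squares`) with tight (10⁻¹⁴) tolerances.
Initial guesses are deterministic and data-driven: kH from the most
acidic point (k/[H⁺]), kOH from the most basic (k·[H⁺]/KW), kH2O from
the pH 5–6 plateau, kcat from the pH 6–7 excess over the background
guess, Ka = 10⁻⁶ M. `kcat` and `Ka` enter the free set only when the
data contain catalyst; requesting them otherwise is rejected as
structurally unidentifiable. Fitting a single profile reproduces the
per-column analysis; passing the catalyst-free and catalyst profiles
together gives the optional shared-background joint fit. Standard errors
are Gauss–Newton: the Jacobian-based covariance scaled by the reduced
chi-square, mapped from the log scale by the delta method, quoted as 1σ.
Non-convergence is returned as a flagged result with the optimizer
message, never silently.

**Concentration series.** The law is affine in catalyst concentration,
so k_obs versus c is fitted by weighted linear least squares (weights
1/se², closed-form normal equations). The slope is the apparent
second-order catalytic constant at the series pH; dividing by f(pH)
(requires Ka) yields the intrinsic `kcat`. At pH 7 with Ka = 3×10⁻⁶ M the
speciation fraction is 0.967, so apparent and intrinsic constants differ
by ~3%.

## Synthetic data

The generator emulates the RP-HPLC experiments: rate constants evaluated
on the study grids (pH 3.0–8.5 in 0.5 steps; catalyst 0–7 mM in 1 mM
steps; eight aliquots log-spaced over three half-lives) with
multiplicative lognormal noise. The noise factor has mean one and
relative standard deviation `cv` (default 0.1 — a plausible relative
error for HPLC peak integration; the true replicate structure of the
experiments is not recorded, so `cv` is a modeling knob, not a claim).
Reported standard errors are cv·k_obs. All randomness flows through a
seeded `numpy` Generator; identical seeds give bitwise-identical output.

Noisy time courses are renormalized the way peak-area shares are: the
monophosphate lineage (N4, N5, cAMP, AMP, Ado) is rescaled to sum to one
and N6 is taken as the complement of the uncleaved pool, so the
share arithmetic of an HPLC trace is preserved and noise-free rows sum to
one exactly.

The side-reaction constants of the default network (isomerization at half
the cleavage rate, the two downstream hydrolyses at twice it) are
assumptions of plausible magnitude — no measured values exist for them —
and are marked as such in the generated metadata. What passing tests
show, therefore, is that the estimators recover the generating rate law
under relative noise on the stated designs; they do not validate response
factors, buffer effects, pH-meter drift or any feature of real
chromatograms the generator does not model.

## Reproducibility and problem sizes

The acceptance script refits noise-free profiles of 23 points (pH 3.0–8.5,
step 0.25) from starting guesses at twice each generating value, and
averages the slopes of 100 replicate noisy catalyst series (8 points
each); the replicate recovery study in the tests uses 100 joint fits of
24-point profile pairs. These sizes make every check run in seconds while
leaving the estimators' statistical behavior clearly measurable. Every
CLI run logs its seed, package versions and a hash of the resolved
configuration, and outputs carry that hash.

## Known limitations

- The mechanism of proton transfer is outside scope; the model is the
  phenomenological rate law only.
- KW is held at its 90 °C value; no temperature extrapolation.
- Equal HPLC response factors across species are assumed.
- The ± values on the reference constants have no stated confidence
  convention; 1σ is assumed throughout. The small mismatch between the
  slope-derived (1.7×10⁻³) and profile-derived (1.6×10⁻³) catalytic
  constants is within those uncertainties and is left as is.
- When the two isomers cleave at different rates the pooled estimator is
  biased by construction; the bias is documented rather than corrected,
  matching the pooled treatment of the experimental analysis.
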