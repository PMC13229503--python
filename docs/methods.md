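# Methods

This note documents the models, estimators and numerical choices behind
`bindkin`, and what the synthetic-data generators do and do not emulate.

## Kinetic schemes and relaxation rates

Both binding mechanisms are modeled as linear three-state chains under
pseudo-first-order conditions (ligand concentration [L] constant, binding
linearized as k₊[L]; no ligand-depletion mode is provided):

- **CS**: open ⇌ closed ⇌ closed·L, with conformational excitation k_e
  (open → closed), relaxation k_r, and binding k₊[L]/k₋ on the closed state.
- **IF**: open ⇌ open·L ⇌ closed·L, with binding k₊[L]/k₋ on the open state
  and conformational rates k_r (closing of the liganded protein) / k_e
  (reopening).

States are ordered (unbound ground, intermediate, bound) everywhere. The
dominant relaxation rate is the smallest-magnitude nonzero eigenvalue of
the 3×3 generator; `exact_relaxation_rate` evaluates it in closed form and
the generator (`rate_matrix`) serves as an independent numerical oracle —
the two agree to a relative 1e−9 over random rate sets in the tests. The
closed-form discriminant is clipped to zero when it falls in
(−1e−12·S², 0); more negative values raise, since they indicate an
inconsistent rate set rather than round-off.

Effective two-state constants follow the standard weak-coupling reductions:
CS k_on = k_e k₊/(k_r + k₊[L]), k_off = k_r k₋/(k_r + k₊[L]); IF
k_on = k₊ k_r/(k₋ + k_r), k_off = k₋ k_e/(k₋ + k_r). `EffectiveRates.K_d`
is defined as k_off/k_on in both cases. For IF this equals the exact
half-saturation constant; for CS it equals k₋k_r/(k₊k_e), which coincides
with the exact half-saturation constant k₋(k_e + k_r)/(k₊k_e) only when the
closed conformation is weakly populated (k_e ≪ k_r) — the regime in which
the effective-rate picture is valid at all. The exact constant is exposed
separately as `equilibrium_kd`. The approximation k_on[L] + k_off deviates
from the exact rate by under ~10% across the tested regime (closed
population ≤ 10%, [L] ≥ K_d); the tests enforce 12%.

ODE integration uses LSODA with rtol 1e−8 / atol 1e−10 (configurable) and
an analytic Jacobian; trajectories are renormalized to unit occupancy,
removing integrator round-off below 1e−9.

Binding free energies are reported as RT ln(K_d/1 M) in **kJ/mol**
(R = 8.314 J mol⁻¹ K⁻¹). For K_d = 35 nM at 298.15 K this gives −42.6
kJ/mol; source captions quoting the same number as "kcal/mol" carry a
unit-label slip, and the enthalpy/entropy split (−62.3 + 19.9 = −42.4)
disagrees with it by 0.2 kJ/mol of reporting rounding — neither is treated
as an error by the code.

## Mechanism discrimination

`mechanism.discriminate` is pure inequality propagation; uncertainty enters
only through the input bounds, and no probabilistic model is imposed.

The CS chain: the SPR bound k_on ≥ k_on_lb forces
k_obs ≥ k_on_lb·L_max + K_d_lb·k_on_lb at the top tested concentration.
Because k_obs([L]) approaches its limit k_e monotonically from either side
(rising for k_e > k₋, falling for k_e < k₋ — and in the falling case
k_obs at L_max ≫ K_d is already within ~2% of k_e), the floor on k_obs is
a floor on k_e in both cases; the population ceiling P = k_e/(k_e + k_r)
then gives k_r ≥ k_e(1/P − 1). A rejection-sampling test confirms that no
rate set admitted by the *exact* relaxation-rate formula violates the
derived k_e bound by more than 5%. CS is declared incompatible when the
implied k_r exceeds the exchange-rate ceiling, leaving only the
fast-exchange escape regime (sub-100-ns by default, below the instrumental
time-tagging resolution).

The IF chain: k_off = K_d·k_on maps the K_d and k_on intervals onto a
k_off interval; the scheme requires k_off < k_e < k_r, so IF is compatible
whenever k_off_min fits under the ceiling, and
P_OL ≥ k_off_min/(k_off_min + ceiling) bounds the open-liganded occupancy
from below. Verdicts carry an equation trail; `replay_trail` recomputes
every number from the recorded constraints.

With the reference constraint set (K_d 10–20 nM, k_on 3·10⁷–10⁸ M⁻¹s⁻¹,
L_max 500 nM, 10% ceiling, 100 s⁻¹ exchange ceiling) the chain produces
k_e ≥ 15.3 s⁻¹, k_r ≥ 137.7 s⁻¹, timescales ≤ 7.26 ms, k_off ∈ [0.3, 2] s⁻¹
and P_OL ≥ 0.3%; rounded presentations (15, 135, 7.4 ms) are one display
step away from the raw values, and both are kept to avoid silent rounding
drift.

## SPR model and fitting

The sensorgram model couples first-order transport of ligand between bulk
and surface (rate k_t, both directions) to 1:1 binding, with the response r
(RU) linked to surface concentrations by [PL] = α·r, [P]_tot = α·r_max.
α defaults to 1 µM/RU. Under the quasi-steady surface approximation only
k_t/α is identified, so the fitted k_t rescales proportionally with α while
r_max, the SSR and every k_on readout are α-invariant; the tests pin this
behavior rather than a literal invariance of k_t.

Fitting protocol, per cycle:

1. **Drift correction** — a·e^(−bt) + c fitted jointly to the pre-injection
   baseline (first 60 s) and the dissociation tail (last 100 s), subtracted;
   linear fallback with a warning if the exponential fit fails.
2. **Association** — k_t and r_max fitted (log-parameterized, bounded,
   multistart from the initial slope and trace maximum) at fixed k_on, with
   k_off tied to K_d·k_on and initial conditions [L]_surf = 0, r = 0.
   When the fitted curve amplitude falls below the residual noise the fit
   is on a flat ridge (the curve is independent of r_max far from
   saturation); it is canonicalized to the minimal consistent r_max and
   flagged `no_signal`.
3. **Dissociation** — k_t alone over the first 50 s, initial conditions
   [L]_surf = [L]_bulk, r = r_max/(1 + K_d/[L]_bulk).
4. **SSR profile** — total (association + dissociation) SSR on a log-spaced
   k_on grid (default 30 points over 10⁵–10¹⁰ M⁻¹s⁻¹), rescaled by its
   minimum so the plateau sits at 1. The y-axis rescaling and the
   threshold (default 1.05) are this package's operationalization of the
   plateau-versus-rise readout. `k_on_lower_bound` returns the smallest
   grid point at or below threshold, flagging profiles that are flat
   everywhere (`unbounded-below`) or that rise at the upper end by more
   than 2× the floor (`identifiable` — k_on directly estimable, a candidate
   outlier in a bound-seeking ensemble). Small plateau tilt (≲ 25%) arises
   from the dissociation boundary layer at very large fixed k_off and is
   expected.

Synthetic study conditions: k_on = 10⁸ M⁻¹s⁻¹, K_d = 10 nM, r_max = 3.5 RU,
k_t = 6 s⁻¹, eight-step ligand ladder 7.8–1000 nM, 50 s association, 360 s
dissociation, 10 Hz sampling, 0.02 RU noise. α·k_on·r_max ≈ 350 s⁻¹ ≫ k_t,
so the cycles are firmly transport-dominated (k_on unidentifiable, profile
flat above a knee), while k_t is large enough that the dissociation phase
decays to within noise of baseline before the drift-tail window — the
regime the drift-correction protocol presumes, mirroring the practice of
discarding traces that still drift at the end of dissociation.

## smFRET pipeline

Photon streams carry integer timestamps (100 ns clock) and a stream label
per photon — DD, DA (donor excitation, donor/acceptor detection) and AA
(acceptor excitation) — from the 50 µs alternation. Burst searches:

- **All-photon**: a photon is burst-like when ≥ 15 photons (itself
  included) fall within a centered 500 µs window; maximal runs of
  burst-like photons with ≥ 150 photons total form bursts. This
  neighborhood-count reading is fixed by a brute-force oracle in the tests.
- **Dual-channel** (AND-gate): the m = 10-photon sliding-window rate
  criterion (local rate ≥ 6× background) evaluated separately on the
  donor-excitation and acceptor-excitation substreams; photons count as
  burst photons only where both criteria hold, and bursts need ≥ 50 photons
  from each excitation. Donor-only and acceptor-only species fail the gate
  by construction.

E* = F_DA/(F_DD + F_DA) and S* = (F_DD + F_DA)/(F_DD + F_DA + F_AA) are
reported uncorrected for background; species gates default to S* ∈
(0.3, 0.8) for the doubly-labeled population. Corrected FRET applies the
direct-excitation (α), crosstalk (β) and detection (γ) factors.

Population fits are maximum-likelihood Gaussian mixtures on burst values
(histogram least squares with 0.02 bins available as an option; constant
samples return a bin-width σ floor with a `degenerate` flag). The
outside-fraction statistic counts bursts outside the union of
⟨E*⟩ ± k·σ bands over the fitted components; k and the band union are
parameters because a pure Gaussian at k = 1 already leaves 31.7% outside,
so any empirical value below that implies a wider effective band.

**BVA**: donor-excitation photons of each burst are partitioned in order
into consecutive n-photon windows (default n = 5; trailing partial windows
dropped), and the SD of window proximity ratios is compared with the
binomial semicircle √(E*(1−E*)/n). The SD estimator sits slightly below
the semicircle for small window counts (finite-sample bias of an SD around
a constrained mean), so calibration checks use bursts long enough
(~3 ms median, tens of windows) for the bias to drop below the
Monte-Carlo SE, and the dynamics positive control is additionally judged
against a matched static simulation.

Titration fits use the Hill isotherm with the exponent fixed at 1,
f = [L]/(K_d + [L]), valid when the protein concentration is far below K_d.

## Synthetic data: what is and is not emulated

The photon-stream generator does **not** model diffusion. Single-molecule
transits are generated directly as bursts: Poisson arrivals (default
5 s⁻¹), log-normal durations (median 1 ms, σ_ln 0.5 — the duration
distribution is a modeling choice, exposed in the config), constant
within-burst brightness (defaults: 250 kHz donor-excitation, 180 kHz
acceptor-excitation detected rates), uniform background per stream
(defaults 1.5/0.8/1.2 kHz for DD/DA/AA). Each donor-excitation photon is
routed to the acceptor channel with probability set by the molecule's
current FRET state; states switch as a two-state CTMC started from its
stationary law. Optional α/β/γ factors (default off) give `accurate_fret`
a truth to recover; optional donor-only/acceptor-only impurity fractions
exercise the species gates. Excitation assignment is carried by the stream
label rather than the timestamp phase, and no entry/exit brightness
envelope, triplet blinking or detector dead-time is modeled — none of the
statistics in scope (burst counts, E*/S*, window ratios, titration
fractions) depend on them. Consequently, passing tests demonstrate the
correctness of the estimators under the stated statistical model, not
robustness to photophysical artifacts of real dyes.

Default state means E₁ = 0.51 / E₂ = 0.68 mirror the apparent-FRET levels
of the open and closed protein. SPR cycles are exact ODE solutions plus
Gaussian noise and optional exponential drift; titrations are binomial
counts around the isotherm; dwell samples are exponential first-passage
times right-censored at the trajectory horizon (defaults emulate 20
trajectories with a 3 µs window and ~45% censoring). Every generator
embeds its truth parameters and seed in the output metadata, and recovery
tests read truth only from there.

## Dwell-time estimation

For exponential dwells right-censored at horizon T, the MLE is
θ̂ = (Σ observed + n_cens·T)/n_obs, with a profile-likelihood CI from the
χ²₁ deficit (default 95%). With zero observed transitions the mean is
unidentified from below and the result carries an exposure-based lower
bound and a flag. Coverage at 20 trajectories and 45% censoring is ≥ 90%
in 200-replicate simulations.

## Problem sizes

Tests and the acceptance script use: 50–120 random rate sets per pathway
for the eigenvalue oracle; 20 SPR cycles across the ladder plus one
13-point SSR profile; 30–60 s photon streams (~10⁵–3×10⁵ photons, a few
hundred bursts) per smFRET condition with a ~10⁴-photon stream for the
brute-force oracle comparison; 500 bursts per titration point; 200
dwell-estimator replicates. These sizes keep every statistic's Monte-Carlo
error well inside its test tolerance.

## Known limitations

- Only the two limiting pathways are modeled; flux-partitioned parallel
  IF/CS networks and ligand-depleting kinetics are out of scope.
- The verdict logic is worst-case inequality propagation — it cannot weigh
  evidence, only exclude regions.
- The SSR-profile threshold (1.05) and grid density set the resolution of
  the k_on bound; the bound is reported to one grid step.
- The Gaussian mixture's component count is user-chosen, not selected by
  an information criterion.
- `correct_drift` presumes the dissociation tail is signal-free; traces
  with strong rebinding that still decay in the tail window bias the
  correction and should be discarded upstream, as in practice.
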