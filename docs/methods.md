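# Methods

## Model and assumptions

The package models a photocycle as a closed network of first-order reactions:
a flash prepares the initial population at t = 0⁺ (photon physics, quantum
yields and photoselection are not modelled), populations evolve as
dP/dt = Q·P with the usual rate matrix Q (columns sum to zero), and every
intermediate eventually drains into an absorbing ground state.  The measured
difference absorbance is the population-weighted superposition of per-state
difference spectra, ΔE(ν̃, t) = Σ_s P_s(t)·ΔA_s(ν̃).  Because P_s(t) of such a
network is a sum of exponentials in the negated nonzero eigenvalues of Q, any
noiseless trace lies exactly in the multi-exponential model class of the
global fit; oscillatory (complex-eigenvalue) networks are rejected as outside
that class.  Kinetics are quoted as half-lives t₁/₂ = τ·ln 2 = ln 2 / k, the
convention used when comparing FTIR, UV/VIS and electrophysiological
transition tables.

## The global fit

The objective is the weighted squared error

F = Σₙ Σₘ w(ν̃ₙ)² (ΔE(ν̃ₙ, tₘ) − [a∞(ν̃ₙ) + Σᵢ aᵢ(ν̃ₙ) e^(−kᵢ tₘ)])².

It is separable: for fixed rates, the amplitudes aᵢ(ν̃) and offsets a∞(ν̃)
solve an ordinary linear least-squares problem per channel, and because the
weight is constant along time within a channel that solution is independent of
the weights.  The fit therefore uses variable projection — an outer bounded
trust-region search over log₁₀ kᵢ only, with the thousands of linear
parameters projected out exactly at every step.  A minimizer of the projected
problem is a minimizer of F.  Choices that matter:

* **log-rate parameterization** — enforces k > 0 and equalizes curvature over
  the seven-decade dynamic range; bounds default to [1/(10·t_max), 10/t_min].
* **multi-start** (default 20, seeded) — the first start is a log-spaced rate
  ladder across the observed window, the rest are Gaussian jitters of it
  (σ = 0.5 decades); the best final objective wins.  Exponential fits have
  local minima; this is the standard mitigation.
* **convergence** — the outer optimizer's relative tolerance (default 1e−10)
  applies to cost, step and gradient; a non-converged best start is returned
  with `converged=False` rather than raised.
* **degeneracy** — rate pairs with relative gap ≤ 1e−9 make the exponential
  design rank deficient and are rejected in the exact linear solver (the
  offending pair is named); fitted rate pairs within a factor of 3 are
  reported as identifiability warnings, reflecting the practical resolution
  limit of exponential analysis.
* **offsets** — fitted by default because the objective includes them; a
  closed photocycle implies a∞ ≈ 0 and `with_offset=False` pins them.
* **weights** — the estimator behind ``inverse_noise`` takes per-channel
  second differences along time divided by √6 (a filter that annihilates
  constant and linear trends, so slow kinetics leak only weakly into the
  noise estimate) and floors the result at the 5th percentile across channels
  so quiet channels cannot dominate F.  ``uniform`` is the default: with the
  homoscedastic default generator both are equivalent, and an undefined
  weighting convention should not silently change results.  The method used
  is recorded in the result.
* **model order** — normally fixed by the experimenter; `select_order` fits
  N = 1..n_max and compares BIC = M·ln(F/M) + p·ln M with p counting the
  shared rates plus every per-channel amplitude and offset.  A dataset whose
  best order does not beat the offset-only model by BIC is flagged
  non-informative.

## The synthetic generator

The generator stands in for measurements that are not publicly deposited.
Its default FTIR model is the branched topology K → {L₁, L₁′} → L₂ → M ⇌ →
N/O → ground with branching fraction φ = 0.7 toward the fast-opening branch,
and apparent half-lives fixed to the six FTIR transition values (450 ns,
18 µs, 1.9 ms, 35 ms, 107 ms, 4.4 s).  The L₂ ⇌ M reverse edge (ratio
r = k_rev/k_fwd, default 0.3) is included by solving the 2×2 block eigenvalue
problem backwards, so the *observable* closing half-lives are independent of
r; r = 0 reduces exactly to the irreversible chain.  For the two closing
rates only ~3× apart, r is realizable up to ≈ 0.35 — stronger reversibility
cannot produce those apparent rates at all.

Species spectra are sums of Gaussian/Lorentzian bands.  Declared default
amplitudes (ΔE, with the −1.0 ground-state C=C bleach at 1529 cm⁻¹ as the
scale): +0.6 at 1184 (protonated 13-cis retinal, K through L₂, absent in M),
−0.5 at 1644 (amide I, open state; −0.25 retained in M so closing appears in
two steps), +0.35 at 1691 (conducting state only), −0.25/+0.25 at 1708/1716
(protonated-carboxylate pair from K / from L₂ on), +0.5 at 1515 (red-shifted
ethylenic product unique to K — without a K-specific band the first
transition would be spectroscopically silent, contradicting the time-resolved
measurements that resolve it), and all N/O amplitudes scaled ×0.1 (weak late
spectrum).  FWHM 8 cm⁻¹ (12 cm⁻¹ for amide I).  No state has a band at
1154 cm⁻¹: this protein shows no C=N-syn (light-adapted) species, and the
band-injection utilities exist precisely to test that detection logic.
Default grids: 1100–1800 cm⁻¹ at 2 cm⁻¹; 120 log-spaced times from 100 ns to
20 s, emulating merged step-scan + rapid-scan coverage.  The UV/VIS model
reuses the topology with the UV/VIS transition half-lives (3 µs … 3.5 s) and
generic visible bands (515 nm bleach, 390 nm M-like product); no λmax values
are claimed for this protein, so only its kinetics carry meaning.

Noise is per-cell Gaussian, homoscedastic by default, optionally per-channel
(to exercise the weights); the RNG seed is an explicit required argument and
there is no global random state.  What the generator does **not** emulate:
baseline drifts, water-vapor lines, correlated detector noise, photoselection
anisotropy, or absolute absorbance scales.  Passing tests on this generator
therefore demonstrate correctness of the estimators under the stated model,
not robustness to instrument artifacts.

## Populations and the species map

Populations are computed from the eigendecomposition of Q when its spectrum is
real and non-degenerate (relative gap ≥ 1e−9) — exact and fast for stiff rate
sets spanning seven decades — and by scaling-and-squaring `expm` otherwise.
For an irreversible scheme the closed form P_s(t) = Σᵢ X[s,i] e^(−kᵢ t) gives
an invertible exponential-to-species map; `amplitude_spectra_to_species`
solves Xᵀ·ΔA = a per channel after checking that the scheme's apparent rates
match the fitted rates within 20% and that cond(X) < 1e8.  Reversible schemes
are rejected — the map is not well posed there — and handled by the direct
scheme-level fit instead (populations × per-state spectra, spectra solved
linearly; variable projection at the scheme level).

## Topology discrimination and its hard limits

Candidate L-topologies (parallel branches; branches with slow exchange;
strictly sequential; a reduced single-L control) are fitted directly and
ranked by BIC, counting scheme rates plus all per-channel per-state spectral
values; a top-two gap below ΔBIC = 10 (the conventional "very strong
evidence" cut) is flagged indistinguishable, and candidates whose fit fails
or whose Jacobian is numerically singular are flagged unidentifiable and
ranked last rather than aborting.

Two structural facts shape what this can and cannot decide.  First, all
topologies with the same number of spectroscopically distinct states span the
same exponential model space when the per-state spectra are free parameters,
so parallel vs sequential arrangements of the L sub-states are exactly
equivalent in fit quality — the data alone cannot order them, which is why
several kinetic arrangements of the two-step opening remain admissible.
Second, against a model with fewer states the comparison is decided by the
balance between the reduced model's systematic misfit and its parsimony
credit (hundreds of spectral parameters × ln M); for the default generator
this crossover sits near a noise level of ~1% of the maximum |ΔE|, above
which BIC prefers the reduced description decisively.

## Identifiability of the noisy fit

On noiseless data the N = 6 fit recovers all six half-lives to machine
precision.  Under per-cell noise of 5% of max |ΔE|, profile-likelihood
curvature of the default generator puts the 1σ relative errors at roughly
9% (450 ns), 7% (18 µs), 18% (1.9 ms), 17% (35 ms), 6% (107 ms) and 51%
(4.4 s) — the late N/O spectrum has amplitude 0.1 against noise σ ≈ 0.05, and
the two closing rates are only 3.06× apart.  Exponential bases on log grids
are severely collinear, so these soft directions are a property of the
problem, not of the optimizer (the fitted optimum scores better than the
generator truth in F).  The noisy-recovery test asserts each component within
3× these bounds.

## Study problem sizes

The default analyses use the full 351 × 120 grid; scheme-level topology fits
and some unit tests use coarser grids (e.g. 88–176 channels, 60–100 times),
which leaves all conclusions unchanged since both the information content and
the BIC penalties scale together.

## Known limitations

No error bars on fitted rates (bootstrap/profile hooks are future work); no
joint FTIR+UV/VIS shared-rate fit (the two modalities are fitted
independently, matching their separately tabulated half-lives); no maximum-
entropy lifetime distributions; no instrument-format parsing; band shapes are
ideal Gaussian/Lorentzian profiles without baselines.
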