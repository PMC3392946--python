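# Methods

## The model

`fsneuron` implements a single-compartment conductance-based model of a
striatal fast-spiking (FS) interneuron. Charge conservation governs the
membrane potential,

    C_m dV/dt = -(I_Na + I_Kv1 + I_Kv3 + I_Ca + I_SK + I_leak) + I_app,

with positive-outward currents (nS × mV = pA):

| current | expression | role |
|---|---|---|
| I_Na | g_Na · m∞(V)³ h · (V − V_Na) | fast transient Na⁺ (spike upstroke) |
| I_Kv1 | g_Kv1 · n1⁴ · (V − V_K) | slow delayed rectifier (Kv1.3-type) |
| I_Kv3 | g_Kv3 · n3² · (V − V_K) | fast delayed rectifier (Kv3.1-type, brief APs) |
| I_SK | g_SK · k² · (V − V_K) | small-conductance Ca²⁺-activated K⁺ |
| I_Ca | g_Ca · a∞(V)² · (V − V_Ca) | high-voltage-activated Ca²⁺ (the sole Ca²⁺ source) |
| I_leak | g_leak · (V − V_leak) | passive leak |

The Na⁺ activation m and the HVA Ca²⁺ activation a are fast relative to the
other gates and are slaved to their steady-state curves (m = m∞(V),
a = a∞(V) = 1/(1 + exp((−6 − V)/7.775))). The gates h, n1, n3 follow
first-order kinetics dx/dt = αₓ(V)(1 − x) − βₓ(V)x. The SK gate k is voltage
independent and driven by shell calcium: k∞ = Ca/(K_SK + Ca) with
K_SK = k_off,sk/k_on,sk = 0.5 μM.

Free calcium in a thin submembrane shell (thickness d = 0.2 μm, area
A = 3000 μm²) obeys

    d[Ca]/dt = −I_Ca/(2 F A d) − γ([Ca] − [Ca]_rest) − d[bound]/dt,

i.e. influx through I_Ca (the conversion constant is
1/(2·F·A·d) ≈ 8.637×10⁻³ μM ms⁻¹ per pA for the default shell), first-order
clearance (γ = 1 ms⁻¹ toward 0.07 μM), and net buffer uptake. Three
buffering conditions are supported:

- **PV** — parvalbumin-like buffer with one mixed Ca²⁺/Mg²⁺ site per binding
  equivalent; Ca²⁺ and Mg²⁺ compete by mass action and [Mg²⁺] is held fixed
  at 500 μM. Derived affinities: K_D,Ca = 0.01 μM, K_D,Mg = 31.25 μM (the
  rate pair is primary; tabulated affinities round the latter to 31 μM).
- **slow** — single Ca²⁺ site with EGTA-like kinetics (k_on = 0.01 μM⁻¹ms⁻¹,
  K_D = 0.1 μM).
- **fast** — single Ca²⁺ site with BAPTA-like / metal-free-PV kinetics
  (k_on = 0.1 μM⁻¹ms⁻¹, K_D = 0.01 μM).

Only the Ca²⁺-bound flux enters the calcium balance; Mg²⁺ binding acts by
occupying PV sites (it is what makes PV kinetically "slow": Ca²⁺ binding
must wait for Mg²⁺ unbinding).

## Gate-rate coefficients as data

The α/β rate functions for h, n1, n3 (and m) are not part of the code: they
ship in `src/fsneuron/data/gate_rates.yaml` as parameterised templates
(linoid, exponential, sigmoid, constant) with coefficients and a source
citation, and custom files with the same schema can be substituted. The
shipped file transcribes the Erisir et al. (1999) fast-spiking interneuron
kinetics as used by Mancilla et al. (2007). Because that transcription is
an external input with real uncertainty (published rate sets of this model
family differ in temperature factors), it was validated against the
reference behaviour of the striatal FS model: the resting state, the Hopf
current of the equilibrium branch (≈44 pA), and the firing rates of the
100 pA step protocols (≈39 Hz unbuffered, ≈30 Hz at 1500 μM PV). That
validation fixed a single ×2 kinetic factor on the Na-inactivation (h)
rates — the standard Q10-style compensation for kinetics fitted at room
temperature — which is baked into the shipped file and noted there. No
other coefficient was adjusted.

Linoid templates have a removable singularity at V_half; it is resolved
analytically (limit C·s) inside a guard band of 10⁻⁷ mV.

## SK gating time constant

The relaxation time of the two-state SK binding scheme is implemented in
mass-action form, τ_k = 1/(k_on,sk·Ca + k_off,sk); a dimensionally literal
alternative τ_k = 1/(K_SK + Ca), with the result read in ms, is available
via `ModelParameters(literal_tau_k=True)` (it changes the step-protocol
frequencies by well under 1 Hz). With the default rates
(k_on,sk = 0.4 μM⁻¹ms⁻¹, k_off,sk = 0.2 ms⁻¹) τ_k stays below 5 ms, so the
SK gate tracks calcium closely within an interspike interval. A consequence
worth stating plainly: at a plateau interspike calcium of ~0.1 μM this
parameterisation bounds the interspike SK current to a few pA, and the
package's measured interspike I_SK levels (see the acceptance outputs) are
correspondingly low at low buffer concentration. Slower SK variants (10× or
1000× slower rate pairs with the same K_SK) were explored and rejected
because they weaken or invert the model's central monotone
frequency-vs-buffer effect.

## Numerics

- **Integrator** — classic fixed-step RK4 (numba-compiled), default
  dt = 0.01 ms, recording stride 5 (50 μs sampling; resolves the ~0.5 ms
  spikes while keeping 5 s runs compact). Halving dt changes the spike
  count of the reference run by 0 and every spike time by < 0.1 ms (tested);
  a 200 ms window agrees with an adaptive DOP853 reference solve at
  rtol 10⁻¹⁰ to < 0.5 mV. Runs are bitwise reproducible; the model has no
  stochastic elements.
- **Burn-in** — every protocol is preceded by a 4 s stimulus-free
  integration (configurable, including the holding current) starting from
  V = −70 mV with gates at steady state, Ca at rest and buffer pools at
  competitive equilibrium with (Ca_rest, Mg_i).
- **Equilibria** — damped Newton on the reduced state (inert slots
  excluded), central finite-difference Jacobian (relative step 10⁻⁶ with an
  absolute floor), eigenvalues via `numpy.linalg.eigvals`. Cold starts use
  an exact 1-D reduction: at equilibrium all gates sit on their steady-state
  curves and shell Ca at its explicit fixed point, so equilibria are roots
  of a scalar current balance in V (bracketed and polished by Newton).
- **Hopf point** — warm-started walk along the branch brackets the first
  stability flip; bisection to 0.1 pA; the critical eigenvalue pair is
  asserted complex.
- **Oscillation onset (SNLC estimate)** — bisection on I_app of the
  criterion "≥2 spikes in the final 1 s of a 6 s integration", run from a
  spiking state inherited from the top of the range (and, separately, from
  rest, to bracket hysteresis). Periodic-orbit continuation with Floquet
  analysis was deliberately not implemented; near onset this model shows
  mixed-mode behaviour (occasional full spikes between subthreshold
  oscillations), so the simulation-based onset sits below a fold located on
  the periodic branch and the onset frequency climbs through low values
  rather than jumping discontinuously.
- **Spike detection** — upward crossings of 0 mV, linearly interpolated,
  1 ms refractory guard. Mean frequency = spikes in window ÷ window
  duration (an `isi` variant is available).
- **Interspike statistics** — Ca extrema over the open interval between
  spike times; I_SK statistics over the subthreshold segment from the AHP
  trough to the next spike (the spike itself, where the driving force is
  maximal, is excluded). Plateau statistics use the fixed 4000–5000 ms
  window of the stimulus by default; a data-driven plateau detector
  (earliest interval from which the lower envelope changes < 1% per
  interval) is also provided.

## Default parameters

Passive: C_m = 30 pF, g_leak = 2.5 nS (input resistance 400 MΩ),
V_leak = −68 mV; the model rests at −67.9 mV (slightly above V_leak because
of a small Na⁺/Ca²⁺ window current; the biological reference value is about
−70 mV). Conductances (nS): g_Na 700, g_Kv1 2, g_Kv3 300, g_SK 2, g_Ca 30.
Reversals (mV): V_Na 74, V_K −90, V_Ca 80. Calcium: γ = 1 ms⁻¹,
Ca_rest = 0.07 μM, Mg_i = 500 μM, shell 0.2 μm × 3000 μm².

## Known limitations

- Single compartment; no Ca²⁺ diffusion, no nano/microdomain geometry, no
  mobile-vs-immobile buffer competition, no BK channels, no channel noise.
- The bifurcation tooling characterises the equilibrium branch and the
  onset of sustained spiking; it does not continue periodic orbits, so the
  unstable cycle branch between the Hopf and the onset is inferred, not
  computed.
- Quantities that depend on the transcribed gate kinetics inherit that
  transcription's uncertainty; the data file is versioned so alternative
  transcriptions can be swapped in and re-validated.
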