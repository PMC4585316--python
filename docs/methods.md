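# Methods

## Model overview

`strandcv` simulates action-potential propagation in thin cultured strands
of cardiomyocytes as a discrete resistor network. Every node of a regular
grid (default spacing h = 5 μm) carries full Luo–Rudy phase-I (LR1)
membrane dynamics — fast Na⁺ current, slow inward (Ca²⁺) current,
time-dependent and inward-rectifier K⁺ currents, plateau and background
currents, six Hodgkin–Huxley gates and intracellular Ca²⁺ — and exchanges
current with its four neighbors through ohmic edge conductances. Membrane
capacitance is 1 μF/cm² with a membrane area of h² per node, appropriate
for a monolayer whose upper surface is the dominant membrane.

The strand (default 3000 × 150 μm) is tessellated into elongated cells by
a jittered brick-wall construction: rows of height ≈ 15 μm whose cells have
lengths drawn around 100 μm (coefficient of variation = `jitter`, default
0.3), with staggered longitudinal boundaries between rows. Every cell is a
four-connected region, the tessellation covers the strand exactly, and the
construction is bit-reproducible from (parameters, seed). In the
jitter-free limit it degenerates to a regular lattice of identical
rectangles. Cell types are assigned per cell (the biological unit that is
mixed at seeding): SCM with probability p_SCM, then low-excitability (LE)
vs high-excitability (HE) with a 2:1 default ratio.

### Cell types

One ionic model is shared by all cell types; they differ only in the
maximal Na⁺ conductance:

| type   | gNa_max (mS/cm²) | role |
|--------|------------------|------|
| PCM    | 13.5             | primary (fetal ventricular) myocyte |
| LE_SCM | 4.5              | low-excitability stem-cell-derived myocyte |
| HE_SCM | 11.5             | high-excitability stem-cell-derived myocyte |

The remaining shared factors rescale the LR1 slow-inward conductance
(×0.8), its gate kinetics (×1.0) and the time-dependent K⁺ conductance
(×10). They were selected by the shipped grid search
(`scripts/calibrate_celltypes.py`) under two constraints: the isolated-cell
upstroke velocities of the SCM types must fall inside the measured bands
(LE 107 ± 13 V/s, HE 230 ± 20 V/s — the gNa values above land at ≈ 99 and
≈ 230 V/s with near-threshold 3-ms stimuli), and the action potential must
be short enough for reliable 1:1 capture at a 300-ms cycle length
(APD90 ≈ 100 ms for all three types). Upstroke velocities are measured on
the derivative of the initial 20 ms of the last beat with the stimulus
interval masked, mirroring just-above-threshold current-clamp pacing.

### Coupling

Edges inside a cell carry the myoplasmic conductance `intra_g`; edges
crossing a cell boundary carry `g_ref × relative_factor(type A, type B)`.
Baseline relative factors are 1 (PCM–PCM), 0.0385 (LE–LE), 0.0205 (HE–HE),
with heterocellular pairs taking the minimum of the two homocellular levels
(each cell contributes one hemichannel, so the weaker expressor limits the
junction). The "enhanced heterocellular coupling" paradigm raises PCM–SCM
entries fourfold (0.1538, 0.0821) and LE–HE to the LE level (0.0385).

Two conductances are calibrated against the two anchor observations of the
control experiments rather than chosen freely:

* `g_ref` (reference junctional conductance per node interface) is
  bisected until all-PCM strands conduct at 34.9 cm/s — the mean control
  CV. This lands near 0.05 μS per 5-μm interface.
* `intra_g` (myoplasmic sheet conductance, σ·thickness of the thin
  monolayer) is fixed at 0.57 μS — equivalent to ~1–2 μm effective cell
  thickness at 150–300 Ω·cm cytoplasmic resistivity — so that pure LE-SCM
  strands at relative coupling 0.0385 conduct near the 5.6 cm/s measured
  in pure-SCM cultures. At this operating point ~80 % of axial resistance
  is junctional; much higher `intra_g` sends the model into a deeply
  discontinuous regime where the 0.0385 scenario blocks decrementally,
  much lower values make it continuum-like and too fast.

The spatial unit convention: an edge conductance g (μS) contributes a
voltage-relaxation rate g·10⁵/h² per ms (Cm = 1 μF/cm², node area h² in
μm²). The myoplasmic sheet conductance of a square tile is independent of
h; junctional conductance is defined per unit interface length, so the
per-edge junctional value scales with h. Both conventions are exercised by
the spatial-refinement test.

## Numerics

Operator splitting per time step (default dt = 0.005 ms):

1. **Membrane** — explicit: Rush–Larsen exponential updates for the six
   gates using per-cell-type lookup tables over V ∈ [−110, 80] mV in
   0.05-mV steps (gate steady states, exp(−dt/τ), the K⁺ rectification
   factor and the gate-free current sum), forward Euler for V and [Ca]ᵢ.
2. **Coupling** — implicit backward Euler, factorized once: the 2D
   operator is split into per-row and per-column tridiagonal systems
   solved exactly by a prefactored Thomas algorithm.

The implicit coupling step is unconditionally stable, which matters
because at h = 5 μm the explicit diffusion stability limit (dt ≈ h²/4D ≈
10⁻⁴ ms at physiological conductances) would be ~50× below the membrane
step. The splitting conserves total charge exactly in the passive limit
(verified to machine precision) and the refinement tests show < 3 % CV
change when dt or h is halved.

Stimulation injects 100 μA/cm² for 2 ms into the leftmost 100 μm. The
analyzed beat starts from the LR1 resting steady state; with APD90 ≈
100 ms ≪ CL 300 ms the gates fully recover in diastole, and a beat
conditioned by a previous CL-300 beat yields the same CV within 1 %
(tested), so single-beat runs are the desk-scale default while multi-beat
trains remain available. A beat ends early once every column up to 92 % of
strand length contains an activated node (1-ms settle margin); per-node
earliest activation time (EAT) is the time of maximal dV/dt, a node counts
as activated above 10 V/s, and a strand is blocked when no node in the
distal 10 % activates within the beat window (150 ms cap).

CV is the inverse slope of the ordinary least-squares regression of the
per-column earliest activation time against x, restricted to 25–75 % of
strand length to exclude stimulation and boundary artifacts
(cv [cm/s] = 0.1 / slope [ms/μm]).

### Refractoriness and its limits

The descending cycle-length ramp decrements CL beat-to-beat by
`ramp_rate·CL/60000` and reports the ERP as the interpulse interval
between the last two propagated beats before the first distal failure.
Distal "success" uses a 30 V/s threshold: premature stimuli in the
relative refractory period evoke ~10 V/s graded responses that must not
count as propagated beats. A known limitation: the LR1 time-dependent K⁺
current produces strong APD rate adaptation, so during a ramp the tissue
keeps capturing far below the slow-rate APD90 (ramp ERP ≈ 35–50 ms for
APD90 ≈ 160–190 ms calibrations, lower still for the default short-AP
calibration). The experimentally observed combination of CL-300 pacing
with ERP ≈ 120–140 ms is therefore not reachable within this ionic model;
ramp machinery is validated by ordering and definition tests instead.

## Synthetic data generators

**Electrograms.** The MEA generator places a biphasic deflection
(difference of two Gaussians ~2 ms wide, steepest downstroke exactly at
the nominal activation time) at each of 12 electrodes (0.5 mm spacing) at
stimulus time + 6 ms latency + cumulative per-segment delays derived from
a controllable true CV, with optional per-segment delay multipliers,
per-electrode timing jitter, additive Gaussian noise, and an optional
refractory cutoff that suppresses beats for ramp emulation. It emulates
timing structure, not electrogram morphology — waveform shape, field
effects, electrode drift and stimulus artifacts of real recordings are
not modeled, so detector tests certify timing recovery (exact when clean;
RMS error ≤ 1 sample at SNR 20), not morphology robustness.

**Micrographs.** The image generator stamps randomly oriented elliptical
bright patches (per-pixel speckle, tight cell-to-cell brightness) on a
background with a camera black level (0.3) plus rare saturated debris
specks, until a target bright-area fraction is reached; the truth mask is
stored. The specks anchor the min–max normalization the way stray debris
does in real GFP-free fields, making an empty field read ≈ 0.1 % bright.
The quantification pipeline is faithful (MAE ≈ 0.01) for bright fractions
up to ~0.5. Above that the printed rescale rules saturate by
construction — no pixel can exceed 3× the mean when the mean exceeds 1/3,
and the below-median cut removes half of a bright-dominated field — so raw
readings undercount at high fractions. This mirrors the real measurements
(pure-SCM preparations read ~77 %, not 100 %) and is exactly why measured
fluorescence levels are renormalized against pure-PCM and pure-SCM
references; the renormalization operation with first-order error
propagation is part of the package.

## Statistics

CV(p_SCM) is fitted by OLS with linear and quadratic polynomials
(statsmodels, classical t-based 95 % CIs, homoscedastic errors — matching
the original analysis). The quadratic relationship counts as non-linear
when zero lies outside the 95 % CI of a₂. Coverage of the a₂ interval
under a linear truth is verified at ≥ 94 % over 1000 simulations. CVarCT
uses the population-SD convention (SD/mean of successive inter-electrode
conduction times), averaged over steady-state beats.

## Problem sizes used in the shipped checks

The test suite runs most solver properties on reduced strands
(600–1000 μm × 30–60 μm) with the same node spacing and cell statistics;
the end-to-end reproduction tests and `scripts/acceptance.py` use
full-size 3000 × 150 μm strands with 5 random realizations per scenario
and p-steps of 0.2 for the sweep columns. These counts are the package's
desk-scale defaults; `realizations=20` with p-step 0.1 reproduces the
full campaign in an overnight run via `strandcv table3`.

## Known limitations

* The cellular architecture is a surrogate: jittered brick-wall cells with
  per-edge-uniform junctional coupling along entire interfaces. Its PCM
  pathways percolate somewhat more effectively than real strand
  architecture appears to; interior mixture points (p_SCM = 1/3, 2/3) run
  ~20 % faster than the reference values and the CV(p) curvature is
  correspondingly smaller.
* LR1 is a guinea-pig ventricular formulation pressed into service for
  murine immature myocytes; rate adaptation (above) and AP morphology are
  approximate.
* The extracellular potential is not modeled; electrogram analysis applies
  to synthetic or imported recordings only.
* Pure-HE strands at relative coupling 0.0205 conduct ~10 % faster than
  the 5.6 cm/s anchor (the LE anchor, used for calibration, matches).
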