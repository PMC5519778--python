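# Methods

## Model and assumptions

The arterial tree is treated as a linear, time-invariant network of lossy
transmission lines. That buys an exact steady-state periodic solution — each
harmonic of the inflow is propagated independently and superposed — at the
price of the usual linearization assumptions: small-amplitude waves around a
mean state, rigid-enough geometry that radii do not vary over the cycle, no
convective acceleration, and reflection/transmission governed entirely by
impedance mismatch. There is no transient: the frequency-domain solution *is*
the periodic steady state, so no settling beats are simulated and no
detrending is ever needed.

Per segment, the Moens-Korteweg speed c₀ = √(Eh/ρD) sets the elastic scale,
and Womersley's F₁₀(α) corrects both the characteristic impedance Z₀ and the
propagation constant γ for the oscillatory viscous velocity profile. The two
`(1−σ²)` factors enter with opposite exponents in Z₀ and γ; with the default
σ = 0.5 the high-frequency phase velocity is c₀/√0.75 ≈ 1.155·c₀, which is why
foot-to-foot PWV readings systematically exceed the Moens-Korteweg path value.
The wall loss angle φ (default 0, purely elastic) may be a constant or a
callable φ(ω).

DC (ω = 0) is singular in the Womersley expressions, so harmonic 0 runs on a
dedicated resistive skeleton: Poiseuille resistance 8μl/πr⁴ per segment in
series, R₁+R₀ at the leaves, parallel at junctions. Mean pressures therefore
obey the Poiseuille gradient and the root mean pressure is exactly
mean flow × DC input impedance.

F₁₀ is evaluated with exponentially scaled complex Bessel functions
(`scipy.special.jve`); the scaling cancels in the ratio 2J₁(z)/(zJ₀(z)), so a
single branch is exact at machine precision for every Womersley number — no
asymptotic switchover is needed.

The pressure transfer function of a terminated segment is implemented in the
canonical form (1+Γ)/(e^{γl} + Γe^{−γl}); the simplified variant without Γ in
the backward term is available behind `as_printed=True` for comparison with
older write-ups.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| ρ (blood density) | 1.05 | g/cm³ | standard value |
| μ → ν (viscosity) | 0.04 P → 0.0381 | cm²/s | standard blood viscosity |
| σ (wall Poisson ratio) | 0.5 | – | incompressible wall; sets the 1.155 phase-velocity factor |
| φ (wall loss angle) | 0 | rad | purely elastic wall; configurable |
| E classes | 4 / 8 / 16 ×10⁵ | Pa | aorta+central, medium muscular, peripheral |
| HR / LVET / mean flow | 70 / 0.3 / 70 | bpm / s / ml·s⁻¹ | standard resting state |
| fs | 1000 | Hz | sub-ms foot timing needs ≥1 kHz; parabolic refinement decouples results from fs |
| Σ terminal Cp | 1.0e-8 | m⁵/Pa | gives a uniform bed decay time R₀Cp ≈ 1.6 s |

## The reference tree and what it does (not) pin down

The 55-segment table is assembled, not measured: lengths, mean radii and wall
thicknesses follow the classical 55-segment systemic tree of the 1-D
modelling literature (tapered vessels are represented by their mean radius);
elastic moduli are grouped into the three classes above, with the
subclavian–brachial trunks kept in the low-modulus central class as in the
classical multibranched tables. Terminal loads are derived: total terminal
resistance is split across the 28 beds in inverse proportion to r³, R₁ is
matched to each terminal vessel's characteristic impedance (minimizing
spurious high-frequency terminal reflection), R₀ takes the remainder, and
compliances are split in proportion to flow so every bed shares the same
decay time. The single free total is calibrated so the DC input impedance of
the whole tree equals the textbook total peripheral resistance 1.6×10⁸
Pa·s·m⁻⁵. `scripts/build_reference_tree.py` regenerates the CSV.

Consequences worth knowing: absolute pressures and PWVs are only as good as
this assembly (the package's own tests grant them a ±10 % band); compressing
a tapered vessel into one uniform segment concentrates distributed reflection
into junction steps, which inflates peripheral systolic amplification at the
elbow and damps it at the ankle — systolic pressure amplifies robustly from
aorta to femoral/brachial, but does not keep rising all the way to the ankle
in this fixture, and the ankle-brachial index comes out near 0.82 rather
than closer to 0.9.

## The inflow source

The source is a prescribed periodic flow at the ascending aorta (no
ventricular coupling). A template shape is time-scaled so its systolic part
spans exactly LVET and its diastolic part the rest of the period, then
amplitude-normalized so the period mean matches the requested mean flow
exactly (invariant to fs and to periodic extension). Two templates ship: the
default half-sine ejection (zero diastolic flow, analytically convenient:
peak = mean·T·π/2LVET), and a synthetic "typical" aortic shape (fast early
acceleration, rounded peak in the first third of systole, brief end-systolic
backflow) drawn to resemble published aortic flow traces, not digitized from
any specific recording. Upstroke-sensitive quantities — maximum-slope feet,
forward/backward timing, the small HR/LVET/Rp dependencies of PWV — are
template-dependent; both templates are exposed precisely so this sensitivity
can be probed.

## Feature extraction

Foot detection works cyclically on one period. The derivative (central
differences) is maximized — earliest sample wins ties — and refined by a
parabolic fit through the three samples around the peak; the intersecting
tangent through that point meets the horizontal through the preceding
diastolic minimum (searched over the half period before the upstroke; the
minimum value is used unrefined, since the sub-sample correction to a
quadratic minimum's value is second order). Both foot estimators are
translation-equivariant and amplitude-invariant by construction; transit
times are wrapped into one period and rejected if they exceed ¾ of it.

Wave separation uses the clinical scalar convention
Pf = (ΔP + Z_c·ΔQ)/2 + P̄, Pb = (ΔP − Z_c·ΔQ)/2 with Z_c estimated as the mean
input-impedance modulus over harmonics 4–10 (configurable band). The
reflected-wave transit time is the tangent-foot delay of Pb behind Pf, and
the effective reflection distance is PWV·RWTT/2 (round trip halved), taking
the carotid-femoral tangent PWV of the same run as the travel speed. Note a
known convention sensitivity: the backward wave in a distributed tree rises
gradually, so its tangent foot lands tens of milliseconds before its
maximum-slope instant; analyses that time the backward wave by its steepest
rise will report correspondingly longer transit times and reflection
distances than this package's default.

## Numerical choices

Frequency grid: harmonics of f₀ = fs/n for an n-sample period (exactly the
`rfft` grid), evaluated up to Nyquist; conjugate symmetry is enforced by the
one-sided transform, so synthesized waveforms are exactly real and
T-periodic. Geometry is converted cm→m centrally; 1 mmHg = 133.322 Pa.
Tree tables round-trip bit-exactly (shortest-repr floats on write,
`float_precision="round_trip"` on read). Degenerate inputs fail loudly:
empty tables, duplicate ids, orphan segments, leaves without loads,
non-positive dimensions, ω = 0 in the AC path, flat waveforms in foot
detection, vanishing line denominators (reported with the segment id).

## Sweep studies

Presets mirror the three in-silico studies plus the compliance sweep:
stiffness 50–150 % (step 10 %), HR 60–100 bpm (step 10, LVET tied to HR by
the regression LVET = −0.0017·HR + 0.413), LVET 0.10–0.45 s at 70 bpm,
peripheral resistance 50–150 % (R₁ and R₀ together, Cp fixed), compliance
50–150 %. The 10 % grid step makes the "per 0.1 of default" reporting unit
natural. Dependencies are reported as mean ± SD of successive-difference
slopes rescaled to the reporting unit — the only reading that yields an SD
from a deterministic sweep — and Pearson p-values use the t distribution
with n−2 df on the grid size, which is descriptive, not inferential. The
whole pipeline is deterministic; a sweep config accepts a seed only for
completeness.

## Known limitations

- Elastic moduli are frequency-independent; wall viscoelasticity enters only
  through the optional loss angle φ. Quantities that hinge on dynamic wall
  behaviour (e.g. HR dependencies of PWV) are therefore muted.
- The small HR/LVET/peripheral-resistance dependencies of timing-based PWV
  are sub-millisecond foot-morphology effects; their sign depends on how
  reflections overlap the upstroke at each site and hence on the exact
  segment table and inflow template. Treat the magnitudes, not the signs, as
  robust outputs of this fixture.
- The R0-only invariance of PWV is approximate: R₀ couples into the lowest
  harmonics whenever ωR₀Cp is finite (≈12 at the fundamental here), so PWVs
  shift by a few hundredths of m/s over a ±50 % R₀ sweep.
- One uniform segment per tapered vessel; no anatomical variants, no
  ventricular coupling, no nonlinear or time-domain solver.
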