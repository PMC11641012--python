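# Methods

## Tether mechanics

The tether is treated as three mechanical elements in series; total
extension at force F is the sum of the segment extensions plus the rigid
offsets.

* **dsDNA handles** — extensible worm-like chain with persistence length
  p, contour length L_c and stretch modulus K. The relation is implicit
  in F (the enthalpic term F/K enters the fractional extension), so
  force-at-extension is found by bracketed root solving; extension-at-
  force is closed-form: substituting u = 1 − l into the Marko–Siggia
  backbone gives the cubic 4u³ + (4f − 3)u² − 1 = 0 (f = F·p/k_BT),
  whose unique root in (0, 1] is evaluated by Cardano's formula (the
  trigonometric branch where three real roots exist) plus two Newton
  polishing steps. Equivalence with an independent bisection of the
  implicit equation is asserted in the tests (< 0.1 nm over 0.1–60 pN;
  in practice ~1e−11 nm).
* **ssDNA** — interpolated Marko–Siggia chain with p_ss = 2 nm; its
  inversion is the same cubic, exact.
* **Folded elements** — force-independent end-to-end offsets: 2 nm per
  folded hairpin, 10.5 nm for the assembled synaptic complex (from the
  integrase–hairpin crystal structure). No compliance is attributed to
  folded structures.

Contour-length bookkeeping uses 0.68 nm/nt (ssDNA) and 0.34 nm/bp
(dsDNA). The canonical construct (5 kbp of handles, a 114-nt spacer, two
63-nt hairpins) yields the state set

| state | ssDNA contour (nm) | offsets (nm) | coordinate (nm) |
|---|---|---|---|
| synapse | 0 | 10.5 | 10.5 |
| substate | 51.1 | 2 + 2 | 55.1 |
| hairpin_bound | 77.5 | 2 + 2 | 81.5 |
| unfolded | 163.2 | 0 | 163.2 |

so disassembly changes the contour coordinate by 71 nm (the fingerprint)
and full unfolding by a further ~82 nm. The substate ssDNA contour is
derived from the measured ΔL₁₋sub = 44.6 nm rather than from structure;
it is a configuration knob. The 63-nt default hairpin size is chosen so
two hairpins reproduce the ~82-nm unfolding signature; exact per-hairpin
nucleotide counts are user-supplied for other constructs.

### Defaults and units

| parameter | default | unit | rationale |
|---|---|---|---|
| k_BT | 4.11 | pN·nm | room temperature (~298 K), configurable |
| p (dsDNA) | 45 | nm | standard dsDNA in physiological buffer |
| K (dsDNA) | 1200 | pN | standard enthalpic stiffness |
| p_ss (ssDNA) | 2 | nm | established ssDNA value for this assay |
| L_c handles | 1700 | nm | 2 × 2.5 kbp × 0.34 nm/bp |

The handle persistence length and stretch modulus are textbook dsDNA
values exposed in the configuration; the assay they emulate reports
segment lengths but not fitted elastic constants.

## Rupture detection and classification

Raw records are block-mean downsampled (the nominal 78-kHz acquisition
divided by 300 gives the 260-Hz analysis rate) and corrected for trap
cross-talk with a single linear coefficient per trace. Cycles are split
at smoothed-extension turning points; cycles that never reach 30 pN
cannot guarantee full hairpin unfolding and are flagged and excluded
from event statistics (but retained in the tables).

Rupture events are force drops ≥ 1 pN within ≤ 5 samples. With a
usable extension channel (`min_jump_nm > 0`, default 2 nm) each
single-sample extension jump coinciding with such a drop is one event,
which keeps transitions on adjacent samples separable; with
`min_jump_nm = 0` detection falls back to drops of the 5-sample-smoothed
force, and candidates within the window merge. The event force is the
mean of the last ≤ 3 unsmoothed samples before the drop — averaging
suppresses the upward bias that taking a raw noisy maximum would add
(~ +0.35 pN at the default 0.3-pN noise).

Inter-event segments are assigned the candidate state whose hybrid-WLC
curve minimises the RMS extension residual over samples above 2 pN
(below that, the curves converge and noise dominates). Ties break toward
the earlier state in the disassembly order synapse → substate →
hairpin-bound → unfolded, making the classifier conservative about extra
transitions; segments with residuals above 15 nm are `unknown`. Each
assignable segment is then re-fitted with a free ssDNA contour length
(offsets fixed to the assigned state); segments too short to constrain a
fit (< 5 points or < 2 pN of force span) fall back to the assigned
state's nominal contour.

Categories: **iii** — first segment is the synapse and the first
hairpin-bound segment is reached in one step; **ii** — reached through
≥ 1 intermediate segment; both require the contour change between the
fitted synapse segment and the fitted hairpin-bound segment to match the
fingerprint within ±10 nm (≈ 2.5 × the 3.9-nm substate SD; the design
value itself has no published acceptance window). Measuring the
cumulative change between those two long segments, rather than summing
per-event changes, keeps short-lived intermediates from blocking the
check. **i** — first segment is hairpin-bound and a rupture at ≥ 6 pN
exists (the threshold separating integrase unbinding from free hairpin
unfolding at 5.7 pN); otherwise **none**. `F_diss` is the force of the
first event of ii/iii cycles, `F_unbind` the first ≥ 6 pN rupture of i
cycles. Dissipated work up to an event is the trapezoidal ∫F dx along
the pull.

## Synthetic data

The generator emulates the quasi-static limit of a dual-trap pulling
experiment: trap separation advances at 250 nm/s, and at each sample the
force solves the balance between the trap spring (0.45 pN/nm effective)
and the hybrid WLC of the current state (grid-interpolated initial
guess, three Newton steps with the analytic compliance, machine-
precision residual — noiseless samples lie exactly on the state curves).
Rupture forces are drawn from the Bell–Evans ramp distribution by
inverse transform,

    F = (k_BT/Δx) · ln( exp(F₀Δx/k_BT) − (rΔx/(k₀k_BT)) · ln U ),

conditioned on the entry force F₀ of the segment (the hazard process is
memoryless), with the loading rate r = v·(1/k_trap + dx/dF)⁻¹ treated as
locally constant and evaluated at a 10-pN reference. Pathway categories
are drawn per cycle from a configurable mix (default 0.5/0.3/0.2 for
iii/ii/i, within the observed ranges of the assay). Substate exit is
modelled as its own Bell bond — the same mechanism as every other
transition — rather than as a force-independent dwell clock, so the
intermediate survives a force interval rather than a fixed time.
Gaussian noise (SD 0.3 pN, the post-downsampling scale) is added to the
force channel only; traces are emitted directly at the 260-Hz analysis
rate. Every stochastic quantity derives from a per-cycle stream
spawned as `SeedSequence(seed, spawn_key=(cycle_id,))`, so any cycle is
reproducible in isolation. (Tuple-entropy seeding such as
`SeedSequence((seed, cycle_id))` is avoided deliberately: streams built
that way share a leading entropy word and showed strong cross-cycle
correlations.)

Bond presets (k₀, Δx): disassembly (0.022 /s, 2 nm), substate exit
(0.05 /s, 2 nm), unbinding+unfolding (0.014 /s, 2 nm), free unfolding
(0.64 /s, 2 nm). These are calibrated so the demonstration medians sit
near the characteristic forces of the assay (≈ 12.7, ≈ 13.4 and
≈ 5.7 pN respectively at the ~30 pN/s default loading rate); they are
demonstration values, not kinetic parameters inferred from published
force distributions — no such inference is attempted.

What the generator does **not** emulate: bead Brownian dynamics and the
coloured force-noise spectrum of a real instrument, extension-channel
noise, hairpin refolding during relaxation, drift, multiple tethers, or
any coupling between pathway category and disassembly force. Passing the
closure tests therefore shows that the pipeline correctly inverts the
stated mechanical and kinetic model at realistic noise amplitudes — not
that it is robust to every instrumental artefact of real data. In
particular the single-sample extension-jump detector exploits the clean
extension channel; for noisy piezo data, set `min_jump_nm = 0` to use
the smoothed force-drop detector alone.

EMSA series apply the Hill–Langmuir curve with exponent 4 and
multiplicative Gaussian noise on each band intensity; CFU counts are
binomial per replicate.

## Statistics

The Hill exponent is fixed at 4 (four integrase subunits assemble the
complex) and exposed for sensitivity checks; c₁/₂ and b_max standard
errors come from the fit covariance. Pairwise comparisons use Welch
(unequal-variance) t tests — the variance assumption is otherwise
unstated — adjusted by a hand-rolled Holm step-down (cross-checked
against statsmodels in the tests) and gated as post-hoc evidence on
ANOVA p < 0.05; Kruskal–Wallis accompanies them for non-normal samples,
with identical-value degeneracy reported as H = 0, p = 1. The
limit-of-detection rule returns 1/Σ recipients with an undefined SD when
no recombinants are observed; LOD-flagged conditions are excluded from
the Pearson stability–efficiency correlation by default (they carry only
an upper bound). The correlation uses log₁₀ efficiency because
recombination frequencies span orders of magnitude; "relative
efficiency" normalisation is left to the caller.

## Numerical and design notes

* Cardano roots are polished with two Newton steps; all inversions
  round-trip to < 1e−6 pN (tested).
* The force-drop threshold (1 pN), detector window (5 samples),
  smoothing window (5 samples), residual threshold (15 nm), minimum
  dwell (1 sample) and fingerprint tolerance (±10 nm) are detector
  defaults chosen for the 260-Hz, 0.3-pN-noise regime; all are exposed
  in `RunConfig`.
* Whether the event force should be a downsampled local maximum or a
  fitted peak is an open choice in the assay description; the local
  pre-drop mean is used here, and the per-event force error is assessed
  by its median against the noise amplitude.
* Problem sizes in the validation runs — 200 cycles for the closure
  check, 100 titration replicates for the noisy Hill recovery, 1000
  null replicates for the type-I-error check — were chosen as the
  smallest ensembles whose binomial/order-statistic intervals are
  meaningfully narrower than the tolerances being checked.

## Known limitations

* No freely-jointed-chain or twistable WLC variants, no temperature-
  dependent persistence length, no sequence-dependent elasticity.
* No hidden-Markov or Bayesian step detection; no force-clamp analysis;
  no trap calibration or bead-image processing (stiffness is an input).
* Gel densitometry is out of scope: EMSA band intensities are inputs.
* Category-ii substate structure is phenomenological (a single
  intermediate at the configured ΔL₁₋sub); ensembles of short-lived
  states are detected as events but not modelled kinetically.
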