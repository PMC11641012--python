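# synaptrap

Force-spectroscopy analysis of integron synaptic-complex stability.

Integron integrases (IntI1) capture and excise gene cassettes by
recombining folded *attC* DNA hairpins. The reactive intermediate is the
*synaptic complex*: four integrase subunits bridging two *attC* hairpins.
Its mechanical stability can be probed with dual-trap optical tweezers by
pulling on a hybrid ssDNA/dsDNA tether carrying both hairpins: complex
rupture appears as a force drop with a designed contour-length change of
71 nm, the *molecular fingerprint* of disassembly. `synaptrap` implements
the complete analysis for such experiments — and a matching synthetic-data
generator with known ground truth — for single-molecule biophysicists who
want a tested, reusable version of the pipeline.

## What it computes

**Polymer mechanics** (`synaptrap.polymer`). The tether is modelled as a
series of an extensible worm-like chain (dsDNA handles), an interpolated
Marko–Siggia worm-like chain (ssDNA), and rigid offsets for folded
elements (2 nm per hairpin, 10.5 nm for the assembled synapse). Both
chains share the entropic backbone

    F = (k_B T / p) · [ 1/(4(1 − l)²) − 1/4 + l ],

with fractional extension `l = x/L` for ssDNA and `l = x/L_c − F/K` for
dsDNA with stretch modulus `K`. The extension-at-force inversion is the
closed-form Cardano root of the underlying cubic; force-at-extension for
the implicit extensible chain is solved numerically, and the two routes
agree to < 1e−10 nm. Contour-length arithmetic reproduces the designed
fingerprint: 114 nt × 0.68 nm/nt + 2 × 2 nm = 81.5 nm end-to-end in the
hairpin-bound state, minus the 10.5-nm synapse offset = 71 nm.

**FEC pipeline** (`synaptrap.pipeline`). Block-mean downsampling (78 kHz
/ 300 → 260 Hz), linear trap cross-talk correction, pull/relax cycle
segmentation (cycles must reach 30 pN), rupture detection (force drops
corroborated by extension jumps), hybrid-WLC state assignment and
contour-length fingerprinting, and per-cycle classification:

* **i** — hairpin-bound start without a synaptic complex (reports the
  unbinding force `F_unbind`; ruptures below 6 pN are free hairpin
  unfolding and excluded),
* **ii** — noncanonical disassembly via intermediate substates
  (`ΔL₁₋sub ≈ 44.6 nm`),
* **iii** — canonical one-step disassembly matching the 71-nm
  fingerprint (reports the disassembly force `F_diss`).

**Synthetic data** (`synaptrap.simulate`). Quasi-static pulling cycles at
250 nm/s with a 0.45 pN/nm trap, Bell–Evans rupture kinetics
(`k(F) = k₀ exp(F·Δx/k_BT)`, sampled under the local loading rate by
inverse transform), Gaussian force noise, plus Hill-shaped EMSA series
and binomial CFU counts — all with per-cycle reproducible ground truth.

**Statistics** (`synaptrap.stats`). EMSA bound fractions
`b = I_bound/(I_bound + I_unbound)` fitted with the Hill–Langmuir curve
`b = b_max / (1 + (c_1/2 / c)⁴)`; one-way ANOVA with Holm-corrected
pairwise Welch t tests and Kruskal–Wallis rank sums for disassembly-force
groups; recombination frequency from CFU counts with the
limit-of-detection rule (all-zero replicates → 1 / Σ recipients); and the
stability–efficiency correlation (Pearson on log₁₀ efficiency, Spearman
on raw pairs).

## Worked example

```sh
$ synaptrap simulate --n-cycles 20 --seed 7 --out demo/sim
wrote 20 cycles (30018 samples) to demo/sim

$ synaptrap analyze demo/sim/trace.csv --out demo/ana
classified 20 cycles: {'i': 1, 'ii': 4, 'iii': 15, 'none': 0}

$ synaptrap report demo/ana/cycles.csv
{
  "n_cycles": 20,
  "category_counts": { "iii": 15, "ii": 4, "i": 1 },
  "category_frequencies": { "iii": 0.75, "ii": 0.2, "i": 0.05 },
  "median_F_diss_pN": 12.29951443,
  "median_F_unbind_pN": 9.904570888333334
}
```

The simulated condition draws pathways with probabilities 0.5 / 0.3 / 0.2
for categories iii / ii / i; at this small n the classifier recovered
15 / 4 / 1. The median disassembly force of ~12.3 pN reflects the default
Bell-bond calibration (analytic ramp median 12.8 pN at the ~32 pN/s
effective loading rate); `F_unbind` comes from the single category-i
cycle. `demo/ana/` also holds per-cycle and per-event CSV tables and a
JSON report embedding the full configuration and its hash.

The same analysis runs from the library:

```python
from synaptrap.config import RunConfig
from synaptrap.simulate import SimulationConfig, simulate_dataset
from synaptrap.workflow import run_analyze

trace, truth = simulate_dataset(SimulationConfig(seed=7), 200)
result = run_analyze(RunConfig(), [trace])
print(result.report["category_frequencies"])
```

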