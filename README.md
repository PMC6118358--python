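# sdstorm

Analysis pipeline for **sequential dSTORM multiplex imaging with DNA strand
displacement**, exercised end to end on a synthetic multi-round acquisition
generator so no microscope data is required.

In this labeling scheme, each antibody carries a single-stranded DNA
*protector*; a dye-labeled *template* strand hybridizes to it (a 30-bp duplex
leaving an 8-nt single-stranded *toehold* on the template), and after imaging
an *invader* strand — the full 38-nt complement of the template — nucleates at
the toehold and displaces the template by branch migration, carrying the dye
away. Because orthogonal gate sets do not cross-hybridize, distinct targets
in the same cell can be labeled, imaged, and stripped in successive rounds
with a single fluorophore species. The quality of such an experiment rests on
a handful of quantitative questions this package answers computationally:

- **Gate structure and orthogonality** (`sdstorm.gates`) — verify from the
  sequences alone that each gate forms the intended duplex/toehold structure
  and that strand sets are mutually orthogonal (longest ungapped antiparallel
  Watson–Crick run across all inter-set strand pairs, default threshold
  max run < 10).
- **Displacement kinetics** (`sdstorm.kinetics`) — pseudo-first-order removal
  of bound template under invader excess,
  `f(t) = (1 − f_res)·(1 − e^{−k·c·(t − t0)})`, with a separable
  photobleaching exponential fitted from the pre-invader segment of an
  intensity trace.
- **Synthetic acquisitions** (`sdstorm.simulate`) — filament- and cluster-like
  structures with discrete binding sites, per-round labeling with a residual
  carryover fraction, minimal blinking photophysics, pixel-integrated Gaussian
  PSF image formation with Poisson statistics, optional EMCCD gain stage.
- **Localization** (`sdstorm.localize`) — maximum-likelihood fitting of the
  model `μ_k = N·Ex_k·Ey_k + b` under a Poisson pixel likelihood
  (per-parameter Newton–Raphson), precision from the Cramér–Rao lower bound
  `CRLB_i = √[(I⁻¹)_ii]` with `I_ij = Σ_k μ_k⁻¹ ∂μ_k/∂θ_i ∂μ_k/∂θ_j`, and a
  deviance goodness-of-fit p-value against χ²(roi² − 4). Accepted emitters
  satisfy background ≤ 200 photons, photons ≥ 250, p ≥ 0.01.
- **Quantification** (`sdstorm.quantify`) — CRLB-width Gaussian
  super-resolution rendering, background-subtracted intensity traces,
  **cross-talk** as the after/before ratio of accepted localization counts,
  per-round count stability, and FFT cross-correlation registration between
  rounds.
- **Orchestration** (`sdstorm.pipeline`, `sdstorm` CLI) — the whole
  label–image–remove cycle from one YAML config, bit-for-bit reproducible
  from its seeds.

## Worked example

Verify the displacement kinetics at the experimental invader concentration
(4.87 µM) with the default rate constant for an 8-nt toehold (10⁵ M⁻¹s⁻¹):

```
$ sdstorm kinetics predict --k 1e5 --conc 4.87e-6 --time 300
{
  "displaced_fraction": 1.0,
  "percent_reduction": 100.0,
  "time_to_95pct_s": 6.151400972390123,
  "time_to_95pct_min": 0.10252334953983538
}
```

i.e. at this concentration the model removes 95% of the dye-labeled template
in ~6 s and is fully saturated long before the 5-minute exchange budget.

Run a six-round (three per target) in-silico experiment:

```
$ sdstorm experiment run examples/experiment.yaml --out out/
```

which simulates, localizes, filters, registers, and renders every round
(~20 s on one CPU at the desk-scale 64 × 64 px / 2,000 frames per round) and
reports:

```
 round target_id  count
     1  clathrin   3326
     2   tubulin   2273
     3  clathrin   3409
     4   tubulin   2108
     5  clathrin   3410
     6   tubulin   2239
CV per target: {'clathrin': 0.014, 'tubulin': 0.039}
cross-talk after round 1: 2.65% (true carryover 2%)
cross-talk after round 2: 6.25% (true carryover 5%)
cross-talk after round 3: 2.43% (true carryover 2%)
cross-talk after round 4: 5.12% (true carryover 5%)
cross-talk after round 5: 1.35% (true carryover 2%)
```

Counts per target are stable across relabeling rounds (CV 1–4%, the
relabeling-robustness measure), and the measured after/before localization
ratios recover the simulated carryover fractions — the closed-loop version of
comparing super-resolution images of the same cell before and after invader
treatment.

Gate verification from a sequence file (IDT-style modification tokens are
accepted):

```
$ sdstorm gates verify gates.fa
Set A: duplex 30 bp, toehold 8 nt (AAACGAAA)
  [PASS] template_length: template is 38 nt
  [PASS] protector_length: protector hybridizing region is 30 nt (linker excluded)
  [PASS] duplex_length: template/protector duplex is 30 bp
  [PASS] toehold_nonzero: toehold is 8 nt (AAACGAAA)
  [PASS] invader_full_complement: invader pairs 38 of 38 template positions
  [PASS] toehold_nucleation: invader 5' end complements the toehold
...
$ sdstorm gates crossreact gates.fa --threshold 10
A vs B: max run 4 (threshold 10) -> orthogonal
```

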