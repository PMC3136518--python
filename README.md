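# polarmod

Single-molecule fluorescence **polar**ization-**mod**ulation analysis:
recovering fluorophore dipole orientations — and light-triggered changes in
them — from movies acquired under continuously rotating excitation
polarization.

## The problem

A group II chaperonin closes the built-in lid over its folding chamber by
rotating the "helical protrusion" at the tip of each apical domain.  To
watch that rotation one molecule at a time, a bifunctional rhodamine is
cross-linked across two engineered cysteines at the protrusion tip of a
surface-immobilized chaperonin, so the dye's absorption dipole tracks the
protrusion axis.  Under excitation polarization rotating at ω deg/s, an
immobile dipole at orientation θ emits

```
I(t) = A · cos²(ωt − θ)          (θ defined modulo 180°)
```

so θ is the phase of a cos² oscillation with period 180/ω.  A UV flash
photoreleases ATP from caged ATP mid-movie; fitting θ separately before
and after the flash gives the rotation angle

```
Δθ = θ_post − θ_pre,   resolved into (−90°, +90°]
```

(the dipole cannot distinguish α from α−180°; the smaller-magnitude angle
is adopted, positive = counterclockwise).  Molecules whose orientation
changes within ~1 s of the flash are *responders*; the Δθ distribution over
many molecules separates into a null peak near 0° and two satellite peaks
near +34° and −35° (protrusion rotation in the upper vs lower ring).

`polarmod` implements the full chain for this class of experiment —
**simulate** (synthetic movies with ground truth) → **extract** (spot
detection, background-subtracted trajectories) → **fit** (cos² phase fits,
Δθ, responder classification) → **analyze** (Gaussian-mixture, lifetime,
brightness and thermal-quenching fits) — for experimentalists who want a
tested, reproducible alternative to one-off scripts, and for method
development against a generator with known truth.

## Worked example

```python
from polarmod.presets import atp_condition, no_atp_condition
from polarmod.pipeline import run_pipeline
from polarmod.popstats import fit_gaussian_sum

# calibrate the responder threshold on a no-nucleotide control
acq, pop = no_atp_condition(seed=7)
null = run_pipeline(acq, pop)
g1 = fit_gaussian_sum(null.valid_deltas, k=1)
threshold = 3.0 * g1.sds[0]
print(f"null peak {g1.means[0]:+.2f} deg, threshold {threshold:.1f} deg")

# caged-ATP condition: movie -> spots -> trajectories -> delta-theta records
acq, pop = atp_condition(seed=11)
res = run_pipeline(acq, pop, threshold=threshold, mixture_k=3)
c = res.manifest.counts
print(f"{c['molecules_simulated']} molecules -> {c['spots_detected']} spots "
      f"-> {c['records_valid']} valid records, {c['responders']} responders")
print("mixture peaks (deg):", [round(m, 1) for m in res.mixture_fit.means])
```

prints

```
null peak -0.26 deg, threshold 16.7 deg
1347 molecules -> 914 spots -> 134 valid records, 16 responders
mixture peaks (deg): [-37.3, 0.7, 29.9]
```

Reading this: of 1347 simulated molecules most photobleach (rate
≈ 0.05 s⁻¹) before enough post-flash signal accumulates, leaving 134
analyzable records — emulating an experiment that analyzes ~136 molecules.
About 10% respond to the ATP-releasing flash, and the three-Gaussian fit of
the Δθ histogram puts the null peak at ≈ 0° and the two rotation peaks near
−35° and +34° (this seed draws them at −37° and +30°; averaged over seeds
they center on the generating ±34/−35°), the signature of the lid-closing
protrusion rotation.

The same stages are available from the shell:

```bash
polarmod simulate --config sim.json --out movie.tif --truth truth.csv --seed 42
polarmod extract  --movie movie.tif --config movie.json --out traj.csv
polarmod fit      --traj traj.csv --config movie.json --out records.csv
polarmod analyze  --records records.csv --k 3 --out report.json
polarmod pipeline --config sim.json --out rundir --seed 42   # all of the above + manifest
```

Movies are plain multi-page 16-bit TIFF; everything else is CSV/JSON, and
`pipeline` writes a manifest with config, seeds, versions and content
digests so a run can be reproduced bit for bit.

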