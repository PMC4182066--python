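# orbishock

Explicit thin-shell finite-element simulation of a blunt strike on the
inferior orbital rim, and analysis of the resulting wall-displacement
wave — the proposed mechanical route to posttraumatic orbital emphysema
(air sucked from the maxillary sinus into the orbit after a blowout-type
injury).

## Who this is for

Researchers in craniofacial trauma biomechanics who want a small, fully
tested, self-contained re-implementation of the classic dynamic orbit
experiment: no commercial FE package, no patient CT required. The
package is a Python library first (`import orbishock`), with short
narrative scripts in `examples/` and a thin `orbishock` CLI.

## The model

The orbital walls are a triangulated shell (~970 flat-facet triangles):
each element superposes a constant-strain membrane (CST) with a discrete
Kirchhoff bending triangle (DKT), six degrees of freedom per node, with
bone as a linear elastic solid (E = 1.2 GPa as measured on orbital-wall
samples, ν = 0.3, ρ = 1900 kg/m³). Nodes where the walls join the skull
(apex ring, superior rim) are fixed.

The strike applies a total force F = 14400 N as six equal 2400 N point
loads on the free inferior rim, with a triangular pulse

    f(t): 0 → 1 at t = 1.3·10⁻³ s → 0 at t = 2.6·10⁻³ s,

directed posteriorly along the orbital axis. The equation of motion
M ü + K u = f(t) is integrated by central differences with a lumped mass
(dt = 0.8 · 2/ω_max ≈ 2·10⁻⁷ s), and the response is sampled every
1 ms up to 10 ms. Post-processing projects each node's displacement onto
its wall normal (positive = into the orbit, negative = toward the sinus)
and reports the outward excursion, the onset of the retrograde
("recurring") wave, the probe-A trace on the anterior floor, and von
Mises surface stresses against a configurable fracture-threshold
surrogate.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```bash
python examples/02_run_strike.py
```

prints, for the default synthetic orbit:

```
total strike force at peak: 14400 N
explicit time step used: 2.24e-07 s, snapshots: 11

floor during the load window: mean -2.62 mm (60% of floor area outward)
peak outward: 22.41 mm at 1 ms (floor_anterior)
retrograde wave onset: 2 ms in floor_anterior
retrograde inward peak: 7.21 mm at 4 ms
probe A: 8.43 mm out, 1.86 mm in, peak-to-peak 10.29 mm
```

Reading this: during the 0–2.6 ms load window the floor moves *outward*,
toward the maxillary sinus (negative mean, 60% of the floor area); after
the outward peak a reversal is detected (the retrograde wave, onset
2 ms); the inward rebound (7.21 mm) is strictly weaker than the outward
excursion (22.41 mm), and the probe on the anterior floor shows the same
asymmetry (8.43 mm out vs 1.86 mm in). That ordering — outward bulge,
reversal, weaker inward swing — is the mechanism under study; the
millimetre values belong to this synthetic geometry and are not expected
to match any patient-derived model.

Other entry points:

```bash
python examples/01_generate_orbit_mesh.py   # mesh + quality report
python examples/03_verification_benchmarks.py
python examples/04_full_pipeline.py         # VTK series, CSV traces, JSON report
orbishock run --out strike_run              # same, from the shell
orbishock benchmarks
```

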