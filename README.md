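# handdose

Monte Carlo per-finger extremity dosimetry for handling a
tungsten-shielded syringe of a beta-plus emitter (¹⁸F-FDG by default).

The package builds a desk-scale analog photon-transport simulation of a
worker's dominant hand gripping a shielded syringe:

* **materials** — embedded mass-interaction-coefficient tables
  (air, water, ICRP-type soft tissue, tungsten; 10 keV–1 MeV) with
  log-log interpolation.
* **geometry** — constructive-solid scene (box / finite cylinder /
  elliptical tube) with point location, ray-boundary distances and
  analytic region masses; vectorized kernels for transport.
* **scene** — the default exposure setup: 100 cm air world, a
  pastern-plus-ten-phalanx soft-tissue hand, and a syringe modelled as
  a tungsten tube (Ø10 mm bore, Ø29 mm outer, 100 mm long) closed by a
  9 mm tungsten plunger roller, holding a water column source.
* **source** — ¹⁸F decays: uniform positions in the liquid, allowed-shape
  β⁺ spectrum (endpoint 0.6335 MeV, branching 0.967), local positron
  termination, back-to-back isotropic 511 keV annihilation photons;
  activity × time → decay-count conversion.
* **transport** — exponential free paths interrupted at boundaries;
  photoelectric absorption and Klein–Nishina Compton scattering (kerma
  approximation for secondaries); history-by-history per-region tallies.
* **dosimetry** — tallies → absorbed doses (E/m), dose-vs-decays OLS
  slope fits, extrapolation to a handled activity, Hp(0.07) via Q = 1,
  normalized mSv/GBq statistics.
* **comparison** — measured Hp(0.07) CSV ingestion, simulated-vs-measured
  range checks, and synthetic measurement-fixture generation.

The default grip pose is a documented stand-in (the study this
reproduces cites an anthropometric atlas without printing finger
dimensions or coordinates); it reproduces the observed exposure ordering
index > middle > ring > small > thumb and is fully configurable.

## CLI

```bash
# run the replicate x level campaign (writes dose_points.csv, tallies.csv,
# provenance.json)
handdose simulate --seed 1 --output-dir runs/demo \
    --n-level 100 --n-level 1000 --n-level 10000 --replicates 5

# fit fingertip dose responses and extrapolate to 300 MBq / 120 s
handdose report runs/demo/dose_points.csv --output-dir runs/demo

# compare against measured Hp(0.07) records
handdose make-fixtures --reference --out measurements.csv
handdose compare runs/demo/dose_report.json measurements.csv --role nurse

# synthetic measurement campaign around a report; geometry inspection
handdose make-fixtures --spread 0.3 --seed 7 --out synthetic.csv
handdose dump-geometry --out geometry.json
```

A YAML config file (`handdose simulate --config run.yaml`) can set every
scene, nuclide, scenario and transport knob; CLI flags override file
values. All outputs embed the config hash and seed; identical
(config, seed) pairs produce byte-identical numeric output.

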