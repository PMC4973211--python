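# stillindex

Indexing of still-shot protein crystal diffraction images — one XFEL pulse
or fixed-target exposure, no crystal rotation — from the positions of their
Bragg spot centroids, given known unit-cell and space-group priors.

A still image carries far less three-dimensional information than a
rotation series: only the curvature of the Ewald sphere, and often just a
few dozen sparse spots.  `stillindex` recovers one or more crystal
orientation matrices per image by taking *pairs of spots to form vectors,
and pairs of vectors to form candidate orientations*:

1. Spot centroids are back-projected onto the Ewald sphere, giving
   reciprocal-space coordinates **x** with |**x**| = 2 sin θ / λ
   ("observed space").
2. Differences between all nearby spot pairs are compared, by length,
   against the table of lattice-allowed inter-reflection vectors
   **B**·Δ**h** ("theoretical space"), where **B** is the Busing–Levy
   matrix of the unit cell and lattice-centring absences remove forbidden
   Δ**h** classes.
3. Any two non-parallel matched vectors whose observed mutual angle agrees
   with a theoretical assignment determine a rotation **U** (two successive
   axis–angle alignments); the full orientation is **R** = **U**·**B**,
   mapping integer (h, k, l) onto observed reciprocal coordinates.
4. Correct orientations are found either by **clustering** candidate
   matrices (most-neighboured matrix under a symmetry-aware similarity
   metric, min over symmetry operators O<sub>s</sub> of
   ‖P − Q·O<sub>s</sub>‖<sub>F</sub>, whose 0.25 threshold corresponds to a
   10° misorientation) or by growing a **vector network** — a
   self-consistent set of ≥ 20 matched vectors — from a seed vector.
5. Candidate solutions are accepted when the spread of per-spot Ewald
   wavelengths (the wavelength whose sphere passes through each modelled
   rlp and the origin) is tight; accepted solutions have their predicted
   spots removed so further lattices on the same image can be indexed.

A companion **pseudo-powder** diagnostic histograms inter-spot vector
lengths pooled over images; its peaks sit at the theoretical distances, so
grid-scanning detector distance (or wavelength, or beam centre) against
the overlap diagnoses metadata errors of tens of millimetres.  A seeded
synthetic still-image generator, sharing its reflection-selection rule
with the spot predictor, provides ground truth for every stage.

Intended users: scientists processing serial synchrotron / XFEL stills who
know their cell and space group and need indexing rates, multi-lattice
deconvolution, or geometry sanity-checks; and method developers who need a
self-contained, testable reference implementation.

## Worked example

Simulate three cubic-I23 stills (cell 106.1 Å, λ = 1.46 Å, detector at
101.2 mm, 0.3 px centroid jitter, 10 % noise spots), index them with the
vector-network branch, and score against ground truth:

```bash
stillindex simulate --config config.json --n-images 3 --seed 7 --out-dir sim
stillindex index    --config config.json sim/sim-*.csv --out sols.jsonl
stillindex evaluate --config config.json --truth sim/truth.json --solutions sols.jsonl
```

with `config.json`:

```json
{
  "geometry": {"wavelength_A": 1.46, "bandwidth": 1e-3, "distance_mm": 101.2,
               "beam_centre_px": [882, 882], "pixel_size_mm": 0.11,
               "panel_px": [1765, 1765]},
  "crystal":  {"cell": [106.1, 106.1, 106.1, 90, 90, 90], "spacegroup": "I23"},
  "simulate": {"rlp_radius": 2e-3, "jitter_px": 0.3, "noise_fraction": 0.1,
               "n_lattices": 1, "d_max": 0.35}
}
```

prints

```
INFO stillindex: sim-0: 81 spots -> 1 lattice(s)
INFO stillindex: sim-1: 86 spots -> 1 lattice(s)
INFO stillindex: sim-2: 91 spots -> 1 lattice(s)
indexed 3 lattice(s) on 3 image(s) -> sols.jsonl
{
  "hit_fraction": 1.0,
  "matched": 3,
  "missed": 0,
  "n_images": 3,
  "rate": 1.0,
  "spurious": 0
}
```

`rate` is lattices correctly recovered per image (the field's "indexing
rate", which exceeds 1.0 when multi-lattice images are deconvoluted) and
`hit_fraction` the fraction of images with at least one correct lattice.
Each record in `sols.jsonl` carries the orientation matrices `U` and
`R = U·B` (row-major) plus acceptance statistics; for `sim-0` the winning
network had 30 member vectors, assigned 74 of 81 spots, and showed an
Ewald-wavelength spread of 0.0028 Å — two orders of magnitude below the
spread of a wrong orientation, which is why it is accepted.

The same library drives everything from Python — see
`stillindex.simulate_image`, `network_index`, `cluster_index`,
`pseudo_powder` and `scan_detector_distance`.

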