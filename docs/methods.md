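# Methods

## Geometry and conventions

The lab frame puts the incident beam along +z with wavevector
s0 = (0, 0, 1/λ); a flat, single, beam-orthogonal panel sits at
z = distance, with 0-based (fast, slow) pixel coordinates and pixel
centres at integer positions.  Back-projection maps a centroid to
rlp = u/λ − s0, where u is the unit direction from the crystal to the
pixel, so every observed rlp lies exactly on the nominal Ewald sphere,
has z ≤ 0, and satisfies |rlp| = 2 sin θ / λ.  The inverse projection
intersects the ray along rlp + s0 with the panel plane and flags
back-scattered (z ≤ 0) or off-panel points.  Multi-panel metrology and
detector tilt are out of scope; fractional-pixel centroids are accepted
as-is.

The "Ewald wavelength" of any reciprocal point q with q_z < 0 is
λ_i = −2 q_z / |q|², the wavelength whose sphere passes through both q and
the origin.  It is the workhorse of solution acceptance and of the
reflection-selection rule below.

## Crystal model

The Busing–Levy **B** matrix (upper-triangular convention, a* along x) maps
integer Miller indices to Cartesian reciprocal Å⁻¹; it is built from the
reciprocal cell computed by gemmi.  Space-group knowledge is reduced to
what indexing needs: the centring type and the proper rotational parts of
the point group, extracted from gemmi's operator tables (a generic config
entry accepting an explicit centring + operator list covers non-tabulated
settings).  Fractional operators W act on Cartesian reciprocal space as
B·W⁻ᵀ·B⁻¹, which is orthogonal exactly when W is a symmetry of the cell —
this is verified at construction.

Theoretical difference vectors are every centring-allowed integer Δh with
|B·Δh| ≤ d_max, enumerated over the index box |h_i| ≤ ‖row_i(B⁻¹)‖·d_max
and stored with both signs.  Axial (screw-axis) absences are deliberately
not applied: a screw axis forbids individual axial reflections, but the
corresponding difference still occurs between general reflection pairs —
which is also why a pseudo-powder pattern shows lines a conventional
powder pattern lacks.  Length collation bins values within 1e−6 Å⁻¹.

Two operator sets matter and are kept separate:

* the **crystal point group** (e.g. 12 proper rotations for I23), used in
  the similarity metric during clustering and network admission;
* the **lattice point group** (proper rotations of the Bravais lattice,
  via `gemmi.find_lattice_symmetry`; 24 for a cubic I or F lattice), used
  to reject geometrically equivalent solutions and to score solutions
  against ground truth.  For cubic crystals in class 23 the lattice has
  432 symmetry, so orientations related by a 4-fold predict identical
  spot positions — the merohedral indexing ambiguity.  Spot positions
  alone cannot distinguish them, and treating them as distinct would
  double-count lattices.

## Vectors, tolerances, matching

Observed inter-spot vectors are all unordered spot pairs with
|rlp_j − rlp_i| ≤ d_max, optionally joined by vectors to the reciprocal
origin (the (0,0,0) reflection), which materially increases the usable
vector count on sparse stills.  Length tolerance is either a constant
(default 5×10⁻⁴ Å⁻¹) or the variable model tol(d) = 2·r_rlp + d·Δλ/λ: the
two rlp-radius terms bound the centre displacement of each endpoint across
the nest of Ewald spheres, the bandwidth term the radial spread between
the extreme spheres.  A vector enters the indexing pool if its length
matches at least one theoretical length within tolerance (binary search on
the sorted table; a brute-force double loop is the test oracle).

Optional neighbour filtering suppresses noise and inter-lattice vectors:
two vectors are neighbours when min(|d_a − d_b|, |d_a + d_b|) is within
tolerance (a vector and its negation are the same unordered object), each
vector is scored by its neighbour count, and a score threshold is chosen
so the retained fraction is as close as possible to p_t = 1/n, with
n = round(spots / spots-per-lattice) (half-up, floored at 1).  With
heavily tied scores no threshold achieves p_t exactly; choosing the
closest achievable fraction keeps the filter order-independent and
meaningful even when most scores are zero.  On two-lattice synthetic
images this enriches intra-lattice vectors about two-fold.  The filter is
off by default and exposed as a config/CLI option.

## Orientation from two vectors

Given observed vectors (i_obs, j_obs) assigned theoretical counterparts
(i_thr, j_thr): Q_a rotates i_obs onto the direction of i_thr about their
cross product (for antiparallel pairs the axis degenerates; a
deterministic perpendicular axis — first basis vector rejected against
i_obs — is substituted); Q_b rotates about i_thr by the angle β that
minimises the angle between Q_b·Q_a·j_obs and j_thr, computed in closed
form as the signed angle between the projections of Q_a·j_obs and j_thr
onto the plane normal to i_thr.  U = (Q_b·Q_a)ᵀ, R = U·B.  The
construction is exact on fabricated data (property-tested to 1e−6) and
its error grows linearly with centroid jitter at small jitter.  Pairs
sharing one spot (three spots total) need no special casing.

The similarity metric between rotations P and Q is
min_s ‖P − Q·O_s‖_F, with operators acting in the crystal frame (right
multiplication: U and U·O_s index the same lattice).  For the trivial
group it equals 2√2·sin(angle/2), so the conventional duplicate threshold
0.25 corresponds to 10.1°, and angular radii (the 8° cluster/admission
neighbourhood) are converted to metric units through that closed form —
one metric everywhere, no mixed degree/metric comparisons.

## Cluster branch

Every pair of matched vectors whose observed angle matches a theoretical
assignment within 1° (degenerate near-parallel pairs excluded) yields a
candidate matrix.  Candidates are scored by their number of neighbours
within the 8°-equivalent metric radius (vectorised all-pairs metric),
greedily selected in descending neighbour count, de-duplicated under
lattice symmetry, and passed through the acceptance stage.  Deterministic
resource caps (80 vectors, 3000 candidates, deterministic truncation)
bound the quadratic cost; on images of ≤ 8 spots the candidate set equals
exhaustive enumeration, which the tests assert.

## Network branch

Seeds are tried most-specific-first: fewest theory matches, then longest
(longer vectors carry proportionately lower relative error).  For each
seed assignment, all pool vectors passing an angle pre-screen against the
seed form bootstrap pairings; the pairing whose orientation has maximal
support (number of pool vectors admitting it within the 8° radius) becomes
the trial consensus.  Support-based selection matters: in cubic length
families a first-come pairing frequently locks onto a wrong but
self-consistent assignment whose support (~15 vectors) can exceed the
noise threshold, while the true consensus has support near the full
intra-lattice pool.  Admissible vectors (best assignment per vector by
metric) are then admitted in deterministic passes honouring the
common-spot requirement (a new vector must share a spot with the existing
network unless the requirement is toggled off) and a member-consistency
check: the candidate is paired with up to 3 existing members (first plus
evenly spaced) and every pairing matrix must lie within the 8° radius of
the consensus; candidates failing the check are retried on later passes,
since the member subset changes as the network grows.  A network is a
solution when it reaches the threshold size (default 20); growth stops at
threshold + 10 members, as size beyond the threshold only gates
acceptance.  Multi-lattice indexing removes the spots predicted by each
accepted solution (2 px radius) and re-runs on the remainder up to
max_lattices, rejecting solutions within metric 0.25 of an earlier one
under lattice symmetry.

Parameter schedules (`multi_cycle`) re-attempt only previously unindexed
images with per-cycle parameters — typically tightening the length
tolerance while relaxing the network threshold, ending with a cluster
cycle — and report the cumulative indexed fraction, which is
non-decreasing by construction.

## Acceptance stage

The paper-level protocol accepts solutions after an initial
orientation-matrix refinement; that full refinement (geometry, mosaicity,
profile parameters) is out of scope here.  What remains is (a) a minimal
orientation polish and (b) the Ewald-wavelength spread statistic.

*Polish*: iterated nearest-hkl assignment (3×3×3 integer neighbourhood of
round(R⁻¹·rlp), centring-respecting) followed by a Kabsch least-squares
rotation fit of B·hkl onto the observed rlps, three iterations,
residual-trimmed.  Without it a raw two-vector matrix is a few tenths of
a degree off on noisy data, and the wavelength statistic — whose
sensitivity to misorientation is amplified by 1/(λ²q²) at low resolution —
cannot separate right from wrong.

*Statistic*: each observed rlp within the resolution cutoff is assigned
its nearest allowed hkl; the per-spot Ewald wavelengths of the model rlps
R·hkl are collected, and the solution is accepted when their standard
deviation is ≤ σ_t or the wavelength histogram (bin width λ·Δλ/λ/4) has a
peak ≥ min_peak, provided at least 10 spots are assigned (a handful of
accidental assignments can show an arbitrarily tight spread).  When
enough spots index cleanly (residual ≤ 1.5×10⁻³ Å⁻¹, and at least
max(5, 15 %) of the pool) the statistics are restricted to them, so noise
spots and other lattices — which carry no meaningful index under this
orientation — do not drown the spread; otherwise all spots contribute,
leaving wrong orientations their tell-tale broad distribution.

Defaults σ_t = 0.02 Å and min_peak = 10 were calibrated once on synthetic
data: the true orientation shows a spread of ~3×10⁻³ Å under the default
study conditions while wrong or random orientations show ≥ 3×10⁻² Å, a
separation of an order of magnitude; the thresholds sit between the two
populations and are exposed in config, as they are inherently
dataset-dependent.

## Spot prediction and the simulator

A reflection is predicted when its Ewald-sphere radius mismatch satisfies
|1/λ_i − 1/λ| ≤ r_rlp + (Δλ/λ)/(2λ), it lies within the resolution
cutoff, is centring-allowed, and projects onto the panel.  The synthetic
still generator is this same function run forward: per lattice a
Haar-uniform orientation (quaternion method), the predicted pixels
jittered by isotropic Gaussian noise, spurious spots added uniformly in
pixel space (what a spot finder hands over), everything shuffled; the
round trip simulator → predictor is bit-exact at zero jitter and the
tests assert it.  Per-image streams derive from (master seed, image
index) via numpy SeedSequence spawn keys, so any image of a set is
independently reproducible.

Study conditions (the generator defaults): a CPV17-like cubic I23 toy —
cell 106.1 Å, λ 1.46 Å, bandwidth 10⁻³ (typical SASE spread), detector
101.2 mm, 0.11 mm pixels, 1765² panel, selection tolerance r_rlp =
2×10⁻³ Å⁻¹ chosen once to give the tens-to-hundreds spot counts typical
of reported hits (~75 per lattice), 0.3 px centroid jitter, 10 % noise
spots.  The geometry-diagnosis fixture is a BEV-like F23 toy (cell 437 Å,
λ 1.31 Å, true distance 85 mm, misrecorded as 105 mm); because all Ewald
spheres pass through the origin, the radius-mismatch units of the
selection rule amplify a geometric rlp size of ~7×10⁻⁵ Å⁻¹ by ~1/(λ²q²)
at these low angles, so that toy's tolerance is 0.08 in radius units,
yielding ~30 low-resolution spots per image.  Indexing of the cubic toy
uses inter-spot vectors to 0.10 Å⁻¹ and spots to 0.35 Å⁻¹.

What the simulator does not model: diffraction intensities, partiality,
mosaic-block substructure, detector point spread, panel tilts and tiled
metrology, non-Gaussian centroid errors, and spot-finder pathologies
beyond uniform false positives.  Passing tests therefore demonstrate the
geometry and the algorithm, not robustness to every artefact of real
detectors; on real data the length tolerances, σ_t and the network
threshold need per-dataset choices, exactly as the per-crystal-form
tuning the method is known to require.

## Pseudo-powder diagnostics

Patterns are histograms (default bin 2×10⁻⁴ Å⁻¹) of inter-spot vector
lengths pooled over images, optionally neighbour-filtered.  The fit score
against the theoretical length table is the fraction of observed vectors
within a tolerance window (default 5×10⁻⁴ Å⁻¹) of any theoretical length
— deterministic, monotone, and parameter-free apart from the window; a
full profile correlation was deliberately avoided.  Grid scans re-back-
project the stored pixel centroids under each trial geometry and return
the argmax (ties to the smaller value).  On synthetic data the score
peaks at the generating distance, wavelength and beam centre within one
grid step, and the 20 mm distance misrecord of the large-cell toy is
recovered to ±1 mm from six images.

## Numerical and degenerate-input choices

Antiparallel alignment axes are chosen deterministically (basis-vector
rejection); near-parallel vector pairs are excluded from candidates at
the pair-angle tolerance; ties in cluster selection break by candidate
index, in grid scans by smaller parameter value, in boot selection by
combo index.  The theoretical-vector enumeration errors out above a
configurable candidate cap (default 2×10⁶ grid points) rather than
silently truncating.  All iteration orders are fixed, so identical input
and parameters give identical output; the suite asserts determinism
end-to-end, including byte-identical CLI reruns.

## Known limitations

Single flat panel only; no cell refinement (the prior cell is trusted);
acceptance thresholds are dataset-dependent by nature; the cluster branch
is quadratic in candidate count and relies on caps for very dense images;
indexing solutions are reported up to lattice symmetry, so for
merohedral classes (e.g. cubic 23) the absolute indexing convention must
be fixed downstream by intensity-based methods.
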