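# Methods

`vifhelix` models and analyses the helical architecture of vimentin
intermediate filaments (VIFs). This note records the model, the analysis
procedures, the numerical choices, and what the synthetic data generator
does and does not emulate.

## The helical model

A VIF is described as a helical assembly of tetramers: the asymmetric unit
is the A11 tetramer (two antiparallel, half-staggered vimentin dimers with
aligned 1B domains), and consecutive units are related by a screw operator
with rise h_r = 42.5 Å and twist 73.7°. The number of units per pitch,
n = P / h_r = 360° / twist ≈ 4.88, is real-valued; the filament nevertheless
organises into 5 protofibrils because tetramer k belongs to protofibril
k mod 5. Within one protofibril, consecutive tetramers are related by the
5th power of the operator, i.e. spaced 5 × 42.5 = 212.5 Å ≈ 21 nm — the
protofibril repeat.

The hand of the helix is not determined by any analysis here; the package
defaults to right-handed (`handedness=+1`), which is an arbitrary,
documented convention.

### Coarse-grained tetramer

Each tetramer is a bead cloud (Gaussian beads, σ = 4 Å by default — the
target resolution regime is ~7 Å, so no atomic detail is attempted):

- Four rod chains in two antiparallel dimers. The tetramer extends
  `cte_span` = 650 Å between the C-terminal ends (CTEs) of the flanking
  2A–2B dimers; each dimer rod runs from its CTE to the 1A N-terminal end
  at `(cte_span + nte_pair_separation)/2` = 470 Å, so the paired 1A–1B
  NTEs are 290 Å apart.
- Domain boundaries follow the vimentin sequence (466 aa, UniProt P08670):
  head 1–85, coil 1A–1B 86–253, linker L12 254–264, coil 2A–2B 265–411,
  tail 412–466; conserved stretches 1A 100–125 and 2B 380–411. Rod
  residues map linearly onto the rod axis; per-bead masses are
  proportional to the residues a bead represents, normalised so four
  chains sum to the 214.6 kDa tetramer (4 × 53.65 kDa from the sequence).
- Head domains are placed as short axial bead strings near the filament
  axis (radius ≤ 10 Å) — a stand-in for the luminal fiber; their internal
  structure is not modelled. Tail beads sit at the 2A–2B CTE positions,
  displaced half-way toward the neighbouring protofibril, representing the
  lateral tail contact sites (annotation only, no energetics; a tail-less
  variant simply omits them).
- Radially, the four chains form a 2×2 bundle (±8 Å offsets) around the
  protofibril center radius of 38 Å, chosen so the bead envelope reaches
  the 55 Å filament radius and the outer diameter ≈ 11 nm.

**Wall-span calibration.** The chain span used for cross-section counting
is set to exactly two protofibril repeats, 2 × n_protofibrils × rise
= 425 Å; the remaining ~45 Å of the 1A end (the NTE protrusion toward the
lumen) is excluded from the rod count. This single calibration makes every
printed stoichiometry an exact lattice consequence: 4 chains in a lone
tetramer's centre, 6 for two overlapping tetramers of a protofibril, 8 for
the full protofibril repeat (3 tetramers), 40 = 5 × 8 for the mature
filament (first reached at 15 tetramers), and an A_CN overlap of
212.5 + 290/2 − 650/2 = 32.5 Å between consecutive tetramers, inside the
expected 30–40 Å window. Interlock sites are computed as midpoints of the
axial overlap between the conserved 1A stretch of a tetramer and the
conserved 2B stretch of its protofibril predecessor; their spacing,
212.5 Å ≈ 21 nm, is a pure symmetry consequence and independent of the
tetramer geometry.

"Chains in cross-section" counts rod chains only (head/tail beads are
annotations); this is the reading under which the published count of 40 is
reproducible as a geometric fact.

## Synthetic data

The generator stands in for the microscopy pipeline (acquisition, motion
correction, CTF, picking, classification are all out of scope):

- **Projections.** Segment images are analytic line integrals of the bead
  model along the beam (y), rendered as 2-D Gaussians; each segment is
  rotated by a random in-plane angle ψ (plus the local tangent angle for
  bent filaments), shifted by sub-box jitter, and degraded with additive
  white Gaussian noise scaled to the noiseless signal RMS. No CTF, no dose
  effects. Records store the exact forward transform, so the noiseless
  image is reproducible bit-for-bit — the ground-truth contract every
  downstream test relies on.
- **Maps.** 3-D Gaussian splatting; the map integral equals total bead
  mass to <0.5%.
- **Missing wedge.** Single-axis tomography convention (tilt axis x, beam
  z): Fourier coefficients whose (k_y, k_z) direction lies outside the
  tilt range are zeroed. Only this forward corruption is modelled; no
  learned restoration.
- **Bending.** A straight model is carried onto an arc-length
  parametrised spline by parallel-transported frames; contour length is
  preserved and a curvature-radius floor of twice the filament radius is
  enforced.

Defaults follow the stated imaging conditions: pixel 3.44 Å, box 110 px,
projection thickness 220 Å. What a green test establishes is therefore
internal consistency of the *methods* on a faithful geometric model — not
that the methods would survive CTF, ice gradients, or heterogeneity, none
of which are simulated.

## Spectral analysis

Power spectra are means of per-segment |FFT|² after undoing each recorded
transform (bilinear resampling; images are mean-subtracted *before*
derotation so the uncovered margins blend into the background). No window
is applied: windows broaden the layer lines and leak the far stronger
equator through their sidelobes into the meridional band.

**Box size.** At the 110-px segment default, the fine layer lines flanking
1/42.5 Å (Bessel orders 0 and ±5, split by ~5.7·10⁻⁴ Å⁻¹) are
unresolvable; precise symmetry measurement therefore uses longer boxes
(512 px ≈ 176 nm), mirroring the practice of analysing long,
computationally assembled filaments rather than raw short segments.

**Meridional Bessel scan.** Each 1-px row in the 1/69–1/30 Å band is
scored by normalised zero-lag correlation against the template
J₀(2πRr)² with R = 55 Å (squared, because the spectrum holds power, not
amplitude), restricted to |r| ≤ 0.6 × the first J₀ zero, after
subtracting a per-column local background (median over rows 4–8 away).
The restriction is essential: first-order layer lines peak only ~0.007 Å⁻¹
off-meridian and masquerade as central peaks under a wider template. The
best row is refined by 3-point parabolic interpolation. Reliability uses
the Fisher-z significance of the winning correlation (z·√(k−3) > 4.5 over
the k template samples), which cleanly separates real meridionals
(r > 0.95) from the best of ~30 white-noise rows.

**Layer-line picking** integrates the spectrum over ±0.02 Å⁻¹ about the
meridian — wide enough to include low-order Bessel maxima (an order-5
line at R = 55 Å peaks near 0.019 Å⁻¹) — and takes prominence-filtered
local maxima.

**Indexing.** Given paired period sequences (P_i around the pitch, h_i
around the rise), n is the closed-form least squares n = Σ P_i h_i / Σ h_i²
for P = n · h_r; pairing is positional. On the printed, 0.1 Å-rounded
periods this gives n = 4.8804 (twist 73.76°), 0.04% from the value
computed from unrounded data (4.8824, twist 73.73°); tests assert at that
rounding-limited tolerance.

**Autocorrelation repeat** collapses the 2-D autocorrelation to the axial
profile and takes the first substantial non-origin maximum — at least half
the height of the strongest peak, so weak ripple shoulders are skipped. An
optional axial Gaussian detrend (σ in px) removes slowly varying
background, needed after straightening.

## Computational assembly

Alignment is exhaustive over a ψ grid (default 2°) with FFT-based integer
shifts against normalised references. Compositing inverts each record's
transform and pastes the matched class average at the segment's crop
position; overlaps are averaged with equal weight (the blending rule is
not otherwise constrained; the unweighted mean is the recorded choice) and
a support map marks empty pixels, which never enter statistics.
Straightening resamples bilinearly along a unit-speed spline;
profile rows read left-to-right for a path running down the image.
Uniform boxing centre-crops assembled filaments to a stated length and
drops shorter ones.

Compositing presumes the segments of one filament have geometrically
coherent orientations (tangent angle + alignment jitter), as real
micrograph crops do; the generator's fully random ψ mode is meant for
orientation-averaged spectra, not for compositing.

## Cross-sections

Sections are thickness-integrated slabs perpendicular to the z-aligned
filament axis (8.84 Å default, matching a tomogram slice). Protofibrils
are counted as prominence-filtered peaks (20% of max-minus-median) of the
annular intensity profile at radius 38 ± 10 Å, sampled every 2° and
smoothed with a wrapped Gaussian of σ = 8° — a protofibril's two dimers
would otherwise split into double peaks. Fixed-alignment averaging rotates
each section by a *given* angle (never searched); coherent averaging
requires sections spaced an integer number of rises apart because helical
symmetry is discrete.

`angular_contrast` is the coefficient of variation (std/mean) of the
smoothed angular profile. Under a ±60° wedge this drops in the population
mean over sections (measured 0.53 → 0.43 over 30 sections); a simple
peak-to-mean ratio is *not* monotone under the wedge because the annulus
mean falls as fast as the peak. Individual sections fluctuate; claims are
therefore made at population level, and the wedge demonstration places
the filament perpendicular to the beam so the section plane contains the
smearing direction.

## Known limitations

- The generator's straight rods have no internal supercoil; layer-line
  intensities (though not positions) differ from real VIF spectra, and the
  Bessel-order structure near the meridional is only approximately
  reproduced at segment-box resolution.
- The luminal fiber and the tails are annotations, not structural models;
  nothing here constrains their conformations.
- Atomic model building, cross-link restraint fitting, resolution
  estimation, and all upstream image processing are out of scope; the
  pipeline consumes simulated stand-ins for their outputs.
- The MRC reader/writer covers mode-2 (float32) single-volume/stack files
  only — sufficient for this package's round trips, not a general library.
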