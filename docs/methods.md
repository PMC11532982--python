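# Methods

## Scope and data model

The package implements the data model and computational core of a cryo-ET
subtomogram-averaging pipeline up to (and excluding) 3D refinement: import
of acquisition metadata, tilt-image curation, the projection model, CTF
handling, tomogram reconstruction for picking, geometric particle sampling
and particle extraction. Algorithms that established external tools own —
movie-frame motion correction, defocus *fitting* from Thon rings, marker
or patch-based tilt-series alignment, neural-network denoising and the
refinement/classification stack — are out of scope; their *metadata* is
fully representable, and the stages that would consume their outputs take
values from nominal acquisition metadata or from simulation ground truth
instead.

Metadata lives in a STAR-file hierarchy: a global table (one row per tilt
series: optics constants, defocus handedness, a pointer to the per-series
file), per-series tables (one row per tilt image: acquisition values,
motion/CTF statistics, the five alignment parameters, the CTF scale
factor), a particle table in centred-Ångstrom coordinates, and an
optimisation-set file bundling the tomogram and particle tables. Typed
records validate the schema invariants on construction (astigmatism equals
|ΔfU − ΔfV|, CTF scale in [0, 1], handedness ∈ {−1, +1}, unique tomogram
names, non-negative accumulated dose); unknown columns are carried through
reads and writes verbatim as strings so foreign metadata survives a round
trip byte-identically. Floats are written with 7 significant digits, which
keeps round-trips within 1e−6 relative.

Conventions chosen where the formats leave them open:

* All paths inside STAR files are project-root-relative with forward
  slashes; per-series and optimisation-set references resolve relative to
  the file that contains them, micrograph paths relative to the project
  root (the working directory of a pipeline run).
* Per-series rows are stored sorted by stage tilt; acquisition order is
  recoverable from the accumulated pre-exposure, which is **not**
  renumbered when images are excluded (dose is physical, not notational).
* The pre-exposure of image *k* is the summed exposure dose of images
  acquired strictly before *k* (its own dose excluded).
* A series emptied by exclusion is kept (with a warning) so bookkeeping
  survives; stages that need images reject it with a named error.
* mdoc dialect: `key = value` headers plus `[ZValue = n]` blocks;
  `TiltAngle` and `ExposureDose` are required per block; the tilt axis is
  accepted both as a `TiltAxisAngle` key and inside the SerialEM free-text
  `[T = ...]` header line.

## Projection geometry

The 3D→2D map per tilt image is `T(Δx, Δy) · Rz(θz) · Ry(θy) · Rx(θx)`
applied to centred coordinates in Å, with the centre of rotation at the
tomogram centre. Angles are stored in degrees and converted internally.
The pixel origin is 0-based with the centred origin at `(nx // 2, ny // 2)`
(integer division); this is stated as the package contract because the
metadata standard does not define a pixel convention, and interop code
must convert explicitly.

Orientations use the ZYZ Euler convention `Rz(rot) · Ry(tilt) · Rz(psi)`;
the subtomogram pre-rotation and the particle rotation compose by
right-multiplication (particle applied first). Per-particle defocus is
`Δf + hand · z` with `z` the third component of the rotated particle
position; the sign is pinned by the handedness semantics (positive-x
particles move closer to focus with increasing stage tilt when
hand = +1), which the test suite asserts as a monotonicity property
rather than as a formula. Astigmatism is treated as depth-independent:
only the mean defocus shifts with particle height, because a per-image
astigmatism estimate carries no depth model.

## CTF model

`CTF(f, α) = scale · [−√(1−A²)·sin χ − A·cos χ]` with
`χ = π λ Δf(α) f² − (π/2) Cs λ³ f⁴` and the azimuth-dependent defocus
`Δf(α) = ½[ΔfU + ΔfV + (ΔfU − ΔfV)·cos 2(α − α₀)]`. Defocus is positive
for underfocus (STAR convention; nominal mdoc defocus is negative for
underfocus and converted on import), and the first extremum is negative.
At reconstruction time the scale factor is `cos θy`, accounting for the
increased specimen thickness at tilt. Phase plates are not modelled.

Derived statistics:

* **Ice-ring density** — mean power spectral density in the amorphous-ice
  band 0.25–0.28 Å⁻¹, normalised by the flanking bands 0.22–0.25 and
  0.28–0.31 Å⁻¹ so the statistic is contrast-scale-free (≈1 for featureless
  images, rising when a ring is present). The normalisation is this
  package's choice; other software may report raw band power, so absolute
  values are not interop-comparable. NaN is returned when the band lies
  beyond Nyquist (pixel size > ~1.79 Å).
* **Defocus search range** — |nominal| ± half-range, converted to unsigned
  underfocus Å, clamped at zero.
* **Dose-dependent CTF-fit resolution** — linear interpolation in spatial
  frequency (1/resolution) between a zero-dose anchor (default 4 Å) and a
  reference-dose anchor (default 10 Å at 60 e/Å²), clamped beyond the
  reference. The linear-in-frequency form is the simplest monotone choice.

## Projector pair and reconstruction

The forward projector treats each voxel as `s³` equal point masses
(`s` = `supersample`, default 1) splatted with bilinear weights at their
projected pixel positions; the back-projector gathers, for each output
voxel, the bilinearly interpolated value of each image at the same
projected positions (zero-padded interpolation at the borders). With equal
`s` the two are exact matrix transposes, which the tests verify to
machine precision as an operator oracle — this adjoint consistency is why
the scatter/gather pair was chosen over ray-marching line integrals.
One-point splatting shows a lattice-interference ripple (up to ~11%
amplitude for in-plane rotations near 45°, the worst case, where all
voxels of a column land on one rotated 2D lattice); `s = 2` pushes the
lattice replicas to twice the frequency and suppresses the ripple to
well under 1%, at 8× cost. Quality-critical comparisons (central-slice
agreement, missing-wedge measurement) use `s = 2`; production tomogram
reconstruction for picking uses `s = 1`, where the ripple is irrelevant
next to noise.

"Weighted" back-projection applies a per-image 1D ramp `|f⊥|`
perpendicular to the in-image tilt axis (the x-axis rotated by θz) — the
standard WBP filter; exact per-tilt-count weighting would be an
alternative. CTF premultiplication in reconstruction uses a single defocus
per image (the image-centre value), so defocus errors grow away from the
tomogram centre; this is acceptable because these tomograms are used for
annotation and picking at large voxel sizes (typically 10 Å), not for
averaging. The tilt-angle offset option (for pre-tilted lamellae) adds a
constant to θy only, at reconstruction time. Even/odd half-tomograms are
reconstructed from the even/odd half-micrographs; back-projection is
linear, so the halves average to the full reconstruction to float32
precision. Output volumes are MRC mode 2 with the binned voxel size
(`tilt-series pixel size × binning`) in the header.

Missing-wedge accounting: the unmeasured wedge of a ±60° single-axis
series is the region `|fz| > tan 60° · |fx|` of Fourier space (the tilt
axis is the specimen y-axis; θz only rotates within the image plane).
When measuring wedge suppression, points near the fy axis must be excluded
(they lie within every central slice) and the volume should be apodised
before the FT (the cube-window sinc tails otherwise dominate); deep inside
the wedge the reconstruction's power is ≥40 dB below the measured region,
decaying smoothly across the boundary where the sinc tails of the nearest
measured slices leak.

## Picking and sampling

Spheres are sampled with a Fibonacci (golden-angle) lattice of
`n = round(4πr²/d²)` points — quasi-uniform with nearest-neighbour
distances in [0.7d, 1.4d]; an optional seeded random rotation of the
lattice emulates random sampling while keeping the spacing guarantees.
The degenerate case `d ≥ πr` yields the antipodal pair. Each pick's
subtomogram triple is the ZYZ decomposition of the frame (x = outward
normal, z = −meridian tangent, y = z × x); the emitted particle angles are
(0, 90°, 0) with tilt prior 90° and psi prior 0, so the composed z-axis is
the outward normal exactly while the particle tilt — the angle the prior
constrains — is 90° for every pick, including at the sphere poles where a
direct (rot, tilt) parameterisation would hit gimbal lock. The psi-prior
convention (in-surface x-axis along the meridian) is a package convention;
only the tilt-prior effect is contractual.

Filaments are natural cubic splines through the control points, resampled
at fixed arc-length intervals by bisection on a dense parameterisation
(1e−3 Å tolerance); the pre-rotation puts particle z perpendicular to the
local tangent so the 90° tilt prior aligns composed z with the tangent.
A two-point filament is handled exactly as a straight segment.

Duplicate removal is a greedy first-kept scan in input order within each
tomogram — order-dependent but deterministic and idempotent, and no two
kept particles are closer than the threshold.

## Extraction

Visibility of a particle on a tilt image requires (a) pre-exposure within
the optional dose cap and (b) the *crop* box, centred at the projected
pixel position, lying fully inside the image — the conservative
definition; "centre inside" would be the permissive alternative. Crops are
taken at integer pixel positions with the sub-pixel residual stored in
metadata rather than applied as an interpolating shift, keeping
premultiplication exact; residual phase shifts belong to downstream
refinement. The big box (`box_px`) is premultiplied by the per-particle
CTF (defocus from the handedness rule) and scaled by cos θy, then reduced
to `crop_px`: a real-space centre crop at binning 1, a Fourier-space crop
(simultaneous binning) otherwise — after the CTF's signal delocalisation
has been compensated inside the big box.

2D stacks store `N_vis · crop²` values plus the visible image names;
pseudo-subtomograms back-project the same crops (no ramp) into a `crop³`
data volume and accumulate each image's squared CTF on its central slice
into a separate `crop³` Fourier-domain weight volume — stored separately
so no division-by-zero policy is baked into the files. Because a tilt
series has far fewer images than a box has pixels on a side, the 2D
payload is `N_tilt/crop` of the 3D one; float16 output (MRC mode 12)
halves either payload exactly, at the cost of third-party reader
compatibility. Emitted bytes are exactly `N_vis·crop²·w` (2D) or
`crop³·w` (3D) with w ∈ {4, 2}, plus the fixed 1024-byte MRC header.

## Synthetic data generator

The simulator emulates a dose-symmetric (0, +s, −s, +2s, …) or ascending
acquisition of a phantom: point beads (gold-fiducial-like) at known
centred-Å positions and/or a Gaussian spherical shell (a virus-like
particle stand-in for sphere picking). Defaults are a ±60°/3° tilt series
(41 images), 10 Å pixels, 3 e/Å² per image, −3 μm nominal defocus, tilt
axis 85°, handedness −1, and additive Gaussian noise with variance scaled
by 1/cos θy to mimic thickness increase at tilt. Even/odd half-images get
independent noise realisations whose mean is bitwise the full image,
matching the even/odd movie-frame convention used for noise2noise
denoising. The mdoc it writes (SerialEM dialect, Windows-style
SubFramePath) and the per-tilt MRC micrographs are consumed verbatim by
the import stage.

What the simulator does **not** model: detector MTF, movie-frame motion,
structured backgrounds, ice gradients, or amplitude-correct electron
counting statistics. Tests passing on this generator therefore validate
geometry, metadata plumbing, filter semantics and operator correctness —
not robustness to real-data artefacts such as alignment errors or
contamination.

## Numerical choices and degenerate inputs

* Degrees at every API boundary, radians internally.
* `premultiply_ctf` requires square, even-sided images (unambiguous
  Fourier grids); reconstruction and extraction only produce such images.
* The ZYZ Euler extraction resolves the tilt → 0/180° degeneracy by
  putting the whole in-plane rotation into psi.
* `ctf_scale_factor` rejects |tilt| ≥ 90°; the tilt-offset option can in
  principle push a tilt past 90°, which then fails loudly rather than
  silently flipping sign.
* Determinism: reconstruction and extraction are pure functions of their
  inputs; repeated runs are byte-identical, and all simulator randomness
  derives from a single integer seed.

## Limitations

* Tilt-series alignment parameters are taken from nominal values or
  ground truth; no estimation from images is performed.
* The exact ramp/weighting filter and float formatting of other software
  differ at the implementation level, so reconstructed volumes are
  comparable in geometry but not bit-for-bit with other packages.
* Magnification anisotropy is ignored; shifts are interpreted in Å in the
  unbinned image frame.
* The ice-ring statistic's normalisation is package-specific (see above).
* Single-defocus CTF premultiplication per image limits the defocus
  accuracy of large tomograms; per-particle extraction re-evaluates the
  defocus at the particle position, which is where accuracy matters here.
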