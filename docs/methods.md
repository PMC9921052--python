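# Methods

## The spot model and L4 numbers

A *spot* is a region-like primitive with an inner region, an environment
(complement) and a symmetric logical *connection* between any two spots:
`aa = 1` for nonempty `a`, `ab = ba`, and a spot never connects its own
environment.  `spotrecon` works with the crisp limiting case: a spot is a
finite binary pixel mask on a grid, connection means sharing at least one
pixel (mere edge-adjacency does not connect), and the grid is embedded in
an unbounded empty plane that belongs to every environment.  The last
convention matters: it makes the environments of any two finite figures
connect (the `ãb̃` bit is 1), so the canonical relation codes remain
reachable even for figures that tile the whole grid, and it is carried
consistently through the logical inner product by an implicit background
atom.

The elementary relation of two spots is the 2×2 bit table
`(ab, ab̃; ãb, ãb̃)`, read row-major as a 4-bit code — an *L4 number*.
Sixteen codes exist; five are named (intersection 1111, separation 0111,
inclusion-more 1101, inclusion-less 1011, indiscernibility 1001), the
rest are classified `other` with their raw code (they arise only for
degenerate figures such as the empty mask).  Swapping the roles of the
two spots transposes the off-diagonal bits; relation vectors and matrices
inherit this, so the inverse of the mapping matrix `⟨Y|X⟩` is its
structural transpose `⟨X|Y⟩` with transposed entries — an involution, and
the indistinguishability matrix (indiscernibility on the diagonal,
separation elsewhere) is its own inverse.

On an *atomic* basis (mutually separated spots, e.g. pixels) the inner
product of two relation vectors is computed bitwise: each output bit is
the OR over atoms of the AND of the matching connection bits.  Sums are
logical, never arithmetic — no counting information is retained anywhere.
The product of a matrix and a vector applies this inner product row-wise
with the unknown spot supplying the left-hand bits; this order is forced
by the identity transformation `a = I a`, which the package tests
against mask-level ground truth.

## Scanning bases, cells and the product rule

The scanning basis is every fully in-bounds k×k square stepped by p
pixels (row-major).  On a 128×128 grid with k = 4, p = 1 that is
125² = 15 625 squares.  The *realized cells* of the basis are the
equivalence classes of pixels covered by exactly the same squares.  For
square bases the covering squares of a pixel form a rectangle in square
index space, so cells are labelled in O(HW) and the 2ⁿ nominal
intersection codes are never enumerated; entirely uncovered pixels form
one flagged cell.  With k = 4, p = 1 every interior pixel is its own
cell covered by 16 squares — the origin of the pixel resolution of the
method despite 4×4 probes.

The product rule maps the scan vector onto the cells.  For a cell `u`
with covering set S, the connection row conjoins `a·xⱼ` over j ∈ S with
`a·x̃ⱼ` over j ∉ S, and the environment row mirrors it; the disjunction
rows are the matching ORs.  All four bits are evaluated *exactly* with
integral-image rectangle sums over the square grid (O(1) per cell), so no
locality truncation is needed at any problem size.

Two bits of the resulting cell code are sound with respect to
set-theoretic ground truth:

* `c21 = 0` (some covering square is included in the figure) implies the
  cell is inside the figure, because the cell lies inside each of its
  covering squares;
* `c11 = 0` (some covering square misses the figure, or the figure sits
  inside a non-covering square) implies the cell is outside.

The boundary corrections therefore classify cells three ways: INSIDE
(`c11 = 1, c21 = 0`), OUTSIDE (`c11 = 0`), AMBIGUOUS (both 1).  The
package proves (by randomized test against brute-force set computations)
that definite calls never contradict the mask truth and that every
genuinely boundary-straddling cell lands in AMBIGUOUS.  The ambiguous
class is irreducible: from square-level relations alone, a slit narrower
than the square is indistinguishable from solid interior, and an
isolated speck from a genuine one-pixel figure.

## Ambiguity resolution and denoising

Binarization must decide the ambiguous cells.  `reconstruct_binary`
fills an ambiguous cell iff some *included* square (scan code 1101/1001)
lies within Chebyshev distance ρ (`inclusion_radius`) of it, with
default ρ = 1.  The rationale: on solid convex bodies the corrections
leave at most a one-cell ambiguity layer along the boundary, so a
one-layer reach is exactly what is needed to absorb that layer and to
keep thin features (star tips) that are attached to a solid body, while
isolated salt specks — which have no included square anywhere near —
are rejected, and pinholes inside a solid body are filled.  This is the
denoising property: flipping 5% of all pixels of the star phantom moves
the area misfit by about two points, and the reconstruction of the noisy
figure is visually clean.  Larger radii were considered and rejected:
they dilate the boundary under heavy salt noise because noise makes
every square near the boundary connect the figure, promoting a band of
outside cells into the ambiguous class.  A radius of 0 disables the
rescue entirely (strict mode).

The trade-off is explicit and documented: with ρ = 1 the method cannot
keep genuinely isolated sub-square-size *features* (they are treated as
noise), and it cannot open slits narrower than the square.  This is the
resolution limit of qualitative scanning, not an implementation limit.

## The spot-based inverse Radon algorithm

The forward sinogram is computed analytically: every pixel contributes
the closed-form projection profile of a unit box (the convolution of two
boxes of widths |cos θ| and |sin θ|), integrated over each unit offset
bin.  Bin integration (rather than point sampling) makes the per-angle
mass exactly equal to the figure area and keeps profiles consistent
across figures of any shape.  Square sinograms use the same closed form
at side k, so the thresholded support of a square at each angle is an
interval whose half-width is found by bisection on the bin-integrated
profile — the analytic path equals the rasterized path bit-for-bit,
which the tests verify.

Both sinograms are thresholded at τ (default 0.5, half a unit pixel
path; configurable for noisy data).  The relation of the figure with
square i is then read from the bits: `c11` = the supports overlap at
some (angle, offset); `c21` = some ray meets the square but not the
figure.  The environment bits toward the sinogram complements are fixed
to 1 — no environment information is inferred from projections.
Inclusion is sound in one direction only: a square inside the figure is
sinogram-included at every angle count (tested for 1, 3 and 18 angles),
while with few angles some outside squares are wrongly counted included
(the intersection of the back-projected shadow bands is larger than the
figure).  That over-inclusion *is* the reconstruction error of the
method, and it shrinks monotonically as angles are added: 2.6% / 5.0% /
6.0% area misfit at 18 / 9 / 6 angles for the default ellipse.

Because sinogram-derived connection bits are ORs over angles they
over-approximate true connection badly, so `radon_reconstruct` runs the
cell machinery in strict mode (ρ = 0): only cells carried by an included
square survive.  Reconstruction from 90+ angles agrees pixelwise with
the direct-scan reconstruction on convex phantoms (≥ 99%).

Impulse ("salt") noise on the sinogram only adds bits, which can only
promote squares toward inclusion at bins they already nearly covered;
the reconstruction is therefore essentially unchanged (the noisy and
noise-free 18-angle misfits agree to well under a point), in sharp
contrast to the Hann-filtered back-projection baseline, whose background
variance at 6 angles exceeds the spot-based background variance many
hundredfold.  Dropped-bit (pepper) sinogram noise is *not* handled: a
single missing ray bin strips inclusion from a whole band of squares, a
direct consequence of the purely logical OR/AND rules; counting-based
robustness is out of scope.

## Grayscale layering

A grayscale image is sliced into L cumulative threshold layers
(`mask_ℓ = img ≥ t_ℓ` at uniform levels over the intensity range) — a
chain of nested spots realizing the intensity axis.  Layers are scanned
and reconstructed independently and recombined by assigning each pixel
the level of the highest layer claiming it.  Nesting makes recombination
well-defined; with L = 256 the round trip is exact to one quantization
step.  With the default 20 layers on the plateaued ramp-disc phantom
every layer reconstructs with < 2% area misfit and the recombined image
is radially monotone.  A constant image degenerates to a single trivial
layer with a warning.

## Phantoms and noise models

All inputs are generated, seeded and deterministic (identical parameters
give bit-identical rasters):

* **star** — filled five-pointed star, outer/inner radii 56/26 on a
  128 grid (scaled with the grid), one point up.  The inner-to-outer
  ratio 0.46 gives the classic filled star silhouette; its area is
  4 278 px.
* **ellipse** — semi-axes 40/24, axis-aligned, centred; rasterized area
  within 2% of πab.
* **shepp_logan** — the standard head phantom resampled to the grid.
* **ramp_disc** — unit-intensity core of radius 20 with a linear radial
  ramp to zero at radius 48 (scaled with the grid).  The core radius
  keeps all 20 default layers far above the scanning-square resolution
  limit; a ramp all the way to the centre would make the top layers
  sub-square-size and unreconstructible by design.
* **noise** — binary figures: independent per-pixel flips
  (salt-and-pepper) at probability p (default experiments use p = 0.05);
  grayscale: additive Gaussian calibrated in closed form to a target
  SNR, defined as `20·log10(mean(clean)/std(noisy − clean))` (within
  0.2 dB); sinograms: additive positive impulses at 5% of bins.

What the phantoms do *not* emulate: anatomical structure, texture,
partial-volume/grayscale boundary effects, detector physics, correlated
or multiplicative noise.  Passing tests demonstrate the logical
machinery and its resolution/denoising properties on crisp synthetic
figures; they say nothing about clinical image quality.

## Numerical choices and degenerate inputs

* All cell aggregations use 2-D prefix sums; empty index rectangles
  return zero, which handles uncovered cells and edge pixels uniformly.
* Default problem sizes: 128×128 grids, k = 4 (direct scan) or k = 5
  (tomography), p = 1; the full pipelines run in well under a second,
  and the randomized soundness checks use ≤ 8×8 grids with ≤ 6 squares
  where brute force is exact.
* Thresholds: τ = 0.5 on sinograms (half a unit path) — any value below
  the smallest chord of interest works for noise-free data; the support
  half-width solver uses 60 bisection steps (≈ 1e-18 precision).
* Empty figures: connection with anything is 0, scans are all-separation
  vectors, reconstruction returns the empty mask, and the area misfit is
  undefined (error) when the original has no inner region.
* The basis-chain transform (`basis_transform`) enumerates only realized
  intersections, guards them with a configurable cap (default 2¹⁶), and
  warns when the two bases are mutually separated — no mapping can carry
  information then, a documented failure mode of the calculus.  Within
  the chain, each intermediate cell lies inside exactly one parent cell
  (cells partition the grid), so the inheritance step is unambiguous.

## Known limitations

* Sub-square-size isolated features are indistinguishable from noise;
  slits narrower than the square are closed.  Both are intrinsic to
  qualitative square scanning.
* Sinogram relations are one-sidedly sound: inclusion claims from few
  angles over-approximate, giving a systematic (monotone in angle count)
  positive area bias for convex figures.
* Only crisp masks are modelled; vague/fuzzy membership and the
  rigid-motion notion of indistinguishability are out of scope.
* Only parallel-beam geometry; no fan/cone beam, no grayscale
  tomography.
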