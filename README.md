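# spotrecon

Qualitative spatial relations as 4-bit logical numbers, and image
reconstruction from nothing but those relations — including a spot-based
inverse Radon algorithm that recovers compact binary figures from as few
as six projection angles.

## The problem

Tomographic and scan-based imaging (CT, MRI, ultrasound, radar) are
inverse problems: the measurements underdetermine the image, and the
classical linear inversions (filtered back-projection) blur and streak
badly when only a handful of projections are available.  `spotrecon`
implements an alternative that throws away almost all quantitative
information on purpose.  A figure *a* is probed with a basis of known
figures *x₁ … xₙ* (sliding squares), and for each probe only the
**elementary relation** is kept — a 2×2 table of connection bits

```
⟨a|x⟩ = | a·x   a·x̃ |      e.g.  1111  intersection   a >< x
        | ã·x   ã·x̃ |            0111  separation     a <> x
                                  1101  inclusion      a > x
                                  1011  inclusion      a < x
                                  1001  indiscernible  a ≈ x
```

where `ã` is the environment (complement) of `a`.  These 4-bit *L4
numbers* form vectors (one code per basis figure) and matrices, with
logical inner products playing the role of numeric linear algebra.
Although each code carries almost no information, tens of thousands of
them pin the figure down to pixel resolution: the reconstruction maps the
scan vector onto the *intersection cells* of the basis (with a 4×4 square
slid at 1-pixel steps every interior pixel is its own cell), classifies
every cell inside/outside/ambiguous by logical product rules plus
boundary corrections, and renders the inside cells.  Reconstruction
quality is measured by the area misfit `mer = |NOI − NRI| / NOI`
between the inner-region pixel counts of the original and reconstructed
figures.

For tomography the same machinery runs on **logical sinograms**: the
parallel-beam sinogram of the figure and the analytic sinograms of all
basis squares are thresholded to bits, the relation of the figure with
each square is read off the bit patterns (inclusion of figures implies
inclusion of all their projections), and the cell machinery inverts the
resulting qualitative scan vector.  Because the relations are logical,
impulse noise on the sinogram barely perturbs the result — the algorithm
has a built-in denoising property that filtered back-projection lacks.

Intended users: researchers in qualitative spatial reasoning / RCC-style
mereotopology who want a concrete executable calculus, and imaging
researchers interested in extreme sparse-view binary tomography.

## Worked example

```python
import numpy as np
from spotrecon import (
    make_star, make_ellipse, build_square_basis, scan_er, reconstruct_binary,
    misfit, forward_sinogram, radon_reconstruct, add_saltpepper,
)

star = make_star((128, 128))
basis = build_square_basis((128, 128), 4, 1)
recon = reconstruct_binary(scan_er(star, basis), basis)
print(f"star: {len(basis)} squares, mer = {misfit(star, recon):.2f}%")

noisy = add_saltpepper(star, 0.05, seed=1)
print(f"noisy star (p=0.05): mer = "
      f"{misfit(star, reconstruct_binary(scan_er(noisy, basis))):.2f}%")

ellipse = make_ellipse((128, 128))
for n in (18, 9, 6):
    sino = forward_sinogram(ellipse, np.arange(n) * 180.0 / n)
    rec = radon_reconstruct(sino, (128, 128), k=5, p=1, tau=0.5)
    print(f"inverse Radon, {n:2d} angles: mer = {misfit(ellipse, rec):.2f}%")
```

prints

```
star: 15625 squares, mer = 0.09%
noisy star (p=0.05): mer = 2.48%
inverse Radon, 18 angles: mer = 2.65%
inverse Radon,  9 angles: mer = 5.03%
inverse Radon,  6 angles: mer = 5.96%
```

The noise-free star comes back with 0.1% area misfit even though the
only input was fifteen thousand 4-bit codes; flipping 5% of all pixels
moves the misfit by about two points because isolated specks and
pinholes are rejected by the cell corrections.  The ellipse is recovered
as a compact, unblurred region from 18, 9 and even 6 projection angles,
with the misfit degrading gracefully as angles are removed.

The same pipelines are available from the shell:

```bash
spotrecon gen --kind star --size 128 --seed 1 star.png
spotrecon scan --size 4 --period 1 star.png star.erv
spotrecon reconstruct star.erv recon.png
spotrecon metrics star.png recon.png
# {"mer": 0.1, "NOI": 4278, "NRI": 4274}
```

plus `gray` (grayscale layering), `radon-forward`, `radon-recon` and
`fbp` (the filtered-back-projection baseline).  See
[docs/methods.md](docs/methods.md) for the model, its parameters and its
limitations.

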