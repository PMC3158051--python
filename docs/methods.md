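# Methods

`territory3d` reimplements, as explicit computation, a scoring procedure that
was originally performed by visual inspection of 3D-rendered multicolor
chromosome-paint FISH images of *C. elegans* germ lines: delineating
chromosome territories, measuring their shape, classifying how homologous
territories relate in space, assigning nuclei to gonad zones, and comparing
the resulting category tables between zones and genotypes. Because the
original microscopy data are not available, the package pairs the scoring
pipeline with a synthetic-data generator that plants known ground truth, so
every classifier and estimator can be validated by recovery.

## The territory model

A chromosome territory is modeled as a **tube**: a smooth 3D centerline of
controlled arclength `L`, a constant tube radius `r` (territory width
`D = 2r`), and a "beads-on-a-string" intensity profile along arclength.
The morphometric quantities are

- width `D` (µm) — premeiotic wild-type territories are drawn from
  `D ~ N(0.67 µm, 0.05 µm)`, the measured width distribution of compact
  territories;
- length `L` (µm) — geodesic length of the traced centerline;
- slenderness `S = L / D` — a territory is **highly extended** iff `S > 6`
  (strict inequality, as defined for scoring);
- painted-segment count `k` — the number of visually distinct signal blocks
  along the territory: intensity peaks separated by gaps of reduced signal,
  plus abutting blocks of different fluorophores.

Centerlines are random planar circular arcs (compact ovoids use gentle arcs,
extended threads strongly curled ones) with a small smooth out-of-plane
perturbation; threads too long to fit the nuclear sphere as an arc acquire a
helical pitch of ~1 µm per turn so successive passes cannot touch. After
shaping, each curve is rescaled to its exact target arclength, so the
planted slenderness is analytic, with no sampling error. The bead profile is
a raised cosine with exactly `bead_count` maxima and a trough intensity of
0.1x peak (bead contrast is not quantified anywhere we could adopt it from;
0.1 gives clearly segmented beads without disconnecting the tube).

## Homolog-pair configurations

Each homolog pair in a nucleus is planted in one of nine configurations,
defined by which interval(s) of the chromosome coordinate (0 = pairing-center
(PC) end) are **associated** (centerlines within one territory width):

| label         | paired interval(s)      |
|---------------|-------------------------|
| V-PC          | [0, 0.10]               |
| Y-PC          | [0, 0.50]               |
| V-NPC         | [0.90, 1]               |
| Y-NPC         | [0.50, 1]               |
| X             | [0.40, 0.60]            |
| O             | [0, 0.10] and [0.90, 1] |
| full          | whole length            |
| no_alignment  | none, but in contact    |
| no_contact    | none, separated         |

Geometrically, homolog B is homolog A displaced along the normal of A's
best-fit plane by a smoothly ramped offset: 1.0 r in paired stretches (the
tubes overlap and render as one thicker thread; fully aligned pairs use
0.3 r, the ~100 nm spacing of synapsed axes), 1.2 µm in unpaired stretches —
well beyond the 1 D pairing distance. Paired constructions use planar arcs
only, because a helical pitch runs along the same normal used for the
displacement and would spuriously bring unrelated coordinates into contact.
The no-alignment configuration is an end-to-side touch between regions of
unrelated chromosome coordinate; the no-contact configuration stacks two
threads on parallel planes with > 0.65 µm of clearance (so that blur cannot
fuse their images).

## Rendering

Rendering is deliberately simple and exactly invertible in the noise-free
limit: a voxel's expected paint intensity is the analytic tube indicator
(exact point-to-segment distance to the centerline) x the bead profile x a
photon scale, written into the channels that paint the local chromosome
coordinate. DAPI covers all chromatin plus a nuclear haze; clustered
(transition-zone) nuclei get a brighter haze hemisphere on the crowded side.
The default noisy condition is Poisson shot noise at 300 expected photons
per unit intensity over a background of 5, blurred by a Gaussian of
sigma = (0.08, 0.05, 0.05) µm (z, y, x). This emulates a *deconvolved*
wide-field stack — the acquisition mode used for this kind of scoring — so
the blur is a post-deconvolution residual, not a raw wide-field PSF. Voxels
are 0.1 µm isotropic by default (optical sections were collected at 0.1 µm
z-steps; the lateral pixel size is not reported, and absolute lateral scale
does not affect any scored quantity, which are all ratios or categories).

## Segmentation

Thresholding that was originally done by eye is replaced by pluggable
policies: `positive` (> 0; exact on noise-free renders), `otsu` (within the
DAPI-defined nuclear region), and `background` (median + 6 scaled-MAD of the
nuclear region). The pipeline default is `background`: Otsu places the
threshold above the bead-trough intensity and shatters beaded territories,
while the background policy keeps troughs; one voxel of halo is then eroded
and internal holes filled. Statistical policies threshold a lightly
denoised (sigma 0.7 voxel Gaussian) copy of the channel. Components use
26-connectivity; channels of one chromosome's paint are unioned, and
components closer than a merge gap (default 0.3 µm, safely below the 0.67 µm
territory width) are merged into one apparent territory. One or two apparent
territories per diploid chromosome are expected; more is flagged as
fragmentation and excluded from pair scoring.

## Morphometry

- **Centerline**: longest geodesic path through the 3D skeleton
  (skimage `skeletonize` + Dijkstra double sweep with lexicographic
  tie-breaks), smoothed with a 3-point moving average to suppress voxel
  staircase; masks thinner than the skeletonizable minimum fall back to the
  principal-axis segment.
- **Width**: the medial tube radius is sampled as the local 3^3 maximum of
  the Euclidean distance transform along the centerline (the skeleton
  jitters off the medial axis by up to a voxel) and averaged robustly
  (mean of samples within one voxel of their median). By default the radius
  is then refined under the capsule volume constraint
  `V = pi r^2 L + 4/3 pi r^3` — the mask volume is known to sub-percent
  accuracy, which removes the lattice quantization jitter of the distance
  transform (sigma ~0.003 µm vs ~0.01 µm). The plain EDT-median estimator
  remains available (`method="edt"`). `D = 2r` plus a quarter-voxel
  partial-volume allowance.
- **Length**: thinning can either retract endpoints from the hemispherical
  end caps or overshoot into them, so the path is first trimmed back to
  full-radius territory (EDT >= r minus a ¾-voxel margin, which is then
  subtracted for trimmed ends) and then completed by the cap overhang (the
  farthest in-cap mask voxel's projection onto the outward tangent minus
  the radius). A consequence worth knowing: a quasi-spherical mask has no
  full-radius tube stretch, so its "length" is reported as ~one voxel and
  its slenderness as ~0 — emphatically not extended, which is the
  classification that matters.
- These calibration constants (quarter-voxel allowance, end completion,
  smoothing window) were fixed once against analytic noise-free tubes of
  known radius and arclength. On the sweep geometry the measured slenderness
  runs ~3-5% below analytic with sigma ~0.05-0.1, placing the strict `S > 6`
  decision boundary between analytic 6.0 and 6.5 with >= 3 sigma margins on
  both sides.
- **Segment count**: per-channel intensities are sampled along the
  centerline (trilinear, half-voxel steps). Peaks of the summed profile
  count as segments when their flanking minima drop below `gap_fraction`
  (0.5) of the lower adjacent peak; peaks closer than 0.3 µm merge; a change
  of dominant channel within an intensity block adds one segment. The 0.5 /
  0.3 µm defaults stand in for "distinctively segmented by eye" and are
  exposed in the configuration.

## Pair scoring

For separated homologs, the edge-to-edge distance `d` (minimum voxel-center
distance less one voxel, since centers sit ~half a voxel inside each
surface; zero on 26-connected contact) is expressed in units of the mean
territory width `D` and classified: touching; close (0 < d <= D);
intermediate (D < d <= 2D); far (d > 2D). The printed bounds overlap at
exactly d = 2D; the package resolves the boundary to intermediate (the
strict reading of `D < d <= 2D`) with a flag to flip it.

Homologs carry identical paint, so associated homologs segment as one merged
territory, which is decomposed through its skeleton graph:

1. *Strand contraction.* Thinning a side-by-side double tube yields one line
   or two bridged parallel strands. Skeleton voxels within 2.4 r of a
   geodesically distant (>= 3x the spatial separation), like-colored voxel
   are partner strands and are merged, collapsing ladders onto the homolog
   pair's axis. The radius used here is the half-max radius — the blurred
   edge of a tube keeps its half-maximum at the true surface, so this
   estimate is robust to PSF fattening of the mask.
2. *Contact veto.* A skeleton neighborhood whose mask mixes strong signal
   from two non-adjacent chromosome segments can only be a contact between
   unrelated regions of the two homologs (homologous association juxtaposes
   like colors); if such stretches exist the pair is scored no-alignment.
3. *Topology + terminal colors.* On the contracted graph: a simple path with
   opposite-colored tips is a fully aligned pair; like-colored tips mean a V
   folded at the opposite end; three branches from a junction are a V or Y
   (the odd-colored branch is the shared stretch; V vs Y at 15% of the
   coordinate, the cutoff that separates end-association from partial
   alignment); four branches around a middle stretch are an X; a cycle wider
   than 0.7 µm is an O (thinning ladders are narrower and are repaired).

The decomposition emits an association profile over 20 coordinate bins plus
a touching flag, and a single function maps profiles to the taxonomy
(decision order: no contact, no alignment, full — >= 90% of bins paired with
both terminal bins paired, tolerating one dropout bin — V, Y, X, O, other).

## Zoning and statistics

Rows of nuclei are counted from the distal tip. The premeiotic zone is the
first 10 rows by default (the proximity analysis uses the first 15 — both
supported, deliberately not merged, since the original definitions differ by
assay). The transition zone is the maximal contiguous run of rows, after the
premeiotic zone, with >= 50% of nuclei clustered and < 90% full
chromosome-I alignment — a quantitative rendering of "clustered chromatin
plus a mixture of chromosome-I alignment states". Clustering is detected
from DAPI asymmetry (intensity centroid displaced by > 10% of the nuclear
radius). Pachytene is a 15-row window (configurable 15-20) beginning 5 rows
proximal of the transition zone's end; rows between and beyond get explicit
labels so zones always partition the gonad. For gonads without full
alignment (*syp-1*), the N meiotic rows are divided into five scoring zones
of widths (n, n, n, n, N - 4n), with n = N/5 rounded half away from zero
(the source says only "rounded to the nearest integer").

Category tables are compared with two-tailed tests via scipy: Pearson
chi-square without continuity correction, exact Fisher on 2x2 tables, and
Mann-Whitney U (exact for small tie-free samples, tie-corrected normal
approximation otherwise). No multiple-testing correction is applied — the
scoring tradition this follows reports raw p-values. The test suite checks
Fisher against exhaustive hypergeometric enumeration for every 2x2 table
with total <= 20 and Mann-Whitney against brute-force labeling enumeration.

## What the synthetic data do and do not show

The generator reproduces the *geometry and logic* of the scored quantities:
tube-like territories at the measured width distribution, the full
configuration taxonomy, beaded intensity profiles, row-organized gonads with
planted zones, and a premeiotic null in which homologous and heterologous
proximity distributions are exchangeable (the chi-square p-values over
replicate simulated gonads are uniform — the logical structure of the
premeiotic finding). It does not reproduce chromatin texture, nucleolus
exclusion, neighboring-nucleus crowding, depth-dependent aberrations, or
the biological frequencies of the configurations in any genotype; passing
recovery tests therefore demonstrates that the *scoring pipeline* is
correct and calibrated, not that it would achieve the same accuracy on raw
microscope data. The original biological quantifications (premeiotic
proximity fractions, per-genotype extension percentages and p-values) would
require the original images, which were never deposited.

## Problem sizes

Default self-check sizes are chosen to give tight estimates at interactive
runtimes: 100-120 territories for the width panel, 2-3 replicates per
slenderness value (1-12, step 0.5), 20 nuclei per configuration label, and
200 simulated gonads of 60 nuclei for the null calibration. All panels
accept larger sizes.

## Known limitations

- Width estimates on noisy renders are biased high by ~0.1-0.2 µm (halo
  above a trough-preserving threshold); noise-free calibration quantities
  are unaffected, but per-zone extension fractions under noise are slightly
  conservative.
- The contact veto needs >= 3 paint segments; with two-color halves paint,
  an end-to-middle contact between non-adjacent regions cannot be
  distinguished from association by color alone.
- Merged homolog pairs are measured as one territory; their volume-refined
  "width" absorbs the doubled cross-section, which only makes the extension
  call more conservative.
- The two-strand decomposition assumes at most one homolog pair per merged
  component; fragmented or multi-chromosome fusions are flagged and
  excluded, mirroring the original exclusion of poorly separated nuclei.
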