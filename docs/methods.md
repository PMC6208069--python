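# Methods

This note documents the models, conventions and numerical choices
behind `kneealign`, and what the synthetic validation does and does not
demonstrate.

## Coordinate conventions

All geometry is in millimetres in right-handed Cartesian frames. Bone
meshes are STL surfaces (binary or ASCII); STL carries no units, so
millimetres are asserted by convention. On read, facet-soup vertices
are welded at 1e-6 mm and zero-area facets dropped with a warning.
Rigid transforms are proper (orthonormal rotation, det +1); reflections
are rejected everywhere, because a mirrored bone or implant is
anatomically meaningless.

Anatomic frames are **anatomically signed**: `ml` always points
medial→lateral, `ap` posterior→anterior, `si` inferior→superior. A
consequence worth stating explicitly: the handedness of the (ml, ap,
si) triple is +1 for right knees and −1 for left knees — left anatomy
is the mirror image of right anatomy, and no sign convention can make
both sides' anatomically labelled axes share a handedness. The frame
records its side; all angle formulas are written in terms of the signed
components, which makes them mirror-consistent without per-side special
cases (verified by the mirror-symmetry tests).

## Frame construction

* Femur — SI axis: knee centre → hip centre (the mechanical axis),
  kept exact; ML axis: transepicondylar axis (medial sulcus → lateral
  epicondyle) orthogonalised against SI; AP = SI × ML, sign-corrected
  on the left. Origin: knee centre.
* Tibia — SI axis: inter-malleolar midpoint → midpoint of the
  medial-third-of-tubercle and PCL-insertion landmarks, kept exact; AP
  axis: PCL insertion → tubercle line orthogonalised against SI;
  ML = AP × SI, sign-corrected on the left. Origin: plateau centre.

Gram–Schmidt order is fixed (SI exact, secondary projected, tertiary by
cross product). SI-primary was chosen because coronal and sagittal
alignment are clinically referenced to the mechanical axis; the
secondary axis absorbs any non-orthogonality of the raw landmark
directions. Landmark sets carry a mandatory side tag; there is no
automatic side detection. The translational origins (knee centre,
plateau centre) are a documented package convention — placement values
depend on them, so swap-in of a different origin convention changes
AP/ML/SI translations but nothing else.

Two independent landmarkings of the same bone can be compared with
`landmark_qc`, which flags any landmark whose placements differ by more
than a threshold (default 4 mm, the review trigger used in practice).

## Angle convention

Component alignment is reported as three projection angles of the posed
component axes in the anatomic frame, not as a sequential Euler
decomposition — the three clinical names carry no rotation order:

* FE = atan2(−a, s) of the component SI axis, (a, s) its AP/SI
  components: positive = superior axis tilted posteriorly (flexion).
* VV = atan2(−m, s), m the ML component: positive = tilted medially
  (varus).
* IE = atan2(a′, m′) of the component ML axis: positive = rotated
  anterior-to-medial (internal rotation).

For rotations about a single anatomic axis the corresponding angle
equals the rotation magnitude exactly and the other two are zero (tested
to 20°). For composed rotations, projection cross-talk is bounded: 3°
FE combined with 2° IE perturbs the reported values by < 0.05°. The
convention tag is embedded in every serialized report. Published
tables from other conventions are comparable only up to sign
definitions, which such tables rarely state.

## Registration

**Kabsch** (paired points): closed-form SVD solution with the standard
reflection guard (flip the last singular vector if det < 0), followed
by one re-orthonormalisation to keep the rotation orthonormal to 1e-15.
Degenerate configurations (< 3 pairs, collinear sources) raise.
Optimality is tested against a 10,000-candidate brute-force oracle and
against `scipy.spatial.transform.Rotation.align_vectors`.

**Trimmed ICP** (surfaces): nearest-neighbour correspondence via
`scipy.spatial.cKDTree`, pairs beyond `max_correspondence_distance`
(default 10 mm) gated out, the worst `trim_fraction` (default 0.1)
trimmed (ties broken stably by destination index), Kabsch update, until
the trimmed rms changes by less than `tolerance` (default 1e-6 mm) or
`max_iterations` (default 100). A step that would raise the rms is
rejected and iteration stops, so the accepted-rms sequence is monotone
non-increasing. Optional deterministic subsampling is controlled by an
explicit seed; the default uses all points.

**Direction of fitting.** `analyze_case` moves the *partial* post-op
surface onto the *full* pre-op mesh and inverts the result. Every
moving point then has a true counterpart, so trimming and gating only
absorb noise instead of fighting the resected region; fitting the full
mesh onto the partial one would drag resected-area points toward
unrelated surface and bias the pose.

**Initialisation.** ICP is local. Manual workflows bridge this with a
hand pre-placement; `kneealign` replaces it with a deterministic
coarse stage: short, subsampled, untrimmed ICP runs from a grid of
perturbations about the bone's principal (long) axis — spins ±12° in 3°
steps and slides ±12 mm in 4 mm steps — the lowest-rms basin is refined
by full untrimmed ICP, and the search is re-centred and repeated until
the rms stops improving (max 3 rounds) before the gated, trimmed fine
stage. The long axis is the right subspace to search: a shaft
constrains spin and slide only through its subtle asymmetries, so those
two pose coordinates have narrow basins of attraction, while the
transverse components converge from far away. The coarse stages do not
trim because, with the partial surface as the moving set, the
worst-fitting points (metaphyseal flares, condyles) are exactly the
ones that carry the misalignment signal. Capture range under the study
conditions is ~12° about the long axis and tens of mm elsewhere; beyond
that, callers supply an explicit initial transform.

## Implant definitions, pose and resections

Real component CAD is vendor-proprietary, so implants are described by
a parametric JSON definition: ≥3 named fiducials, anatomic-labelled
orthonormal local axes, and resection planes with normals oriented
toward the removed bone. Vendor CAD-derived values drop into the same
format. The packaged definitions place the eight femoral fiducials at
the extreme corners of the component envelope (posterior condyle tips,
anterior-flange top corners, distal edges, intercondylar notch) and the
tibial ones around the tray rim plus two keel/stem points — the spread
an engineer picking registration points would aim for, since pose
conditioning scales with the fiducial lever arms. With 0.2 mm
observation noise this layout keeps the fitted orientation within 0.5°
of truth.

Resection thickness is the signed plane-normal distance from the
pre-operative bone's regional extreme vertex to the posed resection
plane, positive on the removed side — the surgical "resection depth"
reading. Regions split medial/lateral at the sagittal plane through the
frame origin; distal regions use the minimum-SI vertex, posterior the
minimum-AP, plateau the maximum-SI. The measure is tessellation-stable
(< 0.05 mm under refinement of the analytic phantom).

## Reliability statistics

`max_abs_dev` is the maximum absolute deviation from the per-case mean;
`ci95` is z-based, `1.96·s/√n` with the sample standard deviation —
the z form (not t) is what reproduces the published worked-example
cells (a t-based interval gives 0.73 where 0.6 is printed). Reported
values round half away from zero to one decimal, matching the tables'
precision. Some published summary cells cannot be regenerated from the
tables' own 1-decimal values (the publication evidently summarised
unrounded internal data); the packaged fixtures annotate those cells as
expected-divergent with both numbers, rather than forcing agreement.

ICC defaults to ICC(2,1) — two-way random effects, absolute agreement,
single measurement — the standard variant for interchangeable raters;
ICC(3,1) and the average-measure forms are selectable. The ANOVA
implementation matches `pingouin.intraclass_corr` to 1e-9 in tests.
ICC is undefined at zero total variance and raises. Band labels:
> 0.9 excellent, (0.80, 0.9] very good, (0.75, 0.80] good, [0.5, 0.75]
moderate, < 0.5 poor; boundary values fall in the lower band as listed.

Effective dose is the product of dose-length-product (mGy·cm) and an
anatomic conversion coefficient (mSv per mGy·cm); the coefficient is an
input, not a built-in table.

## The synthetic phantom

The phantom emulates segmented knee surfaces with primitive, analytic
geometry: the femur is an elliptical (16 × 13 mm), anteriorly bowed
(5 mm) shaft with exponential metaphyseal flares at both ends, capped
by two unequal condylar spheres (medial 21 mm, lateral 19 mm); the
tibia is a 3-lobed (triangular-prism-like) shaft with flares and a
plateau ellipsoid (30 × 20 × 10 mm). These asymmetries are not
decoration: they are the features of real bones that make the rigid
pose observable from the surface, and without them surface registration
is ill-posed (an extruded cylinder is invariant to spin and slide).
Surface sampling is deliberately aperiodic (golden-ratio azimuthal
phase per ring, jittered ring heights) so that no rigid motion maps the
vertex lattice onto itself — a regular grid would hand point-to-vertex
ICP spurious exact minima one grid step away, an artifact no real
segmentation mesh exhibits.

`implant_and_scan` crops bone on the removed side of each posed
resection plane (femoral cuts restricted to the condylar zone), deletes
a 3 mm peri-implant band emulating CT metal flare, applies the unknown
CT-frame offset, and adds isotropic Gaussian jitter to surface vertices
(default SD 0.3 mm ≈ segmentation uncertainty of a ~1 mm-slice
protocol) and fiducial observations (SD 0.2 mm). Default study
conditions: CT offset 10° about a seeded random axis plus 20 mm seeded
random translation; true component poses a few degrees and millimetres
from neutral; true resections ~6–11 mm. All randomness flows through
the spec seed; identical specs give byte-identical outputs. Ground
truth (landmarks, frames, poses, angles, translations, resections) is
recorded and self-consistent under recomputation to 1e-9.

What the phantom does **not** emulate: real cortical/trabecular shape
variation, segmentation artifacts beyond isotropic jitter, metal-flare
physics (flare is a deleted band, not intensity corruption), landmark
placement error (landmarks are analytic), and the manual refinement
loop of human operators. Passing the synthetic envelope therefore shows
the computational chain is correct and noise-stable at realistic noise
scales; it does not certify accuracy on clinical data, where
segmentation and landmarking errors dominate.

## Validation summary

The test suite checks, at tolerances stated in the tests: exact
recovery (≤ 1e-6) on the noise-free identity phantom; recovery within
0.01°/0.01 mm under a noise-free 10°/20 mm CT offset; a maximum error
≤ 0.9° (angles) and ≤ 0.5 mm (translations/resections) across 20 noisy
study-condition phantoms; Kabsch optimality against brute force; ICP
rms monotonicity; frame orthonormality/equivariance on 100 random
landmark sets; scene equivariance of the full report (≤ 1e-6); STL
round-trip fidelity at float32 precision; reproduction of the published
reproducibility cells that are derivable from the printed tables; and
ICC agreement with an independent oracle plus a simulated 11-subject
two-rater study with ICC(2,1) ≥ 0.93 for all six variables.
`scripts/acceptance.py` recomputes the headline numbers (problem sizes:
20 phantoms, 11 subjects × 2 raters) in about a minute.
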