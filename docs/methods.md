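# Methods

All coordinates are world RAS in millimetres. Volumes carry a 4×4 affine;
`world_to_voxel`/`voxel_to_world` are exact inverses. Label volumes are
sampled at the nearest voxel center with round-half-away-from-zero per axis;
points mapping outside the grid read as background (0). Intensity volumes are
sampled trilinearly.

## Synthetic head phantom

The phantom is defined analytically and then voxelized, so every voxel center
is exactly right and mesh/volume disagreement is confined to the sub-voxel
boundary band. Labels: background 0 outside the pial sphere (radius
R_pial = 60); cortical wedges 1..K partition the shell R_white ≤ r < R_pial by
azimuth (K = 8); white matter 100 inside the white sphere (R_white = 50);
subcortical blobs 200, 201, … are spheres strictly inside the white sphere
(default ±20 mm on x, radius 8). Pial and white surfaces are icospheres
(subdivision 4, 2562 vertices) in the same world frame. Depth shafts place
`n` contacts from the target toward the entry at a fixed pitch; grids tile a
tangent plane, optionally lifted along the outward normal and jittered with a
seeded Gaussian, to emulate brain shift.

## Probabilistic region labelling (expanding cylinder)

For a contact at `x` with local shaft axis `u` (central finite difference of
neighbouring contacts), a cubic lattice of pitch 0.5 mm fills a cylinder of
radius r_max = 3 mm and half-length equal to half the local inter-contact
gap. For each radius r_k = k·r_max/6, k = 1..6, the fraction of lattice
points (by nearest-voxel label, background included) gives a per-radius label
distribution; the contact's probability table is the unweighted mean over the
six radii, so Σp = 1 exactly and the label support grows monotonically with
radius. Assignment takes the argmax over grey labels (cortical or
subcortical); ties break to the lower label id and are flagged; if no grey
label has mass, the overall argmax is used and flagged as a fallback.
Bipolar mode applies the same construction at the pair midpoint with the pair
axis and half-separation half-length.

## Volumetric labelling (enclosing volumes)

Per parcellation label, the enclosing surface is the exact boundary of the
union of that label's voxel cubes: a quad is emitted wherever a labelled
voxel's face neighbour (per axis, per sign) has a different label, quads are
triangulated with outward orientation, and vertices are mapped through the
affine. This reproduces voxel volumes exactly (divergence-theorem volume of a
single voxel equals the voxel volume), unlike iso-surface extraction which
shaves corners. Cube unions touching along an edge yield 4-fold edges, so
"closed" is validated as *every undirected edge having an even count ≥ 2*;
ray-parity membership and signed volume remain exact under this relaxation.
Membership tests cast a +x ray with an irrational directional perturbation
and count 2-D barycentric crossings using a (y, z) spatial binning of
triangles; points on the surface (within tolerance of the closest triangle)
count as inside. An alpha-complex alternative (Delaunay tetrahedra filtered
by circumradius ≤ α, default 2 voxels) provides a smoother hull.
Classification applies a fixed precedence: subcortical > cortical grey >
white > pial-surface (inside the pial mesh but in no labelled volume) >
outside.

## Measurements

Bipolar midpoints are contact-pair means. Grey/white distances default to
the distance to the nearest mesh *vertex* (the field's operational
definition); this overestimates by at most `sqrt(d² + e²) − d` for true
distance d and edge length e (≈4.5 mm at subdivision 4), which exceeds
0.5 mm for points near a surface. `method="surface"` instead measures to the
closest point on any triangle and is accurate to the mesh sagitta (~0.05 mm
on the phantom). The shaft angle to the local cortical axis is
`arccos |u · n̂|` in degrees, with `n̂` the area-weighted vertex normal at the
nearest pial vertex. Trajectory summaries count contacts per tissue class
per electrode plus a pooled row.

## Brain-shift snapping

Grid/strip contacts `x_i` with initial positions `x_i⁰` and 4-neighbour grid
edges minimize

    E(x) = Σ_i ‖x_i − x_i⁰‖² + λ Σ_(i,j) (‖x_i − x_j‖ − d_ij⁰)²

subject to every `x_i` lying on the Taubin-smoothed (shrink-compensated,
λ = 0.5, ν = 0.53, 20 iterations) pial surface. The solver alternates one
damped Gauss–Seidel sweep of the unconstrained energy with projection to the
nearest surface point, accepting a step only if it does not increase E
(backtracking over step sizes 1, ½, ¼, ⅛, 1/16); starting from the naive
per-contact projection this guarantees a non-increasing energy trace and a
final energy never worse than naive projection. Depth shafts are never
snapped.

## Oblique reslicing and reporting

A trajectory p0→p1 defines a plane: in-plane axis u = unit(p1−p0), axis v =
the in-plane direction closest to world +z (falling back to +y when the
trajectory is itself near-vertical). Pixels sample the volume on that plane
(nearest-voxel for labels, trilinear for intensities) with an exact
pixel↔world mapping placing p0 and p1 at exact pixels; an axis-aligned
trajectory in an identity-affine volume reproduces the orthogonal slice
bit-exactly. The report renders, per contact, sagittal/coronal/axial slices
through the contact's voxel plus the along-shaft reslice, each with the
contact forward-projected exactly, one page per contact in electrode order.

## File formats

NIfTI-1 for volumes (labels as int32); FreeSurfer binary surfaces, with the
surface-RAS (tkrRAS) offset taken as the world position of voxel index
(I/2, J/2, K/2) of the companion volume; FreeSurfer-style color LUTs with
name-rule categorization plus id-range fallback (1000–2999 cortical,
3000–5999 white); binary STL per label; CSV/TSV contact tables with sniffed
delimiters and line-numbered parse errors; a per-contact region-probability
CSV (8 significant digits so row sums re-read within 1e-6); and iEEG-BIDS
`electrodes.tsv` (name/x/y/z/size plus tissue and measurement columns, "n/a"
for missing) with its `coordsystem.json`.
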