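# Methods

## Model

`solvmap` estimates local binding free energies from cosolvent-MD probe
occupancy by the inverse-Boltzmann relation

    ΔG_i = −RT · ln(n_i / n_bulk)

with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and T defaulting to 300 K (the
simulation temperature the grids are assumed to come from). `n_i` is the
pooled probe count in voxel *i* and `n_bulk` the expected count per voxel
at bulk solvent density over the same frames. The estimator assumes the
simulation samples the probe distribution at equilibrium and that the grid
is fine enough (default 0.5 Å) for counts to be locally homogeneous. No
concentration-correction term beyond the `n_bulk` reference is applied.

Replicas are pooled by summing raw counts (and frame numbers, and bulk
expectations) *before* the log conversion: the log of a sum is far better
behaved than a mean of logs when voxel counts are small. Voxels never
visited get exactly `+cap_kcal` (default +3 kcal/mol) instead of +∞ so
energy grids remain finite and writable; the cap only needs to exceed any
energy that could plausibly enter the top-fraction selection.

If `n_bulk` is not supplied, it is estimated as the mean count over voxels
farther than `shell_max` above the vdW + probe surface — i.e. genuine bulk
solvent — and the estimate is logged.

## Hotspots

The most favorable `top_fraction` of voxels per channel (default 0.02 %,
ceiling rule, ties broken by lower flat index so extraction is
deterministic) is split into 26-connected components. Components of at
least `min_voxels` voxels (default 1) with a favorable average become
hotspots. Hotspot energy is the Boltzmann average of member voxel energies
(w_i = exp(−E_i/RT)), hotspot position the Boltzmann-weighted centroid.
The Boltzmann average is dominated by the deepest members but still sits
above the minimum; on a smooth basin it reads ~0.15–0.2 kcal/mol shallower
than the basin floor at these selection sizes. The top fraction is applied
per channel; the denominator is the full voxel count of the grid.

## Surface distances

A voxel of the analysis lattice is *traversable* when its center is (a) at
least `probe_radius` (default 1.4 Å) outside every atom's vdW sphere and
(b) at most `shell_max` (default 3.0 Å) above that vdW + probe surface.
The band forces paths to follow the surface: without the outer bound,
"surface" distances would cut through bulk solvent; without the inner one,
through the protein. Distances are shortest paths on the 26-connected
lattice restricted to traversable voxels, edge weight = Euclidean distance
between voxel centers, found with A* under the straight-line heuristic
(admissible and consistent ⇒ optimal, and exactly equal to Dijkstra, which
is kept in the package as an independent scipy.sparse.csgraph-based oracle).
Endpoints snap to the nearest traversable voxel within `snap_max`
(default 2.0 Å); anything deeper is reported unreachable (+∞) rather than
tunneled to.

For the all-pairs matrix each hotspot runs a single-source uniform-cost
search. Searches stop at a `distance_horizon` (pipeline default 12 Å):
pocket assembly only discriminates distances up to its merge threshold
(8 Å), so pairs beyond the horizon are reported as +∞ without changing any
pocket, at a large saving in search cost. Set the horizon to ∞ to get the
full matrix. With multiple conformations the matrices combine element-wise
by minimum — a pocket reachable in *any* sampled conformation counts.

The lattice path metric overestimates true geodesics by the usual
Chebyshev-lattice factor (≤ ~8 % for generic directions at 26-connectivity);
link/merge thresholds are calibrated in the same metric, so this is
consistent within the pipeline.

## Pocket assembly, filters, ranking

Stage 1 links hotspots at surface distance ≤ `link_distance` (6 Å) and
keeps connected components with ≥ `min_density` (4) hotspots. Components
already larger than `volume_cap` (500 ų) are rejected. Stage 2 merges the
closest eligible candidate pair (inter-candidate surface distance ≤
`merge_distance`, default 8 Å) whenever the merged volume stays within the
cap, repeating until no merge is possible; ties break on the smaller lowest
hotspot id, making assembly deterministic and order-independent. The cap is
read as a bound on the *merged pocket's* volume, not on the volume gained.

Volume is the union of spheres of `sphere_radius` (2.0 Å) around hotspot
positions, counted on a lattice anchored to the analysis-grid origin —
deterministic for fixed geometry and translation-consistent. At 0.25 Å
counting spacing a single sphere is within 2 % of 4/3·π·r³.

Two ligandability filters are recorded (never silently applied — both flags
appear in the report):

- **Polarity balance**: at least one hotspot of each channel and a minority
  fraction ≥ `polarity_min_fraction` (0.2). A druggable site needs both
  hydrophobic contact and directional polar anchors.
- **Geometry (buriedness)**: fraction of 146 quasi-uniform rays (golden-angle
  spiral) from the pocket's Boltzmann-weighted centroid that hit an atom
  sphere within 8 Å; threshold 0.5. Roughly: 0 in open solvent, 0.5 on a
  flat wall, →1 in an enclosed cavity. Being centroid-based, it can be
  overly generous for sprawling hotspot chains whose centroid sinks under
  the surface; the pocket report keeps the raw value so such cases can be
  audited.

Pockets are ranked by ΔG sum ascending (most favorable first), ties broken
by efficiency (ΔG sum / hotspot count), then by lowest hotspot id; labels
A, B, … follow rank order.

## Pharmacophore export

The `k` (default 2) most favorable hotspots per channel become restraint
features ordered by (energy, id). Polar features carry a 0.5 Å tolerance
and type `Any` by default — the hydroxyl probe donates *and* accepts, and
committing to a direction requires inspecting the receptor, so the
direction is a user option (`Don`/`Acc`). Hydrophobic features carry 1.0 Å
and type `Hyd`. The docking cavity is the Boltzmann-weighted hotspot
centroid with an 8 Å radius (optionally one reference point per hotspot).
Files are fixed-format, 3-decimal, byte-stable across reruns.

## Synthetic systems

The generator emulates what the occupancy analysis of a mixed-solvent
trajectory sees, not the dynamics themselves:

- a toy "protein" of carbon pseudo-atoms (r = 1.70 Å) on a 1.2 Å lattice
  filling a sphere (or slab), minus carved spherical cavities;
- per solvent voxel, counts drawn Poisson with mean
  `bulk_expected · exp(−E(x)/RT)`, where E(x) sums per-site Gaussian energy
  bumps `ΔG_target · exp(−d²/2w²)`; the blob is Gaussian in *energy*, so the
  expected count at a site center inverse-Boltzmann-converts exactly back
  to the target ΔG — the generator's central, testable contract;
- zero counts inside the protein (closer than the probe radius to the vdW
  surface); plain bulk noise everywhere else, including beyond the shell,
  so bulk estimation is exercised too.

Defaults, chosen once as plausible analysis-scale conditions: 0.5 Å grid
spacing, 20 expected bulk counts per voxel, 15 000 pooled frames (three
50 ns replicas at 10 ps saving), kernel width 2.0 Å ≈ the probe's
heavy-atom footprint. A design pre-study fixed the kernel default:
narrower kernels make the top-fraction member set steeper in energy and
bias the Boltzmann-averaged hotspot energy well below the planted target
(−1.48 recovered for −2.0 planted at w = 1.0 on the single-site system,
vs −1.83 at w = 2.0); 2.0 Å keeps the estimator's intrinsic shallowness
within ~0.2 kcal/mol. Preset *clustered* fixtures use 1.0 Å kernels
instead, because five sites ~3.3 Å apart must remain distinct minima after
their energy bumps sum — their per-hotspot energies are correspondingly
shallower, which the truth bookkeeping accepts since those fixtures test
detection (precision/recall), not per-site ΔG recovery.

Preset fixtures carve *buried* cavities (carve-sphere centers below the
surface, so the mouth is narrower than a hemisphere and buriedness lands
near 0.66, robustly on the "buried" side of the 0.5 threshold —
a surface-tangent hemispherical groove sits exactly at ~0.5 and makes the
geometry filter a coin flip). The two-pocket preset plants five sites
(3 + 2 channel split) in each of two opposite cavities ~40 Å apart along
the surface; the three-site preset probes the minimum-density rule; the
background preset has no sites at all.

What passing on these fixtures does **not** show: real occupancy maps have
anisotropic, multi-modal basins, correlated frames, probe-probe exclusion,
and conformational averaging — none of which the Poisson/Gaussian model
emulates. Recovery numbers here validate the pipeline's bookkeeping and
geometry, not force-field-level accuracy.

## Numerical choices

- Boltzmann averages and weights are computed with the minimum energy
  shifted out of the exponent (no overflow for any finite input).
- Selection ties break on the flat voxel index; component labeling uses
  scipy.ndimage with a full 3×3×3 structuring element; assembly and merge
  ties break on lowest hotspot id — every stage is deterministic, and rerun
  outputs are byte-identical (fixed decimal formatting, sorted JSON keys,
  no timestamps).
- A* and the uniform-cost searches keep g-scores in dense arrays over the
  lattice; the Euclidean heuristic is computed in index space times
  spacing, so grid origin cancels.
- XPLOR maps index the lattice on integer cell fractions; the writer rounds
  the origin to the nearest multiple of the spacing and stores values as
  `%12.5E` (≈ 6 significant digits). DX is the lossless dialect.
- Degenerate inputs raise early with specific messages: empty structures,
  grids with no favorable voxel, sites planted inside the protein,
  non-integer occupancy counts, asymmetric distance matrices.

## Parameters at a glance

| parameter | default | units | meaning |
|---|---|---|---|
| `top_fraction` | 2×10⁻⁴ | — | favorable-voxel selection per channel |
| `temperature_K` | 300 | K | analysis temperature |
| `cap_kcal` | 3.0 | kcal/mol | energy for unobserved voxels |
| `probe_radius` | 1.4 | Å | solvent probe above vdW surface |
| `shell_max` | 3.0 | Å | shell thickness for surface paths |
| `snap_max` | 2.0 | Å | endpoint snap tolerance |
| `link_distance` | 6.0 | Å | hotspot linking threshold |
| `min_density` | 4 | — | minimum hotspots per pocket |
| `volume_cap` | 500 | ų | maximum (merged) pocket volume |
| `merge_distance` | 8.0 | Å | merge eligibility between candidates |
| `sphere_radius` | 2.0 | Å | per-hotspot sphere for volume |
| `polarity_min_fraction` | 0.2 | — | minority-channel share |
| `buriedness_threshold` | 0.5 | — | geometry filter cutoff |
| `ray_count` / `ray_reach` | 146 / 8.0 | — / Å | buriedness ray casting |
| `distance_horizon` | 12.0 | Å | surface-search cutoff (> merge) |
| polar / hydrophobic tolerance | 0.5 / 1.0 | Å | pharmacophore restraints |
| cavity radius | 8.0 | Å | docking cavity around hotspots |

## Known limitations

- Surface distances live on a lattice, not a triangulated molecular
  surface; absolute geodesics carry the lattice-metric overestimate.
- Buriedness is evaluated at a single centroid; concave, elongated pockets
  may need per-hotspot evaluation (the raw value is reported for auditing).
- The XPLOR writer cannot represent origins off the spacing lattice.
- Only two probe channels are modeled; probes beyond a polar/hydrophobic
  split (e.g. charged probes) are out of scope.
- Multi-conformation input expects one PDB per conformation with consistent
  chains; MODEL records beyond the first are ignored.
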