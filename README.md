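# solvmap

Identification of ligandable binding pockets on protein surfaces from
mixed-solvent molecular dynamics (cosolvent MD) occupancy maps.

In a cosolvent simulation — e.g. a protein in a 1:4 ethanol–water box — the
organic probe accumulates where it interacts favorably with the surface.
Counting probe atoms per grid voxel over the trajectory, split into a
*polar* channel (the hydroxyl group) and a *hydrophobic* channel (the alkyl
tail), yields occupancy maps whose local enrichment encodes binding free
energy through the inverse-Boltzmann relation

&nbsp;&nbsp;&nbsp;&nbsp;ΔG<sub>i</sub> = −RT·ln(n<sub>i</sub> / n<sub>bulk</sub>)

per voxel *i*. `solvmap` turns such maps (plus the protein structure) into a
ranked list of *pockets* — groups of interaction hotspots that are close
along the protein surface, compact in volume, balanced between polar and
hydrophobic character, and geometrically enclosed enough to hold a
drug-like molecule — and exports pharmacophore restraints and a cavity
definition for restrained docking. It is aimed at structure-based drug
discovery work (e.g. finding tractable sites on E3 ubiquitin ligases for
targeted protein degradation) where the question is *where* on a protein a
small molecule could bind, before any docking or screening is attempted.

The pipeline:

1. **Pooling & conversion** — replica occupancy grids are summed per
   channel and converted to energy grids (zero-count voxels are capped at
   +3 kcal/mol so grids stay finite).
2. **Hotspot extraction** — the top 0.02 % most favorable voxels per
   channel are clustered into 26-connected components; each component is a
   *hotspot* with a Boltzmann-averaged energy and Boltzmann-weighted
   centroid.
3. **Surface distances** — a solvent-shell graph is built above the
   protein's van der Waals + probe surface and hotspot-to-hotspot geodesics
   are computed with A* (admissible Euclidean heuristic, so paths are
   optimal). Paths cannot tunnel through the protein or shortcut through
   bulk solvent. With several conformations, the per-conformation matrices
   combine by element-wise minimum.
4. **Pocket assembly** — hotspots within 6 Å surface distance are linked;
   components with ≥ 4 hotspots become pocket candidates; nearby candidates
   merge greedily while the union-of-spheres volume stays ≤ 500 ų.
5. **Filtering & ranking** — pockets must balance polar and hydrophobic
   hotspots and be buried (ray-casting enclosure ≥ 0.5); survivors are
   ranked by summed hotspot energy (ΔG sum), with *hotspot efficiency* =
   ΔG sum / hotspot count reported alongside.
6. **Export** — the strongest hotspots per channel become pharmacophore
   restraints (tolerance 0.5 Å polar / 1.0 Å hydrophobic) plus an 8 Å
   docking cavity definition.

A synthetic-data generator (`solvmap.synthetic`) builds toy proteins and
occupancy grids with *planted* enrichment sites whose depth encodes a known
ΔG, so the whole pipeline is testable — and its parameter recovery
measurable — without running any MD.

## Worked example

Generate a synthetic system with two planted five-hotspot pockets in buried
cavities on opposite sides of a toy protein, then run the full pipeline:

```bash
solvmap simulate --preset two-pockets --out fixture
cat > config.toml <<EOF
structures = ["fixture/structure.pdb"]
polar_grids = ["fixture/polar.dx"]
hydrophobic_grids = ["fixture/hydrophobic.dx"]
out_dir = "out"
n_frames_per_replica = 15000
bulk_expected = 20.0
EOF
solvmap run --config config.toml
```

which prints

```
10 hotspots, 2 pockets (2 ligandable) -> out
```

and writes `out/pockets.tsv`:

```
label  n_hotspots  n_polar  n_hydrophobic  dg_sum  efficiency  volume   buriedness  passed_polarity  passed_geometry  ligandable  hotspot_ids
A      5           2        3              -8.572  -1.714      155.500  0.664       True             True             True        0,4,5,7,8
B      5           3        2              -8.563  -1.713      156.125  0.658       True             True             True        1,2,3,6,9
```

Both planted pockets are recovered: five hotspots each (the generator
planted five −2.0 kcal/mol sites per cavity; the Boltzmann average over a
hotspot's member voxels is slightly shallower than its deepest voxel, hence
ΔG sums around −8.6 rather than −10), volumes far under the 500 ų cap,
polar/hydrophobic balance and buriedness ≈ 0.66 passing both ligandability
filters. `out/pharma/pocket_A_restraints.txt` holds the docking restraints,
one feature per line (`x y z tolerance type`):

```
2.521 0.800 7.980 0.500 Any
1.503 -2.158 8.022 0.500 Any
-2.565 0.794 8.026 1.000 Hyd
-1.504 -2.033 8.010 1.000 Hyd
```

and `pocket_A_cavity.txt` the cavity reference point with its 8 Å radius.

Thermodynamic helpers follow the Gibbs relation ΔG = RT·ln(K<sub>d</sub>/1 M):

```python
>>> from solvmap import affinity_convert
>>> round(affinity_convert(51e-6, "kd_to_dg", temperature_K=298.0), 2)
-5.85
```

## File formats

- **Grids**: OpenDX (`.dx`, read/write via GridDataFormats) and ASCII
  XPLOR/CNS maps (`.xplor`/`.cns`, built-in reader/writer; ZYX section
  order, `%12.5E` values). Units Å and kcal/mol throughout.
- **Structures**: fixed-column PDB (ATOM/HETATM); waters/heteroatoms are
  excluded by default.
- **Tables**: TSV (hotspots, surface distances, pocket report).
- **Restraints**: plain text, `x y z tolerance type` with 3-decimal
  coordinates; types `Don`/`Acc`/`Any` (polar) and `Hyd` (hydrophobic).

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.
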