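# channelgate

Trajectory analyses for voltage-gated proton-channel (Hv1-type) gating:
continuous water-wire detection, hydrogen-bond / salt-bridge tracking,
helix and sidechain z-kinematics, and pore-radius profiling — plus a
ground-truth synthetic trajectory generator so every stage is testable
without molecular-dynamics data.

**Who it is for.** Researchers who have MD trajectories of a
voltage-sensor-domain channel (or any near-axial membrane pore) and want
the standard gating readouts as reproducible numbers and CSVs: what
fraction of frames carry a membrane-spanning water wire, which helices
moved along the membrane normal and by how much, which salt-bridge
partners switched, and whether the pore is wide enough for water.
`channelgate` analyzes trajectories; it does not run MD.

## The core computations

*Water wire.* A frame carries a continuous water wire when the water
oxygens inside the channel (a cylinder about the pore axis) form a chain
connecting the extracellular side (z ≥ z_hi) to the intracellular side
(z ≤ z_lo) with every adjacent O–O distance < 3.4 Å.  The occupancy —
the fraction of analyzed frames with a wire — is the headline gating
readout, since a spanning hydrogen-bonded water chain is the structural
prerequisite for Grotthuss proton conduction.

*Kinematics.* Helix displacement is the z of each helix's Cα centroid
relative to the pooled four-helix Cα centroid (S1 97–120, S2 133–157,
S3 166–188, S4 193–214 by default); sidechain tracks are measured after
Kabsch superposition on an anchor residue (Asp108 by default).
Coordinates are Å and z increases toward the extracellular side.

*Interactions.* A hydrogen bond requires donor–acceptor distance
≤ 3.4 Å and D–H···A within 30° of linear; salt bridges are the
Arg/Lys → Asp/Glu subset, summarized as per-pair occupancies and
dominant partners.

*Pore profile.* Per z-slice, the radius of the largest sphere centered
in the slice plane touching no atom,
`radius(z) = max_c min_i (|c − x_i| − vdw_i)`, found by a deterministic
branch-and-bound search (a reproducible, slice-planar take on the HOLE
profiler).  A pore is passable for water when the minimum radius
reaches 1.15 Å.

*Electrostatics helpers.* Transmembrane field bookkeeping E = V/z
(default 36 Å membrane) and Henderson–Hasselbalch peptide charge / pI
with bundled EMBOSS- and Lehninger-style pKa tables.

## Worked example

```python
import numpy as np
from channelgate import (SyntheticSpec, generate_trajectory,
                         occupancy_series, helix_z_series, pore_profile,
                         min_radius_and_passability, field_magnitude)

# synthetic 100-frame trajectory: wire planted in 30% of frames,
# S4 helix stepped up by 2 Å at mid-trajectory
sched = np.zeros(100); sched[50:] = 2.0
spec = SyntheticSpec(n_frames=100, seed=7, wire_fraction=0.3,
                     helix_schedules={"S4": sched})
traj, manifest = generate_trajectory(spec)
channel = spec.channel()

wire = occupancy_series(traj, channel)
print(f"wire occupancy: {wire.occupancy:.2%}  "
      f"longest run: {max(wire.run_lengths)} frames")

helices = helix_z_series(traj, channel)
print("final helix displacement (A):",
      ", ".join(f"{k} {s.final_mean():+.2f}" for k, s in helices.items()))

profile = pore_profile(traj.frame(0), channel)
rmin, zmin, ok = min_radius_and_passability(profile)
print(f"min pore radius: {rmin:.2f} A at z = {zmin:+.1f} A  "
      f"({'passable' if ok else 'not passable'} for water)")

print(f"field at 250 mV: {field_magnitude(250).magnitude_mV_per_A:.3f} mV/A")
```

prints

```
wire occupancy: 30.00%  longest run: 3 frames
final helix displacement (A): S1 -0.50, S2 -0.50, S3 -0.50, S4 +1.50
min pore radius: 3.38 A at z = +5.5 A  (passable for water)
field at 250 mV: 6.944 mV/A
```

The occupancy equals the planted fraction exactly (30%).  The +2 Å shift
of S4 alone appears as +1.5 Å for S4 and −0.5 Å for the other three
helices, because displacements are measured relative to the four-helix
center (with equal Cα counts, a 2 Å shift of one helix moves that center
by 0.5 Å).  The 3.38 Å minimum radius sits at a gate-residue slice of
the synthetic scaffold, comfortably above the 1.15 Å water threshold.

## Command line

```sh
channelgate synth --spec spec.yaml --out synth/      # trajectory + manifest
channelgate run   --config run.yaml                  # full pipeline, CSV + JSON
channelgate pore  --pdb synth/trajectory.pdb         # one-shot pore profile
```

`run` emits, per condition: the occupancy stripe CSV and summary, helix
displacement CSVs, sidechain z-tracks, H-bond series and the
salt-bridge partner table, gate z-gap CSVs, pore profiles, the field
magnitude, and a machine-readable `index.json`.  Outputs use fixed
6-decimal formatting: re-running an identical configuration reproduces
byte-identical files.

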