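# loopconf

Conformational-state analysis of protein loop trajectories.

Flexible surface loops — such as the BC-loop of the immune checkpoint
receptor PD-1, whose conformation differs between the unbound receptor,
the PD-L1 complex and the nivolumab complex — often populate a small
number of discrete conformations, and the fraction of simulation time a
loop spends in each conformation depends on the binding partner.
`loopconf` implements the full analysis chain used to quantify this from
molecular-dynamics-style trajectories:

1. **Superposition and descriptors.** Least-squares rigid-body fitting
   (Kabsch, proper rotations only) of every frame onto a reference over a
   *fit* selection (typically the flanking Cα backbone), then

   - per-atom fluctuation
     `RMSF(x) = sqrt( (1/T) Σ_t ||x(t) − x̄||² )`, and
   - frame-to-reference deviation over a *measure* selection (the loop)
     `RMSD = sqrt( (1/N) Σ_i ||x_i − x_i^ref||² )`.

2. **Conformational clustering** of the all-against-all loop RMSD matrix
   by the greedy neighbour-counting (Daura/GROMOS) algorithm: the frame
   with the most neighbours within a cut-off (default 0.2 nm) founds a
   cluster, the cluster is removed, repeat. Cluster sizes measure
   residence times; per-system composition shows which conformations the
   systems share.

3. **Meta-structure by non-metric MDS.** The RMSD submatrix over the top
   cluster centres (default 25) is embedded in 2D by minimizing Kruskal
   stress-1 with isotonic disparities; single-linkage components at a
   distance threshold group nearby centres into meta-clusters, and
   per-system meta-cluster residence times are accounted.

4. **Interactions.** Geometric hydrogen-bond detection between two atom
   groups (donor–acceptor ≤ 0.35 nm, hydrogen within 30° of the
   donor→acceptor axis) and short-range non-bonded energies
   `E = Σ f q_i q_j / r_ij + Σ (C12_ij/r_ij¹² − C6_ij/r_ij⁶)` with
   geometric-mean combination and a 1.4 nm cut-off, summarized as
   per-frame histograms.

Because the original MD trajectories behind such studies are rarely
deposited, the package ships a synthetic generator
(`loopconf.synthetic`) that plants K loop conformations with chosen
occupancies on a hairpin scaffold, so every stage is testable end to end
against known ground truth.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
bundled three-system plan (an apo receptor, a ligand that induces a
unique loop conformation, and a ligand that locks the shared one);
outputs land in `results/analysis/`:

```sh
python analysis/01_simulate.py      # 3 systems x 400 frames, PDB + sidecar
python analysis/02_flexibility.py   # per-system RMSF
python analysis/03_cluster.py       # RMSD matrix, Daura clusters, sweeps
python analysis/04_ordination.py    # MDS embedding + meta-clusters
python analysis/05_interactions.py  # H-bonds + non-bonded energies
```

`02_flexibility.py` prints, per system, the mean loop vs scaffold RMSF —
the loop's apparent flexibility reflects hopping between planted
conformations:

```
apo:  loop RMSF 0.320 nm vs scaffold 0.009 nm
ligA: loop RMSF 0.426 nm vs scaffold 0.009 nm
ligB: loop RMSF 0.100 nm vs scaffold 0.009 nm
```

`03_cluster.py` finds 6 clusters at the 0.2 nm cut-off (one per planted
conformation) and shows their per-system composition; `04_ordination.py`
embeds the 6 centres (stress ≈ 0) and groups them into 3 meta-clusters,
printing the per-system residence fractions:

```
        meta_0  meta_1  meta_2  unassigned
apo       0.18    0.82    0.00         0.0
ligA      0.65    0.00    0.35         0.0
ligB      1.00    0.00    0.00         0.0
```

i.e. the apo system spends ~80% of its time in its own meta-cluster and
~20% in the shared one, ligand A ~70% shared / ~30% unique, and ligand B
is locked (100%) into the shared meta-cluster — the planted pattern,
recovered blindly from coordinates.

The same pipeline is available as a single command with a reproducible
manifest (`loopconf run --out <dir> --seed <n>`), and each stage as a
composable subcommand (`simulate`, `rmsf`, `cluster`, `mds`, `hbonds`,
`energies`).

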