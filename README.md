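# glutencg

Coarse-grained Monte Carlo modelling of wheat storage proteins.

Gliadins and low-molecular-weight glutenin subunits (LMW-GS) are
intrinsically disordered seed proteins: proline/glutamine-rich repeats,
a handful of cysteines that form the disulfide crosslinks behind gluten
networks, and very few charged residues.  `glutencg` is a reusable
pipeline for studying their conformational ensembles:

- **Sequence profiling** — Kyte–Doolittle/Rose sliding-window hydropathy
  (ProtScale convention, window 15), charge census, and the Das–Pappu
  diagram-of-states classification (R1–R5).
- **Bead-chain simulation** — one bead per mature residue (radius 2 Å,
  harmonic bonds around 4.1 Å), hard-sphere excluded volume, an extended
  Debye–Hückel potential `u/k_BT = z_i z_j (l_B/r) e^{-(r-σ)/λ_D} / (1+σ/2λ_D)`
  with implicit 1:1 salt (λ_D = 3.04/√c Å) and explicit neutralizing
  counter-ions, in a periodic 1500 Å cubic box.  Canonical Metropolis
  sampling with single-bead, pivot, crankshaft, whole-chain, and
  counter-ion moves; optional simulated-annealing ladder (default ten
  temperatures, 400→300 K).  Disulfide bonds are permanent stiff
  harmonic restraints between cysteine beads.
- **Ensemble analysis** — radius of gyration `R_g` and its distribution,
  shape factor `R_shape = ⟨R_ee²⟩/⟨R_g²⟩` (≈1 globule, ≈6 random walk,
  ≈12 rod), Flory exponent ν from `R_g = R_0 N^ν` (R_0 = 2 Å), Debye
  scattering `I(q) = Σ_ij sin(q r_ij)/(q r_ij)` with dimensionless
  Kratky plots, residue contact maps, and cysteine contact networks.
- **Synthetic data** — gluten-like sequences with controlled repeat
  content, cysteine contexts and net charge, plus rod / freely-jointed /
  self-avoiding reference chains with known statistics, so everything is
  testable without downloads.

## Worked example

```bash
glutencg synth --length 120 --n-repeat-motifs 4 --n-cys-hydrophobic 3 \
    --n-cys-hydrophilic 1 --net-charge 1 --n-negative 2 --seed 7 --out gluten.fasta
glutencg profile gluten.fasta --out profiles
glutencg simulate gluten.fasta --salt 80 --sweeps 1500 --equil 400 --seed 7 --out ens.npz
glutencg analyze ens.npz --out analysis
```

prints

```
wrote synthetic_gluten_seed7 (120 aa) to gluten.fasta
synthetic_gluten_seed7: length 120, hydropathy index -0.08 (variation 4.24), net charge +1, region R1
saved 150 frames to ens.npz; mean Rg 34.7 Å, drift 3.87e-12 kT
mean Rg 34.7 Å, R_shape 6.55, nu 0.60
```

Reading the numbers: the synthetic 120-mer is a weak polyampholyte
(region R1 of the diagram of states, like the real storage proteins);
after 1500 production sweeps at 80 mM salt the ensemble-mean radius of
gyration is 34.7 Å, the shape factor 6.55 sits near the random-walk
value of 6, and the single-point Flory exponent 0.60 indicates an
expanded, good-solvent-like chain — exactly what a low-charge
hard-sphere chain without attractions should do.  The energy drift
(incremental bookkeeping vs. full recomputation) of ~4e-12 k_BT
confirms exact Metropolis accounting.  `glutencg run config.yaml`
drives the full study (salt scans, with/without disulfide restraints)
from a single YAML file, and `glutencg report` tabulates mean Rg,
variance, ν and R_shape per condition.

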