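# Methods

## Scope and model

`glutencg` models intrinsically disordered wheat storage proteins
(gliadins, LMW glutenin subunits) at one bead per amino acid.  A bead is
charged (+1 for Arg/Lys, −1 for Asp/Glu by default) or neutral; there is
no hydrophobic attraction term, so the chain physics is that of a
weakly charged excluded-volume polymer.  The model is deliberately
minimal: its purpose is to isolate what electrostatics and disulfide
topology alone do to the conformational ensemble, which is why a salt
scan on a low-charge sequence is expected to show almost no effect.

Energy terms (all energies in units of k_BT at the 298 K reference;
other temperatures enter the acceptance rule as a T_ref/T rescaling):

- **Bonds**: harmonic, ½k(b − b₀)² with b₀ = 4.1 Å (Cα–Cα-like spacing)
  and k = 30 k_BT/Å².  k was chosen so the thermal bond-length standard
  deviation √(k_BT/k) ≈ 0.18 Å is below 5 % of b₀; whether the original
  coarse-grained study used rigid or harmonic bonds is not documented,
  and equilibrium chain statistics are insensitive to this choice.
- **Excluded volume**: hard spheres of radius 2 Å on every particle
  pair; overlap is an automatic Metropolis rejection (flagged as an
  infinite excluded-volume term in energy breakdowns).
- **Electrostatics**: extended Debye–Hückel,
  u/k_BT = z_i z_j (l_B/r)·exp(−(r−σ)/λ_D)/(1 + σ/2λ_D), σ = 2R = 4 Å,
  Bjerrum length l_B = 7.14 Å (water, 298 K; the temperature dependence
  of the dielectric constant is out of scope).  The Debye length follows
  the 1:1-salt formula λ_D = 3.04/√(c/M) Å, covering the scanned series
  10/80/500/1000 mM (30.4/10.7/4.3/3.0 Å).  Salt is implicit;
  counter-ions (one monovalent ion per unit of net chain charge,
  opposite sign) are explicit and interact through the same potential,
  giving an electroneutral periodic box (1500 Å cube, minimum-image
  convention).
- **Disulfide restraints**: permanent harmonic restraints
  ½k(r − r₀)² between designated cysteine beads, active throughout the
  run.  The experimental S–S distance (~2 Å) is geometrically forbidden
  between 2 Å-radius bead centres, so the default target is the contact
  distance r₀ = 4.0 Å with k = 10 k_BT/Å² — stiff enough that restrained
  pairs register as permanent contacts (RMS fluctuation ~0.3 Å), which
  preserves the topological intent (a covalently closed loop) in the
  bead representation.  Both target and stiffness are configurable.

Coordinates are stored unwrapped and wrapped only on export.  Because
the box is large compared with sampled chain sizes, the nearest-image
energy is identical either way, and unwrapped storage keeps rigid-move
bookkeeping exact.

## Monte Carlo sampling

Canonical Metropolis with a configurable move mix: single-bead
translation (45 %), pivot (20 %), crankshaft (20 %), whole-chain
translation (3 %) and rotation (4 %), counter-ion translation (8 %).
The original study's all-atom move set (side-chain rotations, biased
Gaussian steps) has no meaning for beads; equilibrium averages are
move-set independent, so the standard coarse-grained set is used.  A
sweep is one attempted move per particle; one configuration is produced
per sweep and every 10th is saved by default.

ΔE for a trial move is evaluated over the complete set of pair terms
involving moved particles (a compiled numba kernel, with a vectorized
numpy fallback), so unchanged pairs cancel identically: the running
total agrees with a full recomputation to ~1e-12 k_BT after 10⁵ moves,
and the test suite enforces < 1e-6.  During equilibration, step sizes
are nudged toward 30–50 % acceptance every 50 sweeps and then frozen,
so production is strictly canonical.

Simulated annealing follows the generic ladder of the study protocol:
ten temperatures descending 400→300 K, 1000 configurations per
temperature per cycle; only target-temperature configurations enter the
returned ensemble.  The bookkeeping (200 cycles → 2×10⁵ configurations
at 300 K, 800 → 8×10⁵) is exposed on the schedule object and tested
there; actual test runs use scaled-down ladders.  Salt scans derive one
child seed per salt from the master seed via `SeedSequence.spawn`, so
runs are independent but reproducible.

## Sequence statistics

Hydropathy profiles follow the ProtScale convention: only full windows
are scored (length − window + 1 positions), the unweighted window mean
is assigned to the centre residue, and the default window is 15.  The
accumulated hydropathy index is the arithmetic mean of the windowed
profile over the mature (signal-peptide-trimmed) sequence.  "Variation"
is reported as the population variance of the profile, with sample
variance and standard deviation alongside, because the term is not
defined in the source literature; it is therefore not used as a
quantitative target.

The charge scheme defaults to Arg/Lys +1, Asp/Glu −1, His and termini
neutral, with His-protonation and charged-termini switches.  Das–Pappu
regions use FCR = f₊ + f₋ boundaries: R1 (FCR < 0.25), R2
(0.25 ≤ FCR ≤ 0.35), R4 (f₊ > 0.35, f₋ ≤ 0.35), R5 (mirror image), R3
otherwise.  Values exactly on the 0.25/0.35 boundaries classify into
the weaker-charge region listed first by these inequalities.

## Synthetic data

`generate_gluten_like_sequence` emulates the statistical structure of
prolamin sequences rather than any particular accession: a P/Q-rich
N-terminal repeat domain built from hepta-/dodecapeptide motifs
("PQQPFPQ", "PQQPQQPFPQQP" by default), cysteines embedded in 7-residue
uniformly hydrophobic (I/V/L/F) or hydrophilic (S/N/Q/T) flanks so a
window-15 profile classifies them unambiguously, Lys/Glu placed to hit
an exact target net charge, and neutral filler.  Defaults (265 residues,
8 cysteines, net +1) mirror a mature α-gliadin-scale chain.  What the
generator does *not* emulate: real repeat-length polymorphism, His
content, and the specific hydropathy landscape of the accessions —
tests passing on synthetic sequences therefore validate the machinery
and the qualitative physics, not accession-specific numbers.

Reference conformations: collinear rods; freely-jointed chains
(independent uniform bond directions; ⟨Ree²⟩ = (n−1)b²,
⟨Rg²⟩ = (n²−1)b²/6n); and hard-sphere self-avoiding chains produced by
the pivot algorithm from a rod start with 10·n accepted moves discarded
(validated by recovering ν ≈ 0.59).  Pivot samples are taken 10
accepted moves apart; radius 0.4·b gives strong excluded volume and
high pivot acceptance.

## Observables and numerical choices

- R_ee uses the first and last chain beads (the bead analogue of
  terminal α-carbons).
- The Flory fit supports single-point inversion ν = ln(R_g/R₀)/ln N
  (R₀ = 2 Å, the convention for the reported exponents) and log-log
  regression.  Regression defaults to a *free* intercept: pinning the
  intercept at ln R₀ biases the slope whenever the chain model's own
  prefactor differs from R₀ (an ideal chain with b = 4.1 Å has prefactor
  1.67 Å, a −0.03 slope bias over n = 50–400), and the exponent — not
  the amplitude — is the quantity of interest.  Fixed-intercept mode is
  available and verified on constructed power laws.
- Debye scattering uses unit form factors, the analytic sinc limit at
  q = 0, ensemble-averaged intensity, and I₀ = N².  Kratky curves are
  normalized by the ensemble-mean R_g.  The Gaussian-chain Kratky
  plateau ((qR_g)²·I/I₀ → 2) is only reached while q stays below the
  bond scale; for a discrete chain this requires qb ≲ 1.3 across
  q·R_g ∈ [5, 15], i.e. n ≳ 800 beads — the plateau test uses 800-bead
  chains for this reason, with the closed-form ⟨Rg²⟩ as normalization
  to avoid blurring by finite-ensemble noise.
- Contact maps count bead-centre distances below 8 Å, excluding
  |i−j| ≤ 1.  The 5 Å criterion of the all-atom analysis refers to
  side-chain heavy atoms; between bead centres the equivalent
  contact shell is bead contact (4 Å) plus side-chain reach, hence the
  8 Å default (configurable).  Cysteine networks are the restriction of
  the map to cysteine pairs; vicinal pairs are excluded by the same
  adjacency rule.
- Guinier fits use ln I vs q² on q·R_g < 1 and agree with the direct
  R_g within 5 % on single conformations and sampled ensembles.

## Problem sizes used in the tests

The statistical-mechanics checks run at desk scale, chosen for
convergence of the asserted statistic: the Boltzmann dimer samples
~10⁴ decorrelated bond lengths out of 2×10⁵ moves (χ² against the
r²-weighted Boltzmann density, p > 0.01); the restrained/unrestrained
comparison and salt scan use a 110-residue gluten-like sequence with
4 cysteines, ~1500 production sweeps, 150 saved frames; Flory anchors
use 2000 ideal chains per length and 1500 pivot-decorrelated SAW
configurations per length at n = 50–400.  The all-atom force-field
results of the original study (mean R_g ≈ 44–48 Å, R_shape ≈ 2–5,
secondary structure) depend on atomistic energetics outside this
model's scope and are treated as qualitative patterns only: restraints
must compact the ensemble and narrow its R_g distribution, contact maps
must light up at restrained pairs, and low-charge chains must be
salt-insensitive (< 10 % spread in mean R_g across 10–1000 mM).

## Known limitations

- No hydrophobic or hydrogen-bond attractions: the chains never
  collapse, so globular shape factors (~1–3) are out of reach by
  construction.
- Counter-ion treatment is hybrid (explicit ions inside an implicit
  screened solvent), inherited from the modelled study design.
- The discrete bead chain distorts scattering beyond q ≈ 1/b.
- Single chains only: no inter-chain disulfides or polymerization,
  although the LMW-GS biology that motivates them is summarized in the
  sequence-profiling layer (cysteine context classification).
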