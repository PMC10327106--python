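# Methods

## Scope and design

`memfield` implements a reduced implicit-membrane composite score — three
membrane terms combined linearly — together with the calibration and
benchmark machinery around it. It does **not** implement an all-atom
soluble-protein score (van der Waals, hydrogen bonds, torsions, reference
energies); a callback hook lets users add one. Consequently absolute
energies and absolute tilt angles of published all-atom benchmarks are out
of scope here; what the package reproduces are the analytic properties of
each term, the calibration procedures, and qualitative physics
(hydrophobic mismatch, head-group ordering of bilayer potentials, charged
side-chain behavior).

## Membrane geometry and hydration

The membrane is a rigid slab: center, unit normal, hydrophobic
half-thickness `t/2` (per lipid: DLPC/DLPG 10.8 Å, DLPE 11.2 Å, DOPC
13.6 Å, POPC 13.7 Å, DPPC 14.4 Å — nominal hydrophobic half-thicknesses,
user-overridable). Hydration is logistic in |depth|,

    f_hyd(z) = 1 / (1 + exp(-(|z| - t/2) / s)),   s = 2 Å by default,

so f_hyd ≈ 0 at the core, 0.5 at the hydrophobic boundary and → 1 in
water. A water-filled pore (axis + radius) contributes a radial sigmoid
combined with the depth term by maximum. Pair hydration is the geometric
mean of the two atomic fractions. Region labels follow fixed thresholds:
f_pore > 0.5 → aqueous; otherwise f_hyd < 0.25 lipid, f_hyd in
[0.25, 0.75] interface, f_hyd > 0.75 aqueous. The classifier is total on
[0,1]²; the corner cases (low hydration but open pore, high hydration but
closed pore) resolve to aqueous, since either condition means the side
chain sees water. Neighbor-count burial (as used by some all-atom
implementations) is not part of f_hyd; users needing parity with such
codes should supply their own hydration model.

## Bilayer potential

The mean-field potential of the empty water–bilayer system is obtained by
solving ∇²Ψ = −ρ/ε₀ spectrally on a periodic 3D charge-density grid
(e/Å³): Ψ̂(k) = 4π·14.3996·ρ̂(k)/k² volts, k = 0 mode zeroed (mean-free
gauge). Boxes with |net charge| > 1e-6 e are rejected unless uniform
background neutralization is requested. No Boltzmann mobile-ion term and
no interior dielectric heterogeneity: the solve is in vacuum permittivity
by design, so ionic-strength assumptions never enter; screening comes from
whatever ion density the input grid contains.

The plane-averaged profile Ψ(z) is fitted on |z| (symmetric leaflets) to

    Ψ̃(z) = A1 + (A1 - A2)/(1 + exp((z - A3)/A4))   for z >= zc
    Ψ̃(z) = C1 z⁴ + C2 z³ + C3 z² + C4 z + C5       for z <  zc

with the water reference Ψ(40 Å) = 0 and value continuity at the split
depth zc enforced by constraining C5. zc is initialized at the largest-z
stationary point of a 5-point moving-average smoothed profile, refined by
a bounded 1-D search on the total residual, then all parameters including
zc are polished jointly by least squares. The sigmoid branch uses
deterministic multi-starts (A4 ∈ {0.5, 1, 2, 4} × two A3 guesses). This
family is over-parameterized — distinct parameter vectors can produce
identical curves — so fit quality is judged by curve RMS, never by
parameter identity. Evaluation clamps to exactly 0 beyond the reference
depth; profiles evaluate symmetrically in ±z.

### Synthetic bilayer densities

The generator emulates head-group electrostatics with mirrored Gaussian
dipole sheets: a positive layer at t/2 + 2 Å (choline/amine) and a
negative layer at t/2 + 5 Å (phosphate), giving a positive dipole
potential at the core, ~0.54 V for PC at an effective (water-screened)
head charge of 0.10 e per 100 Å². PE packs 0.13 e/100 Ų into narrower
sheets — higher local charge density, hence a higher potential than PC.
PG adds a net-negative head layer neutralized by an adsorbed counterion
layer just outside it, which screens the potential below PC. Salt adds an
opposing double layer in the water region (Debye-like placement), lowering
|ΔΨ|. Boxes are neutral by construction (exact after discretization).
In a plane-averaged 1D geometry ΔΨ across a dipole layer depends only on
its first moment per area, which is why PE/PC must differ in charge
density, not merely sheet width. What this generator does *not* emulate:
explicit water ordering, carbonyl dipoles, interface deformation, or any
MD-derived density detail — passing tests therefore validate the solver,
fitting and term machinery, not agreement with simulated lipid profiles.
The shipped profile library (`data/lipid_profiles_synthetic.yaml`) is
generated by exactly this pipeline and is labeled synthetic.

## Energy terms

**Transfer.** Σ_atoms (1 − f_hyd)·ΔG_wl_atom: zero in bulk water, the full
water-to-bilayer transfer energy at the core. This hydration-complement
form is the simplest satisfying both limits; it is applied to all atoms
carrying parameters (hydrogens optional and absent from the shipped set).

**Lipid potential.** Σ_atoms q·ΔΨ(z)·23.0609 kcal/(mol·e·V), over all
charged atoms (a flag could restrict to side chains; all atoms is the
default since the backbone carries real partial charges).

**Excess dielectric Coulomb.** For pairs within r_max = 5.5 Å:

    ΔE_ij = C0 q_i q_j (1/r − 1/r_max) · (1/ε(r, f_ij) − 1/ε_sol(r)),
    ε(r, f) = f·ε_sol(r) + (1 − f)·ε_memb(r),

C0 = 322 Å·kcal/(mol·e²). Both sigmoids share midpoint 5.5 Å and
steepness 0.6 Å, chosen so ε_sol is mid-range (≈43) at the cutoff and
within 1 % of its core value at contact; both are configurable. Pairs
separated by ≤ 2 covalent bonds (1-2, 1-3; bonds detected by heavy-atom
distance, 1.95 Å cutoff, 2.25 Å for sulfur) are excluded — standard
practice, with a switch. The (1/r − 1/r_max) truncation makes the energy
value-continuous (not derivative-continuous) at the cutoff; no additional
switching function is applied.

## Parameters and calibration

`data/atom_params.tsv` is an authored, internally consistent united
heavy-atom set: per-residue charge sums equal formal charges exactly
(backbone N −0.30 / CA +0.30 / C +0.45 / O −0.45; charged termini via
NTER/CTER patches), and per-atom-type transfer energies are anchored to
published hydrophobicity-scale orderings (hydrophobic carbons −0.35…−0.9,
polar N/O +0.8…+1.3, carboxylate O +1.3, ammonium N strongly positive).
Alanine's per-residue sum is mildly favorable (−0.6 kcal/mol), consistent
with polyalanine forming transmembrane helices. The file format is
documented so force-field charge sets can be substituted.

The octanol side-chain scale in `data/ww_scale.tsv` carries the standard
published values; `data/mf_scale_synthetic.tsv` is an explicitly synthetic
stand-in for the bilayer-context scale (a linear transform of the octanol
scale, slope 1.8, with small residue offsets), adequate for exercising the
calibration machinery. Charged Asp/Glu transfer energies are obtained by
fitting bilayer ~ octanol over the shared residues *excluding* Asp and Glu
(whose bilayer measurements are low-pH protonation mixtures) and
evaluating the line at the octanol values of the charged species.

Per-atom-type transfer energies relate to per-residue values through the
stoichiometry matrix A (residues × atom types). With the shipped typing,
one-per-residue backbone types co-occur in every row, so A is
rank-deficient (rank 15 of 20): backbone types are not individually
identifiable from residue sums. The solver therefore raises with a
null-space report by default and offers a ridge (`regularization`)
option; appended rows for charged variants are supported by simply passing
the augmented system.

**Weight fitting.** The three composite weights maximize the Pearson
correlation with experimental mutation ΔΔG values under non-negativity.
Correlation is invariant to positive rescaling, so the constrained
maximizing direction is found in closed form by non-negative least squares
on centered data; a deterministic Nelder-Mead pass polishes it, and the
result is normalized to w_wl = 1. Rows for residues prone to overfitting
(Gly/Ala/Pro/Asp/Glu in the original protocol) are excluded via a mask
that provably cannot influence the objective. Datasets are pooled;
per-dataset centering is available.

## Orientation search

States are (z, tilt, spin): depth of the helix-axis midpoint, tilt of the
principal CA axis (oriented N→C) from the membrane normal folded into
[0°, 90°], spin about the axis. Search is an exhaustive deterministic grid
(z 1 Å over ±40 Å, tilt 2°, spin 10° by default) followed by a pattern
search polish (down to 0.25 Å / 0.5°) that never accepts a worse energy;
ties break by (|z|, tilt, spin). Grid + polish was chosen over Monte Carlo
for bit-reproducibility at peptide scale. Because the structure is rigid,
pair distances — and hence per-pair dielectrics — are precomputed once;
only per-atom depths change per state, so whole z-columns are evaluated
vectorized. The reported minimum is the single global grid minimum (no
spin averaging), with spin recorded.

`ddg_insertion` compares that minimum against the aqueous state, which has
exactly zero energy in the reduced composite and is always a member of the
candidate set — so insertion energies are never positive and an
unfavorable peptide is reported as expelled. `ddg_mutation` uses a fixed
backbone and fixed orientation: side chains are replaced from idealized
templates (biotite's bundled Chemical Component Dictionary geometry at
default conformations, grafted by N/CA/C superposition — no rotamer
repacking), and the water terms cancel by construction.

## Design metrics

Sequence recovery, KL divergence (natural log by default; the perplexity
definition is strictly base-2), per-type log-likelihood differences and
their sum, the design confusion matrix p(s|r), and per-native-residue
perplexity 2^H₂. Distributions are pooled across entries, as defined.
A pseudocount of 0.5 is added to the pooled distributions before
normalizing in `divergence` (warning if any probability shifts by more
than 1e-3); the confusion matrix reports raw normalized counts by default
(pseudocount opt-in) so that a perfect design yields the exact identity
matrix; rows with no native occurrences are omitted rather than
zero-filled. Region stratification uses the thresholds above; the
buried/surface split in the synthetic generator is a labeled Bernoulli
assignment (real-structure burial criteria are user-defined).

## Synthetic data generators

All generators are pure functions of (parameters, seed). The sequence-set
generator draws natives from a stated membrane-protein-like frequency
table and resamples non-recovered positions from the background
*excluding* the native residue, so measured recovery is exactly binomial
around the target (default 0.3, the scale of fixed-backbone design
protocols; default size 50 × 200 positions). The ΔΔG-set generator draws
term energies uniformly from ±5 / ±30 / ±100 kcal/mol — ranges that give
each term a visible share of the response under the calibrated weights —
and adds Gaussian noise (0.5 kcal/mol in the standard noisy setting,
comparable to experimental ΔΔG uncertainty).

## Numerical choices

* Constants: 1/(4πε₀) = 14.3996 V·Å/e; e·V → 23.0609 kcal/mol; C0 = 322
  Å·kcal/(mol·e²); r_max = 5.5 Å; water reference 40 Å.
* Poisson: k = 0 zeroed; net-charge tolerance 1e-6 e; validation against a
  real-space Ewald oracle (erfc image sum + reciprocal sum + background
  term + Gaussian-smearing correction, mean-free gauge) on 32³ grids
  agrees to ~1e-9 relative; the acceptance bound is 1e-5.
* Piecewise fit: fold grid equals the profile's own sample grid (no
  interpolation error); exact synthetic curves refit to ~1e-16 RMS.
* Sigmoid arguments are clipped at ±60 before exponentiation.
* Degenerate inputs: flat profiles short-circuit to a zero fit; empty PDB
  files, zero-length sequences, constant-x regressions, rank-deficient
  solves and singular (r = 0) pairs raise typed errors.
* Problem sizes in the validation suite (32³ solver boxes, 20 fit
  replicates, 1000-position metric fixtures, n = 100 weight fits, the
  AA20–AA40 series at 2-residue steps) were chosen as the smallest sizes
  at which each statistical bound is comfortably non-trivial.

## Known limitations

* No all-atom base score: absolute composite energies are not comparable
  to published all-atom benchmark values, and strongly hydrophobic
  peptides (long WALPs) are buried at high tilt.
* Rigid slab: no curvature, leaflet asymmetry, interface deformation, or
  pKa shifts; symmetric-leaflet fitting only.
* Fixed side-chain templates at default conformations; no repacking.
* Shipped charges, transfer energies, bilayer densities and the
  bilayer-context scale are synthetic stand-ins — internally consistent
  and clearly labeled, suitable for methodology validation, not for
  quantitative comparison with experiment without substituting measured
  parameter sets.
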