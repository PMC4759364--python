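# Methods

This note records the models, conventions and parameter choices behind
`hairpinlab`, in the order the pipeline runs them.

## Sequence census

A two-stranded antiparallel β-hairpin of length L pairs residue *i* of the
N-side strand with residue *L−i* of the C-side strand. For L = 19 the
register yields eight facing pairs (1,18)…(8,11); the central turn (9,10)
and the terminal residue 19 stay unpaired. Even-index pairs — (2,17),
(4,15), (6,13), (8,11) — carry the inter-strand backbone hydrogen bonds,
two per pair (one in each donor direction), labelled HB1…HB8 from the
termini inward. Odd-index pairs present their side chains to each other
and can form hydrophobic contacts.

Residues are classified into four groups: positive-polar (R, K, H),
negative-polar (D, E), uncharged-polar (S, T, N, Q, Y, C, W) and non-polar
(A, V, L, I, M, F, P, G). Tyrosine and cysteine are treated as uncharged
polar and proline/glycine as non-polar; histidine is grouped with the
positively charged residues. This is the standard assignment under which
the census reproduces the expected pair counts for both packaged peptides
(EF1: 3 hydrophobic pairs, 8 total; EF2: 2 and 6).

The ionic rule is a deliberate heuristic: a salt bridge is counted between
oppositely charged residues at most two positions apart, both inside the
central window 8…12 where the chain bends back on itself. For EF1 this
finds GLU9–ARG11 and nothing for EF2. It is positional, not
structure-derived, and is documented as such.

One ambiguity is resolved by construction: the innermost register pair of
EF2 is listed twice in the same donor direction in the source material;
`hairpinlab` emits HB8 as the reverse-direction bond (PHE11→ARG8),
matching the two-bonds-per-pair pattern of every other register pair.

## Structure model and I/O

Frames carry backbone N, H, CA, C, O plus one CB pseudo-atom per
non-glycine residue; coordinates are in nm internally (PDB I/O converts
to/from Å, giving 1 × 10⁻⁴ nm round-trip precision). Terminal caps, when
present in input files, are stored at residue indices 0 and L+1 and are
excluded from every analysis selection, so residue numbering matches the
uncapped 1…L convention.

The `main-chain` selection is {N, CA, O} — the amide nitrogen, chiral
carbon and carbonyl oxygen. The carbonyl carbon is not part of it by
default (pass `("N", "CA", "C", "O")` to include it); this matches the
convention used for the packaged analyses.

## Descriptors

RMSD uses a weighted Kabsch superposition (SVD-based, reflection
corrected) with fit and evaluation selections that default to the same
atom set. R_g is mass-weighted by default (switchable). RMSF is measured
about the iterated mean structure: frames are fitted, averaged, and
refitted to the average (two rounds), a common convention when no external
reference is given. Strand-split RMSF fits only one strand (e.g. residues
1–10) and reports fluctuations of either strand against that reference;
which strand the original analysis fitted for its C-side panel is not
documented, so both modes are exposed.

SASA is Shrake–Rupley with a deterministic Fibonacci sphere lattice
(default 960 points; bit-stable, no RNG), probe 0.14 nm, Bondi-type radii
for N/C/O and a three-class CB radius (small 0.20, medium 0.25, large
0.30 nm) standing in for the whole side chain. Because the radii set of
the original analysis is unknown and the model is coarse-grained, absolute
SASA values are internal indices, not literature-comparable numbers.

## Secondary structure and H-bonds

Backbone H-bonds use the Kabsch–Sander electrostatic energy with the
standard −0.5 kcal/mol cutoff. Missing amide hydrogens (coarse frames,
prolines excepted) are reconstructed 1.01 Å from N along the anti-bisector
of the two in-plane N bonds; prolines and the first residue never donate.
Assignment implements the antiparallel/parallel bridge patterns, E for
bridged residues with a bridged neighbour, B for isolated bridges, H/G
from consecutive 4-/3-turns, T for remaining turn residues, with priority
H > E > B > G > T > C. The β-sheet rate is the per-frame fraction of E
residues; counting B as sheet is a switch (default off) since either
reading of "β-sheet" is defensible.

Register-bond "length" is the H⋯O distance: formed bonds then sit at
~0.20 nm, which is the scale the published per-bond tables show (N⋯O
would be ~0.29 nm). Formation uses donor–acceptor ≤ 0.35 nm and H–N⋯O
angle ≤ 30°, the common MD-analysis convention, both configurable; the
original criterion is unstated.

## Autocorrelation and free-energy landscapes

The autocorrelation C(t) = (1/(N−j)) Σ f(iΔt) f((i+j)Δt) is provided
exactly as written (raw variant, which decays to the squared mean) and as
the mean-subtracted, C(0)-normalized variant that decays to zero; which
one produced the published figures is not stated, so neither is guessed.

The landscape is ΔG = −k_B T ln(P/P_max) with k_B = 0.0083145 kJ/mol/K;
the sign is fixed so that ΔG ≥ 0 with ΔG = 0 at the most populated bin,
which the "vicinity of the global minimum ≤ 1.5 kJ/mol" threshold language
requires. Binning defaults to 0.02 nm per axis over the padded data range
(0.04 nm in the desk-scale pipeline, where histograms are thinner); empty
bins are masked, not capped. Basins are 8-connected components of
sub-threshold bins; the reported RMSD/R_g ranges are the outer bin edges
of the component containing the global minimum. 8-connectivity tolerates
sparse desk-scale sampling.

## Synthetic-data generator

The generator exists to exercise every analysis stage with data that has
the right statistical structure: temperature-dependent hairpin fraying,
register-bond breakage, and a stability ordering between an 8-pair
(EF1-like) and a 6-pair (EF2-like) peptide. It is not a force field.

Chains are built from φ/ψ torsions (ω fixed trans) by internal-coordinate
construction with standard bond lengths and angles. The ideal 19-mer
hairpin uses packaged per-residue torsions — β-strand values plus a
two-residue turn — tuned once, off-line, so that all eight register H⋯O
distances close at 0.194–0.198 nm and pass both the geometric and the
Kabsch–Sander criteria; the tuning is not re-run at build time.

The energy is Gō-type, in reduced units (k_B = 1): one bounded Gaussian
well per census interaction — depth 1.0 per register H-bond at
r₀ = 0.20 nm (σ 0.05 nm), depth 1.5 per hydrophobic pair at the native
CB–CB distance r₀ = 0.38 nm (σ 0.12 nm), depth 1.5 per ionic pair at
r₀ = 0.50 nm — plus a soft-sphere CA–CA repulsion (onset 0.35 nm) for
residues more than two apart and a weak cosine bias (0.30 per torsion)
toward the ideal-hairpin torsions. Side-chain wells are deeper than a
single H-bond well because each stands for a whole side-chain contact.

Sampling is Metropolis Monte Carlo in torsion space (single-torsion and
crankshaft moves), with replica exchange over a temperature ladder:
alternating even/odd neighbour pairs, acceptance
min(1, exp[(β_i − β_j)(E_i − E_j)]). Ladder temperatures in Kelvin map
linearly to reduced sampler temperatures with 300 K ≡ 0.22 reduced units —
calibrated once so the fully stabilized hairpin is predominantly folded
but fluctuating at 300 K (β-sheet rate ≈ 0.35–0.45, 3–4 of 8 register
bonds formed on average) and substantially frayed at 450 K. The packaged
48-rung ladder mirrors the published protocol exactly; the desk-scale
default is an 8-rung ladder (300, 310, 322.5, 343, 367, 395, 422,
450.5 K), denser at the bottom and containing the four analysis
temperatures. Default runs take 400 snapshots per temperature at a
thinning of 10 sweeps with exchange attempts every 5 sweeps and the first
10 % discarded as burn-in; these sizes keep a full two-peptide contrast
under a few minutes on one CPU while leaving the directional statistics
well resolved. The sampler inner loop (chain build + energy + sweep) is
numba-compiled; runs are bit-reproducible for a fixed seed.

What the generator emulates: the census-driven stability contrast, thermal
fraying from the termini inward, exchange-driven mixing across
temperatures. What it does not: explicit solvent, realistic kinetics or
absolute time scales, side-chain rotamers, any force-field energetics —
so passing tests demonstrate that the *analysis* stages behave correctly
on data with the right structure, not that the model reproduces published
absolute trajectory statistics (whose values depend on μs-scale all-atom
simulation and are out of scope).

## Verification strategy

Every numerical stage is checked against an independent oracle: Kabsch
superposition against a brute-force quaternion search; SASA against
closed-form sphere and two-sphere lens areas; the autocorrelation against
hand-computed values and the AR(1) closed form ρ^lag; Boltzmann inversion
against quadrature of a known 2D double-well density sampled by an
independent Metropolis chain; the exchange rule against the exact
product-Boltzmann stationary distribution of a two-replica/two-state
system; secondary structure against builder-ideal hairpin and helix
geometry. The EF1-vs-EF2 contrast is asserted directionally over ten
shared-seed pairs (more H-bonds, narrower ΔG ≤ 2.5 kJ/mol basin, lower
Cα RMSF over residues 4–14 for EF1).

## Known limitations

- The census is positional; it cannot see non-register or
  structure-dependent contacts.
- The ionic rule is a documented heuristic with a fixed window.
- The coarse-grained SASA radii make absolute areas model-specific.
- DSSP codes cover E/B/H/G/T/C only (no π-helix, bends or ladder
  bookkeeping beyond what these require).
- FEL maps are built per temperature from demultiplexed samples; no
  WHAM/MBAR reweighting across the ladder.
- The sampler's reduced-unit temperature mapping is a calibration, not a
  physical Kelvin scale.
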