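# Methods

## Backbone model and construction

Peptides are represented by their backbone atoms N, CA, C, O (plus the
amide H where placed); side chains are not built. Chains are constructed
from internal coordinates by natural-extension (NeRF) placement with fixed
bond geometry: N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å;
angles N-CA-C 111.2°, CA-C-N 116.6°, C-N-CA 121.9°, CA-C-O 120.8°. The
peptide bond ω defaults to 180°. Residue 1 sits in a canonical frame (N at
the origin, CA on +x, C in the xy plane); every downstream observable is
invariant under rigid motion, so the frame choice is immaterial. The
carbonyl O of residue *i* is placed anti to the amide N of residue *i*+1
(torsion ψᵢ + 180°); the chain-terminal O, whose ψ is undefined, uses the
trans-like default. Build and measurement are exact inverses to well below
10⁻³ degrees.

Internal lengths are Å throughout; centre-of-mass distances and the
(RMSD, Rg) free-energy-surface axes are reported in nm, the unit
convention of the steered-simulation literature this pipeline mirrors.

## Helix parameters

Rise per residue and residues per turn come from a cylinder fit to the CA
trace. A short helix covers partial turns, so its centroid does not lie on
the helix axis and the principal axis of the coordinates is tilted; both
direction *and* offset must be fitted. The direction is initialised from
consecutive cross products of the trace's second differences (exact for an
ideal helix, where second differences point radially inward) and refined
by Nelder–Mead minimisation of the radial-spread about the least-squares
(Kåsa) circle centre in the perpendicular plane. Rise is the mean advance
of CA along the axis; twist is the mean angular step about the axis
oriented N→C, giving residues per turn = 360°/|twist| and handedness from
the twist sign. With the fixed bond geometry above, a chain built at
(−57°, −47°) measures 1.565 Å/residue and 3.62 residues/turn
(right-handed) and a chain at (−75°, 145°) measures 3.08 Å/residue and
2.99 residues/turn (left-handed) — the canonical α and PPII geometries to
within the precision such round figures are usually quoted at.

## Secondary structure

Hydrogen bonds use the Kabsch–Sander electrostatic model,
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, with a bond
accepted below −0.5 kcal/mol; distances closer than 0.5 Å clamp the energy
at −9.9 (the reference implementation's policy). Amide hydrogens, when
absent, are placed 1.0 Å from N anti-parallel to the preceding carbonyl;
prolines and the N-terminus carry none. Labels follow the DSSP pattern
rules: H from two consecutive 4-turns, G/I from 3-/5-turns, E from
parallel/antiparallel bridge patterns (isolated single bridges are folded
into E rather than kept as a separate B class), T for residues inside a
turn, S for CA-curvature bends above 70°. Where the 4- and 5-turn patterns
overlap, the π-helix label wins, matching the behaviour of current
reference implementations; on a 50-structure synthetic panel the assigner
agrees with the mdtraj DSSP implementation on ≈99% of residues (the test
suite requires ≥95%).

Ramachandran regions are boxes of half-width 30° (wrap-aware Chebyshev
distance) around α (−60°, −45°), β (−135°, 135°), PPII (−75°, 150°) and
left-handed α (+60°, +45°); ties break α > β > PPII > αL and everything
else is "other". The 30° half-width separates the α and PPII boxes on the
φ axis while covering the thermal spread of each state.

## Helicity statistics

Metric i is the per-frame mean fraction of residues labelled H, in
percent (pooling residue-frames would give the identical number for
equal-length frames). Metric ii is the percentage of frames whose H
fraction reaches 70%. Metric iii is the percentage of frames within 2 Å
CA RMSD of the ideal reference helix built at the window centres
(−57°, −47°) — the ±7° quoted with that definition is read as the
tolerance band of the ideal-helix dihedrals, not as a family of reference
structures. "Helical" throughout means DSSP H only; 3₁₀ (G) and π (I)
content is tabulated separately.

## Free-energy surfaces and basins

Surfaces are −ln(count/max count) over 2D histograms — 10° bins on the
(φ, ψ) torus, 0.05 nm bins in (RMSD, Rg) — so the global minimum is 0 and
empty bins are masked rather than pseudo-counted; only relative
populations are meaningful. Basins are found by steepest-descent
assignment on the grid: local minima within a seeding window (default
1.0 kT) of the global minimum seed basins, every occupied bin descends to
its sink, samples inherit their bin's assignment, and basins below a
population floor (default 1%) are discarded. Cluster centres are the
centroid of assigned samples, the representative frame is the assigned
sample nearest that centroid, and populations are percentages of all
samples — so they sum to ≤100 and unassigned shallow regions are simply
left out. The exact basin-boundary definition is an open choice in this
kind of analysis; steepest-descent flood fill is this package's documented
one. Broad diffuse states bottom out well above compact ones, so analyses
that must capture both (for instance a compact-helix/extended-β mixture)
should widen the seeding window (the drivers use 3.0).

Hydrogen-bond occupancy counts a backbone pair (|i−j| ≥ 2) as bonded in a
frame when the amide-H to carbonyl-O distance is within 2.8 Å — a plain
distance criterion with no angle term, matching the stated cutoff
convention. On an ideal α helix both the i→i+4 and the tighter i→i+3
H···O contacts fall inside 2.8 Å, so both appear saturated; the
Kabsch–Sander energy, not the distance count, is what distinguishes them
for assignment.

## Pulling profiles

Replicate sets are long tables of (replicate, frame, COM distance,
helical count) with non-decreasing distance within each replicate.
Profiles average the helical count across replicates per time point (the
default, since a shared constant-velocity schedule makes time and distance
interchangeable); a distance-binned mode serves unevenly pulled data and
keeps only bins covered by every replicate. Uncertainty is the
leave-one-out jackknife SE of the replicate mean at each grid point,
undefined (NaN) for a single replicate. A profile "retains helicity" when
the interpolated count at the probe distance (default 1.8 nm) is at least
half (default) the count at the starting distance (default 1.33 nm); both
thresholds and distances are exposed in `RunConfig`.

## Replica exchange with solute tempering

The λ ladder is equally spaced from 0 (the physical Hamiltonian) to
λ_max; the default is 8 rungs to 0.5. Scaling uses
E(λ) = (1−λ)·E_ss + √(1−λ)·E_sw + E_ww — solute-solute damped linearly,
solute-solvent by the geometric-mean rule, solvent-solvent untouched —
the standard form in the solute-tempering lineage, which reduces to the
plain sum at λ = 0. Bonded solute terms are not treated separately at toy
scale. Exchange of adjacent rungs uses the Metropolis rule on
Δ = [E_a(x_b) + E_b(x_a)] − [E_a(x_a) + E_b(x_b)]. The toy system is a
periodic double well on a dihedral-like coordinate,
E_ss = b(1−cos 2θ)/2 with barrier b = 4 kT and a solvent tilt
E_sw = (1−cos θ)/2, the minimal system showing λ-accelerated barrier
crossing. Validation is two-fold: an exact detailed-balance /
stationary-eigenvector check on an enumerable 2-replica 2-state system,
and a two-sample KS comparison of the λ = 0 marginal against a direct
Metropolis chain (thinned ×25 to de-correlate; the statistic must stay
under the 1% critical value). Exchange acceptance on this mild toy is
high (~96%) and is reported, not targeted: acceptance ranges quoted for
solvated peptides are system-specific.

## Thermodynamics and design

ΔG = RT·ln(K_d in molar), R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹. The default
temperature is 293 K — the unique temperature at which the conversion
reproduces the bundled calorimetric table self-consistently, since the
table's source states none. One bundled row (p53-P27N, −9.076 kcal/mol)
sits 0.006 kcal/mol off the exact round trip of its own K_d; it is carried
as printed rather than corrected.

The redesign operates on 12/1 (MPRFMDYWEGLN) with the anchor triad
F4/W8/L11 and all charged residues (R3, D6, E9) locked. Rules either
delete a position or substitute it from an option set; the candidate list
is the cross product of the substitution options with all deletions
applied, deterministically ordered by score. The shipped rule set —
delete Met1; P2→T; M5→A; Y7→L; G10→L — yields the single candidate
TRFADLWELLN. Candidates are ranked by mean per-residue helix propensity
from a bundled 0–1 scale. The scale is this package's own consensus
ordering of published helix-propensity measurements (Ala highest, then
Arg, then Leu, down to Gly and Pro lowest); published free-energy scales
tie Arg and Leu, and the strict Ala > Arg > Leu ordering used for ranking
is resolved in Arg's favour by convention here. The scale file is
user-replaceable; only orderings, never absolute helix contents, are
asserted anywhere.

## Synthetic data: what it emulates, and what it does not

The ensemble generator draws, per frame, a segmentation of the chain into
contiguous blocks (geometric lengths, default mean 8) with states sampled
from the (helix, β, PPII, coil) weights; block structure matters because
the assignment rules require hydrogen-bond *runs* — independently drawn
per-residue states would almost never produce two consecutive turns.
Dihedrals are the state centres (α (−57°, −47°), β (−135°, 135°), PPII
(−75°, 150°), coil uniform) plus angular noise of sd 10° — wide enough to
spread free-energy-surface bins, narrow enough that region classification
keeps the state identity. Within structured blocks the noise is
anti-correlated between ψᵢ and φᵢ₊₁ (crankshaft coupling, the dominant
libration mode of real helices): each angle's marginal stays N(0, sd)
while the hydrogen-bond pattern survives, as it does in thermally
fluctuating real helices; with independent noise of the same width ~9% of
interior helix bonds would break, which is a property of uncorrelated
jitter, not of real ensembles. The generator stores both the drawn state
labels (whose fractions match the weights to multinomial accuracy) and
the secondary-structure string the assigner is expected to produce:
helix runs keep H except where a chain terminus clips the bond pattern
(one residue at an end touching the terminus) or the run is shorter than
4, the minimum H run two consecutive turns can produce.

The pulling generator advances the COM distance deterministically from
1.33 nm (0.01 nm/frame over 120 frames, mirroring a 0.1 nm/ns schedule)
and sets the helical count to helical_start × [floor + (1−floor) /
(1 + e^{k(d−mid)})] plus integer-rounded Gaussian noise (sd 0.7 residues),
clamped to [0, n]. Presets: "p53-like" (mid 2.3 nm, floor 0.5 — retains
≥50% past the probe) and "12/1-like" (mid 1.65 nm, floor 0 — unwinds
before 1.8 nm).

What passing tests on these ensembles shows is that the *analysis chain*
is correct: assignment recovers planted structure, surfaces and basins
recover planted mixtures, profiles recover planted unwinding parameters.
It does not show anything about real peptide thermodynamics: the
generator is not a force-field sampler, carries no receptor atoms, no
side-chain packing, no coupling between frames (frames are i.i.d., so
there is no kinetics), and its state weights are inputs, not predictions.
Percentages measured on synthetic ensembles are properties of the chosen
weights, not of the named peptides.

## Problem sizes and numerical choices

Default analysis sizes — 2000-frame ensembles of 12–30-mers, 10 pulling
replicates × 120 frames, 10⁵-sweep toy REST runs — are the package's
working scale: large enough for multinomial fluctuations of a few points
at worst, small enough that the entire suite runs in minutes on one CPU.
Histogram minima are shifted to exactly 0 before masking; basin descent
breaks plateau ties by staying put (a cell with no strictly lower
neighbour is a minimum); circular quantities (ω near ±180°, twist
unwrapping) are compared on the circle; the degenerate single-value
histogram edge case pads to one full bin. Random streams derive from
numpy `default_rng` seeds carried in every spec object, so identical
specs are bit-identical.

## Known limitations

- The DSSP implementation covers the turn/helix/bridge/bend core but not
  β-bulge special-casing or the finer S/T bookkeeping of the reference
  implementations; disagreement concentrates at segment boundaries.
- Basin extraction operates on the binned surface, so basins separated by
  less than a bin width merge, and populations inherit histogram noise.
- The ideal-helix rise at textbook bond geometry is 1.56 Å/residue, a few
  percent above the canonical 1.5 Å round figure; relaxing bond angles
  per-residue would close the gap but is out of scope for a fixed-geometry
  builder.
- `com_distance` is provided for completeness; the pulling generator
  emits distances directly rather than embedding a receptor.
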