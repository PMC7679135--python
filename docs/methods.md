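# Methods

This note documents the models, conventions and numerical choices behind
`gatelatch`, and what the synthetic ensembles do and do not establish about
real MD data.

## System and coordinate conventions

The channel is a hexamer; all per-subunit observables are computed for each
of the six chains and pooled or averaged as stated. Author residue
numbering is used throughout (dOrai convention, matching the closed-state
crystal structure); hOrai1 numbers map by a fixed offset of −72
(hOrai1 F99 = dOrai F171, M101 = M173, F187 = F259, H134 = H206).

Every frame is aligned before analysis: the principal axis
(largest-variance eigenvector) of the TM1 pore-helix Cα cloud
(residues 141–174, all six chains) is rotated onto +z and the cloud's
centroid is translated to the origin. The axis sign is fixed by the helix
N→C direction so upside-down inputs align identically. Because a principal
axis leaves the azimuth free, an optional already-aligned reference
structure pins it by a least-squares rotation about z of the pore-helix Cα
atoms; azimuthal observables (gate rotation versus a reference) require
this pinned alignment, and with it all geometry observables are invariant
under rigid motions of the input to 1e-6 Å / 1e-4°.

Axial coordinates are measured relative to the z of the pore-helix Cα
centre of mass of the same frame, so hydration profiles are robust to
residual drift.

## Gate-latch geometry

Phe ring positions are the mass-weighted centroid of the six ring carbons
(CG, CD1, CD2, CE1, CE2, CZ); ring hydrogens, absent from crystal
structures, are excluded. Four distances are defined for the Met at 173:
d1/d3 from its Sδ/Cβ to the F171 ring of the nearest of the two
ring-adjacent subunits (recomputed per frame; exact ties break toward the
ring successor), and d2/d4 from Sδ/Cβ to the nearest F259 ring over all
subunits (in practice the same subunit's TM3). The radial angle of the
gate residue uses as vertex the Cα centre of mass of two helical turns
centred on it, implemented as residues ±3 (seven residues ≈ 1.9 turns;
configurable) — one ray to the vertex's perpendicular foot on the pore
axis, the other to the residue's Cα. Azimuthal gate rotation is the signed
Cα azimuth change versus the reference, wrapped to (−180°, 180°], positive
counterclockwise viewed from the extracellular (+z) side. The
pore-diameter proxy is twice the mean xy-radius of the six gate-ring
centroids; it is a transparent stand-in, not a solvent-accessible pore
radius (no HOLE-style solver is included).

## Hydration profiling

Water oxygens and ions are counted per frame inside a cylinder of radius
10 Å about the pore axis, binned axially (default 1 Å bins, chosen to
resolve helical-turn-scale features). The per-bin quantity is the mean
count per frame; error bars are the standard error over independent
simulation repeats, and per-repeat scalars are always formed before an SEM
is taken. Comparisons between variants at a stated z (e.g. 15 Å, the
hydrophobic gate) use the single bin containing z and a two-sided Welch
t-test with repeats as samples. Species are recognized by common
residue/atom naming conventions (HOH/SOL/WAT/TIP3 + O/OW/OH2 for water;
NA/SOD, CL/CLA for ions) with a per-call override map.

## Ensemble statistics

Trajectories carry a physical time per frame (frame i at
offset + (i+1)·Δt, Δt defaulting to 1 ns); the first 100 ns of each repeat
is discarded as equilibration by default. Distance distributions are plain
normalized histograms (default 0.2 Å bins, edges aligned to multiples of
the width so distributions from different sample sets share edges); any
kernel smoothing in published figures is treated as presentation, since
every downstream quantity (AUC, PMF, ratios) is defined on the
probabilities. The contact AUC is the mass below the cutoff with the
straddling bin counted pro rata. Welch tests and Pearson correlations are
scipy's implementations; the degenerate Welch case (both groups constant)
returns t = 0, p = 1 when means agree and is an error otherwise.

## Free energies

PMFs are Boltzmann inversions W(d) − W(d0) = −RT ln[p(d)/p(d0)] with
R = 1.98720425×10⁻³ kcal/(mol·K). The reference d0 defaults to the bin of
maximum probability, putting the PMF minimum at zero; zero-probability
bins are flagged undefined (NaN + mask) rather than carried as ±inf.
Contact discretization splits p(d) at 7 Å — the practical outer range of
the sulfur-aromatic interaction — and
ΔG = −RT ln(P_contact/P_non-contact). The thermodynamic cycle over
{closed, open} × {contact, non-contact} closes identically:
ΔΔG = ΔG₂ − ΔG₁ is reported, ΔG₄ − ΔG₃ is set equal to it, and the
per-channel estimate multiplies by the six subunits under an explicit
additivity flag (cooperativity between latches is out of scope). The
default temperature for free-energy conversion is 298.15 K, which
reproduces the published per-contact values (+0.13/−0.65 kcal/mol from
ratios 0.8 and 3) to their printed precision; a simulation thermostat
temperature (e.g. 323.15 K) may be passed explicitly and gives slightly
larger magnitudes. Headline values are conventionally reported at two
decimals (ΔG), one decimal (ΔΔG) and the nearest integer (per channel);
the library returns full precision and rounding is left to the caller.

## Synthetic ensembles and what they show

The generator emulates the statistical structure of the MD observables at
desk scale, not the physics. Six ideal TM1-like Cα helices (2.3 Å radius,
1.5 Å rise, 100°/residue, helix axes 10 Å from the pore axis) carry the
Met and the two Phe rings; the static structure is built with the gate
rings exactly 7.3 Å (Cβ→F171, adjacent subunit) and the TM3 rings exactly
5.8 Å (Cβ→F259) from the Met Cβ — the closed-crystal separations — so the
measurement conventions can be validated against a known answer.

Dynamics are a per-subunit two-state Markov chain (default switching
propensity 0.2/ns) with prescribed stationary contact probability;
conditional on the state the Sδ-to-ring distance is drawn from a truncated
normal confined to its side of the 7 Å cutoff (contact: μ 5.0 Å, σ 0.6,
echoing the ~5 Å sulfur-aromatic optimum; non-contact: μ 8.5 Å, σ 0.8,
upper-truncated at 12 Å so the adjacent-partner assignment stays
unambiguous). Truncation at the cutoff makes the two-state ground truth
exact: the stationary probability equals P(d < 7 Å) and −RT ln(ratio) is
the exact recovery target. A latched Met also rotates its partner
subunit's gate ring and Cα azimuthally (default 20°), coupling rotation to
contact as in open channels. Small Gaussian jitter (0.05 Å) plays the role
of thermal noise. Solvent is an inhomogeneous Poisson gas in a 24 Å × 24 Å
× 60 Å slab: bulk water-oxygen density 0.0334 Å⁻³ multiplied by a
dewetting factor (default 0.3, a partially dewetted closed-like gate)
inside the 10–20 Å axial gate window; ions at ~150 mM equivalent. Because
a trajectory's topology must be fixed, the solvent count is frozen at the
integer mean of the intensity and positions are redrawn i.i.d. per frame;
expected per-bin cylinder counts remain ρπr²Δz (bulk) and f·ρπr²Δz (gate).

Default problem sizes mirror the production protocol the statistics assume
(400 frames at 1 ns, first 100 ns trimmed, 5–10 repeats); tests and
examples use these or smaller sizes. One master seed drives everything;
per-repeat seeds derive from it deterministically.

Passing tests on these ensembles establish that the pipeline measures what
it claims (conventions, estimators, error propagation, parameter
recovery). They do not establish anything about force fields, sampling
convergence, autocorrelation structure beyond the two-state chain, water
orientation, or ion permeation in real trajectories.

## Functional quantification

Fractional inhibition is 1 − |I_b|/|I_ctrl| and fold change |I_post|/|I_pre|
(magnitudes; sign-discordant pairs are flagged). Gain-of-function calls
are strict: current density must exceed 2 pA/pF. E-FRET uses the
three-cube sensitized-emission form F_c = I_DA − a·I_AA − d·I_DD,
E = F_c/(F_c + G·I_DD), with default calibration a = 0.12, b = 0.008,
c = 0.002, d = 0.33, G = 1.85; b and c are carried for completeness but do
not enter this formula. Analysis is conventionally restricted to cells
with YFP/CFP ratios in [2, 6], inclusive at both ends.

## Known limitations

Multi-model PDB and plain-text frame tables are the only trajectory
formats; binary MD formats are out of scope (convert upstream). The
pore-diameter proxy is geometric, not solvent-based. No autocorrelation-
aware error estimation is provided — SEM over repeats is the only error
model, as in the analysis it reproduces. The per-channel free energy
assumes additive latches; cooperative corrections would lower it.
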