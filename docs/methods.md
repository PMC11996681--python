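# Methods

This note documents the models and estimators implemented in
`hydrodna`, the parameter defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical
choices that matter for reproducing results.

## Permutation reduction of water identities

**Model.** An MD trajectory stores waters in an arbitrary, physically
meaningless order. Permutation reduction finds, for every frame, a
bijection between storage slots and site labels such that each label's
oxygen stays close to a fixed reference position. Per-label statistics
(mean position, RMSF, positional covariance) then describe hydration
*sites* rather than arbitrary molecules, and no coordinate is altered —
any label-free observable is bit-identical before and after.

**Assignment.** Each frame is solved as a linear sum assignment
(`scipy.optimize.linear_sum_assignment`) over a cost matrix of
oxygen–reference distances, with per-axis minimum-image displacements
when an orthorhombic box is present. Two deliberate choices:

- *Linear, not squared, distance costs (default).* Squared costs
  minimise a sum of squares and therefore prefer splitting one long
  displacement into several short hops. When freely exchanging waters
  teleport across the box between frames (as the synthetic bulk does,
  and as real bulk does on long frame strides), a squared-cost matching
  will route such a move "through" an occupied hydration site, stealing
  the site's occupant and inflating its apparent mobility. Linear costs
  obey the triangle inequality, so a detour through a site never pays.
  Measured on the standard classification scenario (20 pinned sites,
  50 exchanging bulk waters), label recovery is 0.35 with squared
  costs, 0.94 with linear costs and > 0.999 with the gate below;
  `cost="squared"` remains available.
- *Displacement gating (default 2.5 Å).* As in gated nearest-neighbour
  tracking, any pair farther apart than the gate pays a large constant
  plus its distance. In-gate continuations of a site can then never be
  sacrificed to shorten a far exchange, while over-gate pairs are still
  ranked by distance among themselves (with every pair over the gate
  the solution reduces to the ungated one). The default of 2.5 Å sits
  above the frame-to-frame displacement of a bound site at the
  low-mobility scale (√3·σ with σ well below 1 Å) and below typical
  site separations; `gate=None` disables it.

**References.** Labels anchor to the first frame's oxygen positions by
default, or to crystallographic/user-provided positions. References
stay *fixed* by default: the label is defined as "the water nearest
this position". An optional iterative mode (`reference_update="mean"`)
re-centres each reference on its site's assigned mean and re-assigns
until labels stop changing or the largest mean shift drops below `tol`
(default 0.01 Å, max 50 sweeps). Mean updating sharpens well-sampled
bound sites, but for an unbound water the mean of its wanderings is the
box centroid, and many such collapsed references crowding the centre
shadow genuine interface sites; it is therefore opt-in and recommended
only for selections without freely exchanging waters. The squared-cost
objective under mean updates is block-coordinate descent and its total
cost is non-increasing across sweeps (tested).

**Mobility.** RMSF_i = sqrt(mean_t |x_i(t) − x̄_i|²) on permuted oxygen
tracks. A single frame reports RMSF 0 with a warning flag. Equilibration
is checked by running any summary independently on the first and second
halves of the frames (`split_half_consistency`).

## Interfacial waters and mobility classes

A water is interfacial when its oxygen is simultaneously within a
cutoff of *some* protein atom and *some* DNA atom. Both literature
variants are first-class modes with the cutoff always explicit in
output metadata:

- `instantaneous`, cutoff 5 Å: tested per frame; the trajectory-level
  set is the union over frames and the qualifying fraction per site is
  reported. A minimum-fraction filter exists but defaults to 0 because
  the mobility classification itself separates transient visitors
  (high RMSF) from residents.
- `mean_position`, cutoff 4 Å: tested once, site mean positions against
  a reference structure.

Partner atoms include hydrogens by default (the criterion names "a
protein atom and a DNA atom", not heavy atoms); heavy-only is a flag.
Low mobility means interfacial AND RMSF strictly below 1.9 Å. Replica
summaries use the n−1-denominator standard deviation over replicas,
s.e.m. = s/√n.

## Solvent entropy

Each site's **first-order translational entropy** applies Schlitter's
formula to the 3×3 covariance Σ of its permuted oxygen positions with
the mass of one water molecule (18.015 u):

    s = (R/2) ln det[ I + (k_B T e²/ħ²) m Σ ]   [J K⁻¹ mol⁻¹]

with CODATA 2018 constants, T = 298.15 K by default, and e Euler's
number. This is a quasi-harmonic *proxy*: rotational degrees of freedom
and water–water correlation terms are out of scope, so absolute values
carry the proxy's own scale and only orderings and the bookkeeping
below are meaningful. A rank-deficient covariance (pinned site) is
flagged degenerate; its determinant is 1 along pinned axes, so a fully
pinned site reports exactly 0. Per-site entropy is monotone in
positional variance and its ordering matches the RMSF ordering
(Spearman ρ ≥ 0.9 across σ = 0.1–3 Å, tested).

**Interface bookkeeping.** With N interfacial waters of mean entropy
S_avg:

    S_total = N·S_avg,   ΔS_solv = N·(S_avg − S_bulk)

S_bulk defaults to 118 J K⁻¹ mol⁻¹ but is a parameter: a proxy
estimator has its own bulk scale, so quantitative work should recompute
the bulk mean from bulk waters of the same estimator and report both.
The identity holds to better than 1e−9 on every report (tested); an
empty interface yields N = 0, S_avg undefined, ΔS_solv = 0.

**Solute.** Schlitter's upper bound on the mass-weighted 3N×3N
covariance after least-squares (Kabsch) superposition of each frame
onto the selection's mean structure (two passes: fit to the first
frame, refit to the resulting mean; heavy atoms drive the fit). Fewer
than 3·N_atoms frames flags the estimate as under-sampled. Residue
RMSF averages per-atom RMSF within each residue, reported for all atoms
and for the main-chain subset (protein N/CA/C/O; DNA phosphate–sugar
backbone).

## Hydrogen bonds and water bridges

Donors/acceptors: N and O atoms with fewer than four covalent bonds;
donors additionally carry ≥ 1 bonded hydrogen (one donor entry per
hydrogen). Bonds come from a distance heuristic (H to nearest heavy
atom within 1.2 Å; heavy pairs within 1.9 Å in the same or adjacent
residue), sufficient for this bookkeeping. A hydrogen bond requires
d(D,A) < 3.0 Å and ∠(D,H,A) > 120°, both strict. Topologies without
water hydrogens must opt in to a distance-only O···O/N criterion, which
is flagged in every output.

A bridge of order k is a path protein-polar-atom → k distinct waters →
DNA-polar-atom on the undirected hydrogen-bond graph (waters collapsed
to one node per molecule; ions excluded), k ≤ 3; order 0 is a direct
bond. Order counts *intervening water molecules* — the nomenclature in
parts of the literature is inconsistent, and this definition is the
self-consistent one. Enumeration is a depth-first search verified
against exhaustive simple-path search on small graphs. Occupancy is
summed per residue–nucleotide pair (a frame counts once however many
chains bridge the pair; per-order and per-chain fractions are kept for
audit), and a pair is stable iff its fraction exceeds 0.05 strictly.

## HT-SELEX enrichment

For k-mer w: normalized count = occurrences/reads (overlapping
occurrences, both strands by default — SELEX ligands are
double-stranded, so w and its reverse complement are indistinguishable
and get identical counts); fold change = normalized count in the signal
cycle over the background cycle (cycle 0 by default); enrichment = 100
× fold change / fold change of the reference k-mer (TAAACG), so the
reference is exactly 100 by construction. Zero background counts give a
flagged infinite fold change unless a pseudocount is enabled (off by
default, recorded in metadata).

**Local maxima.** A k-mer is flagged when its enrichment strictly
exceeds that of every *related sequence*: its 18 Hamming-1 substitution
neighbours and, by default, its 8 single-base shifts. The shift
comparison matters: a k-mer overlapping a true optimum by k−1 bases
inherits part of the optimum's enrichment while its substitution
neighbourhood is flat, so substitution-only flagging produces one
spurious maximum per motif flank. Candidates must additionally exceed a
minimum fold change (default 2.0) — below it, enrichment is sampling
noise around 1 and a constant landscape plus noise would otherwise
yield maxima at the noise rate. Both knobs are parameters.

**Temperature series.** Enrichment profiles across conditions
(0–40 °C) are summarised per k-mer by the sign of the Spearman
correlation with temperature; series that are constant to numerical
precision report trend 0. Because the reference k-mer is pinned at
100 % by definition, trends of the reference itself (or of everything,
when the reference responds to temperature) should be read on the
`fold_change` measure.

**Seed PWM.** Single-position-wildcard counting: a window (either
strand) matching the seed at all non-N positions contributes its base
at every position; a window with exactly one mismatch contributes only
at the mismatched position. Columns are normalised to frequencies;
empty columns become uniform and are flagged.

## Synthetic data

The generators emulate the *statistical* structure the estimators
assume, not the physics that produces it:

- **Scaffold complex**: a protein contact plane and a linear DNA axis
  6.8 Å apart; pinned interfacial sites on the gap axis at 4 Å spacing
  (within 4 Å of both partners by construction), pinned distal sites
  behind the protein, bulk waters uniform in a surrounding box
  excluding the 2.4 Å packing radius of solute atoms and occupied
  sites. Infeasible requests (more interfacial sites than the solute
  extent covers) raise a geometric error.
- **Trajectory**: pinned waters i.i.d. Gaussian about their centres
  (default σ = 0.3 Å, i.e. RMSF ≈ 0.52 Å, firmly in the low-mobility
  class); bulk waters *resampled independently every frame* — they
  teleport rather than diffuse, which is the worst case for identity
  tracking and is exactly what the gated assignment is tested against.
  Optional per-frame scrambling of water storage order exercises
  permutation reduction with a recorded ground-truth mapping; optional
  solute jitter feeds the Schlitter and residue-RMSF paths.
- **Bridge fixtures**: donor–water–…–acceptor chains with every D–A
  distance and D–H–A angle constructed exactly (closed-form hydrogen
  placement), orders 0–3.
- **SELEX pools**: cycle 0 is uniform random sequence; cycle c+1
  resamples reads with probability proportional to the maximum planted
  weight of any k-mer occurrence on either strand (equivalent in
  distribution to acceptance sampling with top-up). The default
  landscape plants TAAACG at weight 10, TAATTG at 8 and two Hamming-1
  shoulders at ≤ 4 over background 1; the temperature variant lets the
  AC optimum's weight fall linearly from 10 at 0 °C to 4 at 40 °C with
  the TT optimum constant, mirroring an enthalpy-driven vs
  entropy-driven contrast. Expected fold changes are computed
  analytically given the realised input pool (each read weighted by
  w^c), exact for one cycle and accurate to resampling noise for more.

What passing tests therefore do **not** show: correctness under
continuous diffusion, force-field realism, varying water number,
PCR/sequencing bias, or cooperative binding. They do show that each
estimator recovers planted structure under its own model assumptions at
realistic noise levels, and that all bookkeeping identities hold
exactly.

**Problem sizes.** The standard runs are 2 000 frames × 20 sites for
label recovery, 300 frames × 70 waters for classification (plus 10 + 10
replicate runs of 100 frames), 5 000 draws for the oscillator check,
and 10⁵ reads/cycle for the deep SELEX run with 2×10⁴ reads per level
of the temperature series — sizes at which every recovery statistic is
comfortably inside its tolerance while the whole suite runs in seconds.

## Numerical choices and edge cases

- Coordinates in Å, entropies in J K⁻¹ mol⁻¹, temperatures in K;
  constants CODATA 2018, collected in one module.
- Orthorhombic minimum-image only; triclinic cells rejected loudly.
- Assignment ties broken deterministically by the solver (lowest site
  label first); identical seeds give byte-identical outputs, and
  manifests record config hash, seed and per-file checksums (path
  fields are excluded from the hash so identical analyses match
  regardless of output location).
- Strict inequalities everywhere the thresholds are defined strictly
  (RMSF < 1.9, d < 3.0, angle > 120, fraction > 0.05); boundary tests
  probe the closed side where float-exact construction is possible.
- Degenerate inputs: empty water systems run to completion with
  warnings; single-frame mobility returns 0 with a flag; empty
  interface gives ΔS_solv = 0; waters without hydrogens skip bridge
  detection unless the distance-only mode is requested.

## Known limitations

- The per-water entropy is a first-order translational proxy; its
  absolute scale is not comparable to estimators that include
  rotational and correlation terms, and the 118 J K⁻¹ mol⁻¹ bulk
  default belongs to such a fuller estimator.
- Constant water number is assumed; grand-canonical tracking and
  waters crossing periodic images are out of scope (inputs are wrapped
  before assignment).
- Bond inference is heuristic; exotic residues or metal coordination
  may need explicit topology rules.
- The SELEX selection model is single-hit multiplicative; multi-site
  and cooperative binding are not modelled.
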