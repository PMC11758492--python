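# Methods

This note records the models implemented in `hdxcalib`, the defaults and
why, the numerical choices, and what the synthetic fixtures do and do
not establish.

## Exchangeable-site inventories

Counting uses neutral forms. Backbone amides: one per residue after the
first, excluding prolines; an acetylated N-terminus converts the
α-amine into an amide, adding one backbone site unless residue 1 is
proline. Side-chain hydrogens per residue: K amine 2, R guanidino 4
(neutral form; required to reproduce bradykinin's 12 side-chain sites),
S/T/Y hydroxyl 1 (pooled into one class), D/E carboxyl 1, N/Q
side-chain amide 2, H imidazole 1, W indole 1, C thiol 1. Termini: free
α-amine 2, free carboxylic acid 1, C-terminal amide 2 (counted in the
side-chain amide class — the literature tables only fix the free-acid
count, so this is a package choice). A protonated MS ion adds its
charge to the total only; class counts stay neutral.

Second-residue amides are counted normally (Nt17's printed 16 backbone
sites equal 17 − 1 and force this).

## Intrinsic rates k_int

Per-amide rates are the sum of acid-, base- and water-catalysed
pathways. Each pathway multiplies a poly-DL-alanine reference rate
(293 K, D₂O: log₁₀ k = 1.62, 10.18, −1.5 in M⁻¹ min⁻¹ / min⁻¹) by the
log-additive side-chain corrections of the residue itself and its left
neighbour (packaged CSV, `hdxcalib/data/kint_neighbor_factors.csv`,
version 1), an Arrhenius factor (Ea = 14, 17, 19 kcal/mol), and the
catalyst concentration. pD is the pH-meter reading plus a configurable
offset (default +0.4); [OD⁻] uses pK_D = 15.05, held
temperature-independent (the Arrhenius factors absorb most of the
temperature response over the relevant range; documented limitation).
Histidine uses the protonated-imidazolium factors, Asp/Glu the
carboxylate forms; terminal corrections apply to the second and final
amides. Defaults pH 7.0 and 300 K are package choices — the source
measurements do not fix the droplet's effective pH or temperature — and
every consumer takes them as explicit arguments.

## Uptake and internal-standard scaling

Centroids are intensity-weighted mean m/z converted to neutral mass
with a proton mass of 1.00728 Da; the D–H mass difference is fixed at
1.00628 Da. A centroid's uncertainty is the weighted standard error
over isotopic peaks with effective n = (Σw)²/Σw²; this is a
peak-statistics stand-in, replaceable upstream. Shifts below −0.05 Da
are flagged as apparent back-exchange but never clamped silently.
Scaling regresses analyte uptake on the internal standard's percent
exchange (unweighted OLS, as a spreadsheet LINEST would) and evaluates
at the 75% reference with the standard prediction-variance formula.
Charge states pool by supplied weights (total ion intensity in
practice; equal by default) with inverse-variance weighting behind a
flag — the original study's exact weighting is not public, so both are
labelled and neither is claimed as its.

## Side-chain decomposition

Class propensities solve `counts · p ≈ uptake` under p ≥ 0
(`scipy.optimize.nnls`). Standards are assumed referenced to the 75%
condition and to contribute no backbone uptake on the standards' time
scale. When the unconstrained least-squares solution is already
nonnegative the NNLS solution equals it — the analytic cross-check is a
test invariant. Parameter uncertainties come from the OLS covariance on
the interior (non-boundary) support; boundary-active classes get none.
This approximates the sampling error of an inequality-constrained
estimator and is reported as such. Propensities above 1 are clipped and
flagged. % BB = 100 · (total − side)/n_backbone, uncertainty propagated
from the total (and side, when supplied); negative values are flagged,
not rejected.

## State classification

SASA is Shrake–Rupley with probe 1.4 Å, 960 deterministic
golden-spiral sphere points, and Bondi-style radii including hydrogens
(H 1.20, C 1.70, N 1.55, O 1.52, S 1.80 Å). Occluders are protein
atoms only — water is the solvent being probed. The open comparison is
inclusive (SASA ≥ 8.3 Å²).

Hydrogen-bond geometry: the 3.3 Å cutoff anchors at the amide H to
acceptor distance (configurable to N–O), and the angle is at the
hydrogen, N–H···A ≥ 150° (within 30° of linear). The source criteria do
not name the anchoring atoms; exchange requires water contact with the
amide hydrogen itself, hence the default. Water acceptors are water
oxygens (residue names TIP3/HOH/WAT/SOL); intramolecular acceptors are
protein N/O heavy atoms excluding the amide's own nitrogen. Minimum-
image corrections apply when an orthorhombic box is present; SASA is
computed without periodic images (adequate for solvated peptides
centered in their box).

inter: open ⇔ exposed AND ≥ 2 in-geometry waters. intra: closed ⇔
buried OR any intramolecular H-bond. Because intra's closed condition
implies inter's, the intra open set contains the inter open set
frame-by-frame; the per-residue inequality f_o(intra) ≥ f_o(inter) is a
test invariant. Frames are evenly subsampled to at most 2.5 × 10⁴.
Replicates are classified independently.

## Protection factors and theoretical exchange

PF_i = (1 − f_o)/f_o with f_o clamped to [1/n, 1 − 1/n] (truncation,
not Laplace smoothing: pseudocounts would bias every unsaturated
residue; clamped residues are flagged instead). Digital rule: residue i
exchanges iff ln PF_i < 0; exactly 0 counts as not exchanged (strict
inequality). Combined model: HDX_i = 1 − exp(−k_int,i · t / PF_i),
reconstructed from the steady-state approximation k_obs = k_int/PF; the
stated closed forms (1 − e⁻¹ at k_int t = PF, limits 0 and 1) pin the
functional form. Default t = 1 s; for rank correlations t is arbitrary
since it rescales all contributions monotonically. Replicates aggregate
by averaging f_o before recomputing PF (primary), with ln PF averaging
behind a flag; which the original analysis used is not stated.

## Structural descriptors

Gyration tensor eigenvalues give Rg = √(λ₁+λ₂+λ₃) and asphericity
δ = 1 − 3(λ₁λ₂+λ₂λ₃+λ₃λ₁)/(λ₁+λ₂+λ₃)², mass-weighted by default.
Backbone RMSD superposes N/CA/C/O optimally (MDAnalysis) before the
deviation. Contacts: minimum heavy-atom inter-residue distance
≤ 4.5 Å, |i−j| ≥ 2 (the reference "H-bond contact distance" is
unquantified; 4.5 Å sits in the 4–5 Å feature reported for these
systems and is configurable). Helicity counts a residue helical when
φ ∈ −57° ± 30° and ψ ∈ −47° ± 30°; this is a documented dihedral
approximation, not a DSSP/STRIDE reimplementation.

## Synthetic fixtures

Toy trajectories are built from ideal internal coordinates (N–CA
1.458, CA–C 1.525, C–N 1.329 Å; standard angles; NeRF chain
extension) with rigid three-site waters placed analytically inside or
outside the H-bond acceptance cone; nothing is physically simulated.
Closed frames either park the residue's waters far away (closed under
inter only) or additionally cage the amide H in twelve carbon occluders
at 2 Å (closed under both models). Open/closed schedules are Bresenham
sequences, so realized open fractions equal their targets to 1/n_frames
and the per-frame truth is recorded in a JSON manifest. Random coils
are rejection-sampled dihedrals with a 2.0 Å nonlocal hard-sphere
clash check. Envelopes convolve a base isotope pattern with the exact
binomial deuterium distribution, making the expected centroid shift
n·p·1.00628 Da to machine precision; intensity noise is seeded and
relative. All generators are bit-reproducible given (spec, seed).

A green classification test on these fixtures establishes that the
geometric operators implement their definitions exactly — it does not
establish that the thresholds transfer to force-field ensembles, that
droplet pH/temperature match bulk assumptions, or anything about
conformational sampling, which requires real MD input.

## Known limitations

* Peak lists must be pre-centroided; no profile-mode peak picking,
  species deconvolution, or mzML ingestion.
* EX2-like kinetics only (k_obs = k_int/PF); EX1 regimes are out of
  scope.
* The designed KDD peptide's published sequence and site counts are
  mutually inconsistent; both sequence variants ship in the registry
  and no count is asserted for it.
* k_int neighbour factors are shipped as a versioned data file; users
  with preferred parameter sets can point `kint_profile` at another
  table id.
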