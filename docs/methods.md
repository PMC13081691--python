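# Methods

## Scope and data model

`foldscreen` operates strictly downstream of structure prediction: its
inputs are predicted complex coordinates (mmCIF/PDB, pLDDT in the B-factor
column) and the predictor's confidence output (PAE matrix, pTM, ipTM).  A
`ComplexModel` + `ConfidenceBundle` pair is indexed globally: 0-based,
contiguous across chains in model chain order — the order of the PAE
rows/columns.  All user-facing output is 1-based with chain ids.  pLDDT
precedence is confidence-file values over B-factors (AlphaFold3 mmCIF
stores pLDDT in B-factors; ColabFold JSON is authoritative when present);
AlphaFold3 per-atom values are averaged per residue, since every
downstream metric is per-residue.  PAE entries above 35 Å are rejected as
corrupt — AlphaFold2's ceiling is 31.75 Å, so larger values indicate unit
errors.  Only the 20 standard amino acids are scored; common modified
residues (MSE, SEP, TPO, …) map to their parent, anything else is dropped
with a warning.

Two confidence-JSON dialects are parsed.  ColabFold files carry
residue-level `pae` and no chain map; the chain assignment is adopted from
the structure when the bundle is attached.  AlphaFold3-server files carry
token-level PAE; reduction keeps exactly the first protein token of each
(chain, residue) and drops ligand/ion tokens (identified by
`token_is_protein` or `token_res_names` when present).  Whether the
upstream tooling fed residue- or token-level AF3 PAE to its scorers is not
documented anywhere we could rely on; this reduction rule is therefore
stated as the package's contract and covered by dialect-equivalence tests.

## Confidence metrics

**Weighted score.** `0.8·ipTM + 0.2·pTM`, the conventional multimer
ranking combination.  Bands: > 0.80 high, 0.60–0.80 intermediate, > 0.40
permissive pass.

**ipSAE family.**  For direction A→B, each residue *i* of A collects
partners `S_i = {j ∈ B : PAE(i,j) < c}` with `c = 15 Å` (strict
inequality — ties at the cutoff are excluded).  Its score is the mean TM
kernel `1/(1+(PAE/d0)²)` over `S_i`; the direction score is the best
residue; the pair score is the best direction, and 0.0 exactly when no
interchain PAE clears the cutoff.  The variants differ only in `d0(n) =
max(1.0, 1.24·(n−15)^⅓ − 1.8)`:

| variant | n |
|---|---|
| `ipsae` | `|S_i|`, per residue |
| `d0chn` | `L_A + L_B` |
| `d0dom` | residues of A and B participating in any sub-cutoff pair of the direction's PAE block |

The `d0dom` normalisation makes scores comparable across paralogues with
different disordered-tail lengths, which is why it is the headline
variant in reports.  The d0 floor of 1.0 Å is a documented choice: the
raw formula is negative or complex below n ≈ 18, and a 1 Å floor keeps
the kernel meaningful for tiny interfaces.  The 15 Å PAE and distance
cutoffs are the screening protocol's operating point; the stricter 10 Å
cutoff suggested elsewhere is available via `ScoringConfig.pae_cutoff`.
(`dist_cutoff` is carried in the config for parity with that protocol's
parameter set; the coordinate-based masks below use the explicit contact
cutoffs instead.)

**pDockQ.**  Contacts are interchain Cβ–Cβ pairs (Cα for glycine) within
8 Å; `x = ⟨pLDDT⟩ · ln N` over residues in ≥ 1 contact; the sigmoid
constants (0.724, 0.052, 152.611, floor 0.018) are the original
single-interface fit.  pLDDT is used on its 0–100 scale.  Zero contacts
return the 0.018 floor.  Bands: ≥ 0.23 acceptable, ≥ 0.49 medium, ≥ 0.80
high.

**Masked interface pTM.**  The actifpTM idea — score only the actual
interface — requires distograms and PAE probability maps that predictors
do not export.  The package therefore computes a coordinate-contact
approximation: the interface set I is all residues with any interchain
heavy-atom distance ≤ 8 Å; the score is an ipTM-style max-over-residues of
mean kernels over interchain pairs within I, with `d0(|I|)`; 0.0 for an
empty interface.  Outputs label it `masked_iptm(actifpTM-approx)` so it is
never mistaken for the distogram-weighted original.

All asymmetric scores report both directions and their max; the max is
the filtering value.

## Triage filters

Filters apply in documented order: weighted > 0.40 (permissive,
sensitivity-oriented), then pDockQ ≥ 0.23.  The two commute for the
retain set; the recorded exclusion reason is the first failure.  ipSAE
bands (< 0.20 false-like, > 0.40 true-like) are recorded as labels only.
One unreadable model never aborts a screen — the row is recorded as
failed and the pipeline continues.  When a pair is modelled by several
replicates, the best-by-weighted replicate represents the pair; no
aggregation rule is universal here, so this choice is explicit and
recorded.

## Interface similarity and clustering

Residues are mapped between models by global pairwise alignment (BLOSUM62,
gap open 11, extend 1); chains pair by the assignment maximising total
alignment score, exhaustively over the few-chain permutations.  A mapping
is refused when no assignment scores positive: a correspondence between
non-homologous chains would make the downstream comparison meaningless.
Unaligned positions are excluded from both numerator and denominator so
paralogue length differences cannot dominate — the same logic as trimming
models to their shared interacting domain.

Interface lDDT uses the conventional parameter set: backbone N/CA/C/O plus
CB, reference pairs on different chains within a 15 Å inclusion radius,
preservation thresholds {0.5, 1, 2, 4} Å.  The score is computed in both
directions and averaged, making edges undirected.  Reference pairs with
unmapped atoms are skipped and surfaced as a coverage fraction rather than
silently counted against the score.  A model with no interchain pairs
within the radius raises an undefined-interface error — deliberately
distinct from scoring 0.

The similarity network keeps edges at lDDT ≥ 0.80 (the conventional
"same interface" threshold); clusters are connected components, the
minimal deterministic reading of "groups sharing an interface"; a greedy
mode (seed at the highest-degree node, absorb neighbours) is available
where star-like topologies should not chain together.  Consensus: a pair
is consensus-supported when retained models from ≥ 2 distinct prediction
methods fall in one cluster.

## Plausibility checks

Interface membership for residue-sharing comparisons uses heavy-atom 5 Å
contacts (PISA-like); this is intentionally separate from pDockQ's Cβ 8 Å
definition — the two cutoffs serve different formulas.  Shared-interface
overlap is reported both as Jaccard (symmetric) and directionally
(|∩|/|interface₁|).  Two empty interfaces define overlap 1.0, with a
warning.

Domain trimming removes residues outside annotated ranges and slices the
PAE matrix and pLDDT to the survivors; it never re-predicts.  Membrane
proximity flags residues with any atom within 3.5 Å of the upper-leaflet
plane of an externally oriented model (normal along z); both-leaflet mode
is a flag.  Localization compatibility is a tri-state over user-supplied
annotation tables: compartment sets that intersect, or that both face the
cytosol (ER membrane ↔ cytosol), are compatible; luminal compartments are
topologically isolated from cytosolic ones; missing annotation yields
"unknown".  A transmembrane segment participating in an interface sets
`membrane_plausible = no`; the flag never auto-excludes.

## Amphipathicity

Mean hydrophobicity ⟨H⟩ and hydrophobic moment
`μH = (1/N)·‖Σ H_n·e^{i n δ}‖` with δ = 100°/residue, on the
Fauchère–Pliska octanol/water scale (the helical-wheel servers' default,
bundled as a constant table).  Display rounds to 2 dp; full precision is
kept internally.  μH is deliberately not shift- or permutation-invariant —
it measures face segregation of the raw scale values.

## Synthetic data

The generator emulates the statistical structure of predicted dimers, not
their physics: idealized α-helices (rise 1.5 Å, twist 100°, Cα radius
2.3 Å, N/CA/C/O/CB atoms with fixed local geometry), chain B placed so the
closest heavy-atom approach equals `interface_gap`; PAE low
(`pae_intra_base` = 2 Å) within chains and `pae_inter_base` between
chains with independent noise on (i,j) and (j,i) (no symmetrisation,
matching real predictor output); pLDDT around 90.  Summary ipTM follows
the monotone fixture convention `clip(1.1·e^{−pae_inter_base/8}, 0,
0.95)` plus small seeded noise, with pTM tied to it — explicitly
non-physical, chosen so the true/false dial moves every metric coherently.
Screen fixtures draw true-like pairs at `pae_inter_base` ∈ [2, 4.5] Å
(summary ipTM > 0.6, docked at 4 Å) and false-like pairs at ≥ 20 Å
(ipTM < 0.3, 12 Å gap), so construction labels are unambiguous at the
documented thresholds.  Pose families for clustering tests dock chain B
against faces of chain A rotated 120° apart (inter-group displacements far
exceeding 10 Å) with sub-Å rigid jitter within groups.

What passing these fixtures does **not** show: robustness to AlphaFold's
correlated error structure, MSA-depth effects, disordered regions, real
side-chain packing, or borderline-confidence models — real screens live in
the grey zone the dial deliberately avoids.  The fixtures establish that
the arithmetic, contracts and thresholds behave exactly as specified, not
that the thresholds are optimal for any particular proteome.

## Numerical choices and problem sizes

Scores agree with independent brute-force double-loop oracles to 1e-12;
rigid-motion invariance of coordinate metrics holds to 1e-9 under random
rotations.  Test problem sizes are desk-scale by design: 100 random ipSAE
fixtures at 3–40 residues/chain, 20+20-residue dimers for lDDT oracles,
3×5 pose families over 20 seeds, 24–48-pair screens — large enough to
exercise every code path, small enough to run the whole suite in well
under a minute.

## Known limitations

* The masked interface pTM is a coordinate-contact approximation;
  distogram-weighted actifpTM values from ColabFold will differ.
* pDockQ uses the original single-interface fit, not the multi-interface
  pDockQ2 branch.
* Interface-lDDT values correlate with, but need not match to the second
  decimal, those of structure-search tools whose exact atom sets and
  directionality conventions are unpublished.
* Cross-paralogue mapping is sequence-based; structurally conserved but
  sequence-divergent interfaces below the alignability threshold are
  refused rather than guessed.
* The membrane check needs an externally oriented model; the package does
  not compute membrane placement.
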