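# Methods

This note documents the models and procedures implemented in `impscan`,
their assumptions, the defaults that matter, and what the synthetic
fixtures do and do not establish.

## Coordinate model and conventions

Structures are chains of residues of atoms; coordinates are in Å and
residues are addressed exclusively by PDB author numbering (integer plus
insertion code). No renumbering is ever performed: published mutation sites
(e.g. R1518 in one ARID1B isoform numbering, R1456 in another) stay in the
frame of the input file, and reconciling isoform frames is the user's
responsibility. Reading collapses altlocs to the highest-occupancy copy and
drops HETATM/water records; non-standard residues map to `X` and are
excluded from class-dependent computations with a warning. Hydrogens are
read when present, but every default geometric criterion operates on heavy
atoms, so hydrogen-free modeled structures are first-class inputs.

## Solvent accessibility

Shrake–Rupley quadrature with a 1.4 Å probe and 960 points per atom by
default. The point set is a fixed golden-spiral lattice, so areas are
bit-reproducible with no RNG; accuracy on an isolated atom is exact at the
printed precision and a dense independent quadrature agrees within a few
percent per atom. Van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 Å)
and the per-residue reference maxima (theoretical Gly-X-Gly values used for
relative accessibility) ship as data files. The quadrature count is a
speed/accuracy dial: the mutation scan uses 320 points for its per-mutant
NIS and burial terms (classification thresholds there are coarse — 0.05
relative SASA — and the reduced count changes no planted-fixture result),
while single descriptor reports use the 960-point default.

## Interface descriptor

A residue pair is an interfacial contact iff any heavy-atom pair across the
partition is within 5.5 Å; counting is at residue level (one count per
pair) to match the convention of the contact-based affinity model the
package reimplements. Contacts are keyed by unordered polarity-class pair
from a configurable class map; the shipped default is charged = {D,E,K,R},
polar = {C,H,N,Q,S,T,W,Y}, apolar = {A,F,G,I,L,M,P,V}. Histidine is not
charged by default (no protonation model); both the class map and the
salt-bridge criteria can opt it in, and an alternative map matching the
published consensus model's own classification (H charged, C/W apolar)
ships alongside.

Hydrogen bonds: cross-partition donor/acceptor N/O pairs within 3.5 Å.
When the file carries hydrogens, HBplus-style conditions are added
(H···acceptor ≤ 2.5 Å, donor-H-acceptor angle ≥ 90°); donors without a
modeled hydrogen fall back to the heavy-atom rule. Each donor–acceptor atom
pair counts once. Salt bridges: a (basic, acidic) residue pair counts once
iff the minimum distance between a listed basic nitrogen (Lys NZ; Arg
NE/NH1/NH2) and a listed acidic oxygen (Asp OD1/OD2; Glu OE1/OE2) is
≤ 4.0 Å.

The non-interacting surface (NIS) comprises residues of the *bound* complex
with relative SASA ≥ 0.05 that are not interfacial; its charged/apolar/
polar percentages are fractions of the NIS residue count. Note a
consequence exercised in the tests: a fully separated complex has zero
contacts but a fully populated NIS, so the affinity prediction for it is
the intercept plus NIS terms, not the bare intercept.

BSA = SASA(A alone) + SASA(B alone) − SASA(AB), clamped at zero with a
warning if quadrature noise drives it negative.

## Affinity model

ΔG (kcal/mol) is linear in the six contact counts and the apolar/charged
NIS percentages. Weights are data, never code: the packaged default file
carries the published consensus coefficients (w_cc = −0.09459,
w_ca = −0.10007, w_pp = 0.19577, w_pa = −0.22671, %NIS apolar 0.18681,
%NIS charged 0.13810, intercept −15.9433; classes without a published term
carry weight 0), so the pipeline's arithmetic is testable with toy weights
independently of that parameterization. ΔΔG_binding is mutant minus wild
type with positive = destabilizing. The package makes no claim of
reproducing any particular study's absolute energies — reported values such
as −13.6 or −18.0 kcal/mol for NLS–importin complexes depend on unpublished
structural models and third-party tool versions and serve only as scale
anchors in the documentation.

## Mutant construction and the folding surrogate

Side chains are rebuilt from idealized chemical-component templates
superimposed on the target backbone frame (N/CA/C); each rotatable χ is
scanned over the minimal grid {−60°, 60°, 180°} and the rotamer with the
fewest heavy-atom clashes (< 2.6 Å to atoms outside the residue) wins, ties
resolved by enumeration order. The procedure is deterministic; a seed
parameter exists for interface stability but the deterministic tie-break
never consults it. Glycine mutations truncate to the backbone; proline
keeps its template ring. This is a deliberate determinism-over-accuracy
choice: the package's claims concern the scan procedure and selection
logic, not side-chain prediction quality.

ΔΔG_folding is a surrogate score, not a force field:

    ΔΔG_f = w_clash·ΔN_clash + w_hb·max(0, −ΔN_intra_hbond)
          + w_sb·max(0, −ΔN_intra_bridge) + w_bur·max(0, −ΔA_buried_apolar)

with defaults 1.0 kcal/mol per clash, 0.5 per lost intra-chain H-bond or
salt bridge, and 0.012 kcal/mol/Ų of lost buried apolar side-chain area
(buried area per apolar residue = side-chain reference maximum minus
side-chain SASA, floored at zero). All deltas are mutant minus wild type
within the mutated chain group; identical structures score exactly zero.
The scorer's contract is pluggable so an external stability predictor can
replace it; its absolute values are only meaningful inside one scan.

## Pair nomination and the 19×19 scan

From a pose ensemble, a ligand residue's occupancy is the fraction of poses
in which it is interfacial. Pairs with both occupancies ≥ 0.5 and
side-chain-centroid distance ≤ 8 Å in the representative pose are
nominated, sorted by minimum occupancy then distance. The 0.5 and 8 Å
defaults quantify the qualitative criteria "present at the interface of a
large fraction of poses" and "in each other's vicinity" and are
configurable.

The scan enumerates all 19×19 non-wild-type substitution pairs at two
ligand sites (wild-type letters are excluded from the axes since their ΔΔG
is identically zero; single-site effects come from a single-site scan).
Each cell runs the full mutant-evaluation path; the grid is bit-identical
across same-seed reruns and transposes exactly under site-order swap.
Candidates pass iff ΔΔG_binding ≥ 0.8 and ΔΔG_folding ≤ 0.05 kcal/mol,
both inclusive; a folding-*stabilizing* mutation (negative ΔΔG_f) passes
the folding arm. The 0.8 threshold is treated as a criterion constant with
no further derivation.

## Elastic-network sampling and FG selection

The ANM places unit springs between Cα pairs within 15 Å; the 3N×3N
Hessian's six near-zero eigenvalues (tolerance 1e-8·λ_max) are the
rigid-body modes of a connected network, and disconnected networks trigger
a warning naming the components. Conformers displace the Cα trace along a
random combination of the lowest non-rigid modes, rescaled so the Cα RMSD
to the parent equals the target exactly; full atoms travel with their
residue by rigid transport (translation by the Cα shift plus the minimal
rotation aligning the local chain tangent). Energy minimization is replaced
by clash rejection-resampling (reject if any Cα pair < 2.5 Å; error out
above a bounded attempt budget), and "iterative" sampling re-seeds later
generations from accepted conformers round-robin. The sampler makes no
claim of thermodynamic weighting — it supplies geometric diversity for the
selection step, which is the operative criterion.

FG motifs are plain F-followed-by-G dipeptides (overlaps allowed); extended
nucleoporin patterns (FxFG, GLFG) are opt-in. A motif is exposed in a
conformer iff its Phe's relative SASA is ≥ 0.25 (an invented, configurable
threshold). The selected cluster is the largest set of exposed motifs whose
Phe-Cα atoms are *all pairwise* within 30 Å — a maximum clique, found
exactly for ≤ 25 motifs and by greedy search with single-swap improvement
beyond; a connected-component interpretation of "within 30 Å of each
other" is available behind a flag. Conformers reaching the minimum clique
size (default 5) are ranked by clique size, then mean intra-clique
distance.

## Sequence utilities

Classical NLS candidates: monopartite K(K/R)X(K/R) and bipartite
(K/R)(K/R)–X(10–12)–[≥3 basic of 5]; all overlapping hits are reported with
a basic-fraction score. These are convenience scanners, not predictors, and
published NLS boundaries enter the pipeline as user inputs. The disorder
proxy applies a windowed (21-residue) charge–hydropathy rule: rescaled
Kyte–Doolittle hydropathy below (|mean net charge| + 1.151)/2.785 calls the
residue disordered. It is a coarse stand-in for a real disorder predictor
and is labelled as such.

## Synthetic fixtures: what they establish

The generators build *geometric toys with exact planted features*, not
proteins: residues are compact atom groups with correct names and elements,
placed so that exactly the requested features exist under the default
criteria — generic contacts at 4.6 Å between anchor atoms, salt bridges at
3.7 Å (inside the 4.0 Å bridge cutoff but outside the 3.5 Å H-bond cutoff,
so a bridge never double-counts as an H-bond), and H-bonds at 2.9 Å between
a laterally offset backbone O/N pair, letting one residue pair host both a
bridge and an H-bond (required by the fixture at the reported
NLS-interface scale of 24 H-bonds and 4 bridges on 24 contacts). Every
generator re-runs the analysis modules on its output and asserts equality
with its truth ledger before returning, retrying with bounded jitter.

Pose ensembles realize per-residue occupancy patterns with rigid-body
transforms only: poses that keep all contacts are identities, poses that
break distant "decoy" contacts tilt the ligand about an axis through the
kept residues, and poses that break everything translate the ligand away;
each pose is verified against the intended interface pattern. FG fixtures
place motif Phe positions on a ring (cluster) or far apart (dispersed) so
the planted conformer's maximum clique is exact by construction.

Consequently, passing tests establish that the *detectors, counters,
scoring arithmetic, filters and selectors* behave exactly as specified on
inputs with known truth. They do not establish accuracy on real
structures: toy geometry has no packing, no backbone continuity across the
interface, and planted features sit comfortably inside their cutoffs
rather than at the ambiguous margins real interfaces produce.

## Problem sizes and numerical choices

Default test/acceptance sizes: toy complexes of 24–66 residues, 20-pose
ensembles, 50-conformer FG fixtures over a 130-residue/22-motif chain,
80–100-residue chains for ANM checks — sizes chosen so planted features are
unambiguous and the full pipeline (including three 19×19 scans) runs in
minutes on one CPU. Degenerate inputs are defined, not special-cased:
zero contacts give a zero descriptor with populated NIS; zero NIS residues
give 0% compositions with a warning; an all-buried FG ensemble selects
nothing; a zero-RMSD target returns exact copies. All randomness flows
through explicit integer seeds (numpy Generator); everything else is
deterministic, including the SASA point set and rotamer tie-breaks.

## Known limitations

No electrostatics, pKa, π-interactions or explicit solvent; no backbone
flexibility in mutants; the folding surrogate ignores entropy and
solvation; ANM sampling is harmonic and unweighted; mmCIF input is read
through the same parser but is not exercised by the test suite; nucleic
acids, ligands and crystallographic symmetry are out of scope.
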