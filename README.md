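# impscan

Structural-bioinformatics toolkit for the in-silico analysis of
nuclear-import protein–protein interfaces: interface descriptors,
contact-based binding-energy prediction, exhaustive paired-mutation ΔΔG
scanning with a dual selection criterion, and elastic-network conformer
sampling with FG-motif cluster selection.

The package targets the kind of question raised by cargo proteins such as
ARID1B, whose nuclear import runs through an NLS–importin-α (KPNA2)
interface, the importin-β (KPNB1) carrier, and FG-nucleoporin docking at
the nuclear pore (RANBP2): *which interface residues carry the binding, and
which paired substitutions would weaken cargo–importin binding without
destabilizing the cargo itself?*

## What it computes

**Interface descriptor.** For a two-group chain partition of a complex:
interfacial contacts (residue pairs with any heavy-atom pair ≤ 5.5 Å)
classified by polarity class pair (charged/polar/apolar → `cc, cp, ca, pp,
pa, aa`), buried surface area (BSA = SASA_A + SASA_B − SASA_AB via a
deterministic Shrake–Rupley quadrature), the charged/apolar/polar
composition of the non-interacting surface (NIS), geometric hydrogen bonds
(donor–acceptor N/O ≤ 3.5 Å, with HBplus-style H-distance and angle checks
when hydrogens are present) and salt bridges (basic N to acidic O ≤ 4.0 Å).

**Binding affinity.** A contact-based linear model

    ΔG = Σ_k w_k·IC_k + w_NIS,apolar·%NIS_apolar + w_NIS,charged·%NIS_charged + β₀

with weights shipped as data; the packaged default reproduces a published
contact-based consensus model. Mutational effects are scored as
ΔΔG_binding = ΔG(mutant) − ΔG(wild type), positive = weaker binding.

**Paired-mutation scan.** All 19×19 non-wild-type substitution pairs at two
ligand sites, with deterministic side-chain rebuilding (idealized templates,
minimal {−60°, 60°, 180°} χ rotamer grid, minimum-clash objective) and a
surrogate folding score ΔΔG_folding (clash, lost intra-chain H-bond/bridge,
lost buried apolar area terms; pluggable so a force-field scorer can be
substituted). Candidates pass the dual criterion
**ΔΔG_binding ≥ 0.8 and ΔΔG_folding ≤ 0.05 kcal/mol** (both inclusive).

**Pair nomination.** Given a docked-pose ensemble, residue pairs that are
interfacial in a large fraction of poses (occupancy ≥ 0.5 each) and mutually
close (side-chain centroids ≤ 8 Å) are nominated for scanning.

**FG-motif conformer selection.** A Cα anisotropic network model supplies
low-frequency modes; conformers are sampled at a fixed Cα RMSD with clash
rejection, and ranked by the largest set of solvent-exposed FG dipeptides
whose Phe-Cα atoms are *mutually* within 30 Å (maximum clique) — the
docking-readiness criterion for FG-nucleoporin segments (e.g. a conformer
with ≥ 5 exposed FG motifs within 30 Å of each other).

All inputs the original study leaves unpublished are replaced by the
`synth` module: self-verifying synthetic fixtures with planted ground truth
(contact counts per class, bridges, H-bonds, pose occupancies, FG cliques).

## Worked example

```bash
# generate a toy complex with a planted interface and its truth ledger
impscan simulate --kind complex --seed 42 --out demo

# descriptor + predicted binding energy
impscan affinity --complex demo/complex.pdb --group-a A --group-b B
```

    dG = -5.44 kcal/mol  (contacts=13, bsa=512.1 A^2, hbonds=3, bridges=2)

The 13 contacts, 3 hydrogen bonds and 2 salt bridges recover exactly the
counts recorded in `demo/ledger.json`; the ΔG is the linear model evaluated
on that descriptor (toy interfaces are far smaller than real ones, hence
the modest magnitude).

```bash
# exhaustive 19x19 scan at two ligand sites with a dual criterion
impscan scan --complex demo/complex.pdb --group-a A --group-b B \
    --site B:1 --site B:4 --criteria 0.09:0.05 --seed 7 --out demo/scan
```

    251 substitution pairs pass the dual criterion (outputs in demo/scan)

`demo/scan/` then holds `heatmap_binding.tsv`, `heatmap_folding.tsv`,
`heatmap_filter.tsv`, `candidates.tsv` and a `manifest.json` with
input/output digests. A row such as

    E1A-L4G	0.636107	0.000000	1

reads: mutating Glu1→Ala and Leu4→Gly destabilizes binding by
0.64 kcal/mol while leaving the surrogate folding score unchanged, so the
pair passes the (here deliberately loose) 0.09/0.05 filter. At the default
0.8/0.05 thresholds this toy interface yields no candidates — single toy
contacts carry less than 0.8 kcal/mol of model weight — which is the
expected behavior, not an error.

Other subcommands: `interface`, `compare`, `nominate-pairs`, `pick-fg`,
`scan-motifs`, `simulate` (see `impscan --help`).

## Limitations

Binding energies are linear-model predictions on contact counts, not
physics; the folding score is an explicitly labelled surrogate, comparable
only within a scan; synthetic fixtures are geometric toys, not proteins.
See `docs/methods.md` for the model details, defaults and their rationale.
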