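# Methods

This note documents the model and procedure implemented by `znsites`, its
tunable parameters, the synthetic data used to validate it, and the design
choices made where the design was genuinely open.

## Detection model

A zinc ion in a crystal structure is treated as biologically relevant when
its first coordination shell is dominated by protein atoms. The
operational rules, applied to the biological assembly of each structure:

* **Liganding atom**: any non-carbon, non-hydrogen, non-metal atom within
  the distance cutoff of the metal (centre-to-centre, boundary inclusive).
  Carbon is excluded because it does not donate lone pairs; other metals
  are never ligands of each other.
* **Angle filter**: within one residue, candidate atoms are examined
  nearest-first, and a candidate is dropped when the angle it subtends at
  the metal with any closer retained atom of the same residue is strictly
  below the minimum angle. This keeps a genuinely bidentate carboxylate
  (both oxygens ~60° apart at the metal) while discarding the second
  oxygen of a monodentate carboxylate that merely points near the metal.
  The angle is measured at the metal vertex — the only vertex that is
  well defined without bond-topology perception. The comparison carries a
  1e-9-degree guard so that geometry constructed exactly on the boundary
  is classified by the strict rule rather than by floating-point round-off.
* **Site formation**: metals sharing at least one liganding residue are
  merged transitively (union-find). Clusters without a zinc are dropped;
  clusters with one are *sites*, and they may be multi-metal ("co-active").
* **Salt filter**: a zinc is eligible only with ≥ 2 distinct protein
  liganding residues *and* ≥ 3 protein liganding atoms; waters and
  non-protein hetero ligands never count toward these thresholds. A site
  is kept when at least one of its zincs is eligible. Exclusion reasons
  are checked in a fixed order: missing side chains (backbone-only file),
  absence from the selected assembly, then the residue count before the
  atom count.
* **Symmetry handling**: metal copies that share a source atom and lie
  within the duplicate tolerance of each other are collapsed to the copy
  with the lowest transform index. Whole sites duplicated verbatim by
  assembly expansion (same source chain/residue identities) are stored
  once with a copy counter.

Every zinc atom of the input file is accounted for exactly once — in a
site or in an exclusion record. This accounting identity is asserted by
the tests on every scenario.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `cutoff` | 3.0 | Å | upper bound of first-shell Zn–ligand distances; typical Zn–N/S/O bonds are 1.9–2.6 Å |
| `min_angle` | 45 | degrees | separates independent donors from atoms shadowing a closer donor of the same residue |
| `min_protein_residues` | 2 | count | a single anchoring residue indicates a surface/salt zinc |
| `min_protein_atoms` | 3 | count | allows 2 residues when one is bidentate; excludes two-atom adventitious contacts |
| `duplicate_tolerance` | 0.5 | Å | coincident symmetry copies differ only by numeric noise (≪ 0.5 Å); genuine neighbours are > 2 Å apart |
| `metal_elements` | all metals | — | the full metallic block of the periodic table; Na/K/Mg/Ca count as co-active metals |

The distance cutoff is inclusive (≤ 3.0 Å) and the angle rule strict
(< 45°); both boundaries are exercised by dedicated tests.

## Assembly selection

PDB REMARK 350 records carry no energy annotation, so "the lowest-energy
zinc-containing assembly" cannot be read from the file format. The
instruction object accepts an optional energy (kcal/mol, e.g. supplied
from mmCIF-style metadata); when energies are absent the first-listed
zinc-containing assembly is used, then the first assembly, then the
asymmetric unit. The fallback chain is deterministic and documented as a
choice, not asserted as the behaviour of any other implementation.

Other parsing conventions: first model only for multi-model (NMR) files;
for alternate locations the highest-occupancy conformer wins, ties going
to altloc `A`; a file is *backbone-only* when no protein residue carries a
heavy atom outside {N, CA, C, O, CB}. Residues recognised as amino acids
(including modified ones such as MSE) count as protein residues; modified
residues appear as `X` in chain sequences. Coordinates are orthogonal
Ångströms; no crystallographic symmetry beyond the declared assembly
transforms is ever generated.

## Redundancy clustering

Chains are clustered by greedy incremental clustering: sequences in order
of decreasing length (ties by chain key) either join the first cluster
whose representative they match at ≥ 90% identity or seed a new cluster.
Identity is computed from a global alignment (match +1, mismatch 0, linear
gap −1) as matches divided by the shorter length, so a fragment identical
to part of a longer chain scores 1.0 — the convention of the widely used
greedy clustering tools. Comparing against the representative only (not
all members) keeps the procedure order-independent and O(n·k).

Two sites are equivalent when (i) the multisets of chain-cluster ids of
their liganding chains match, (ii) the liganding residue one-letter types
agree in sequence order per chain, and (iii) the residue types at sequence
positions −1/+1 of each liganding residue agree, with `-` encoding a chain
terminus so that termini never match a residue type. Multi-chain
(interface) sites compare chain-order-independently: per-chain entries are
sorted before comparison. Non-protein ligands (waters, cofactors) are not
part of the fingerprint. The representative of a cluster is the member
from the structure with the numerically lowest resolution; structures
without one (NMR) rank last, and remaining ties break on the smallest
PDB id.

## Statistics

* **Residue signature**: one-letter codes of the protein liganding
  residues, alphabetically, each with its count (`C3H1`, `D1E1H2`); the
  count suffix is always present.
* **Coordination mode**: the number of liganding contacts of a
  single-zinc site, *including* waters and other non-protein ligands.
* **Distance statistics**: mean and sample (n−1) standard deviation of
  contact distances per liganding element, pooled over single-zinc sites
  from structures with resolution strictly better than 3 Å.
* **Co-active table**: for multi-metal sites, the per-element atom count
  (for zinc: the count of *extra* zincs, so a three-zinc site contributes
  +2) and the number of sites containing the element, plus a
  metals-per-site histogram.
* **Enzymatic enrichment**: a protein is called enzymatic when any
  whitespace token of its molecule name ends in "ase" (a deliberate,
  simple heuristic — it also fires on words like "base"). The 2×2
  enrichment table is tested with a two-sided Fisher exact test
  (`scipy.stats.fisher_exact`); the test suite verifies it against exact
  integer enumeration of all tables with the observed margins.

## Synthetic data

The fixture generator builds small PDB files whose detection outcome is
known *by construction* — ground truth is what the generator placed, never
what the detector returned. Scenarios cover each rule: a water-only salt;
a tetrahedral Cys₄ site; a bidentate aspartate; an adjustable two-oxygen
angle probe; a 3-fold interface site that is a salt in the asymmetric unit
(the insulin-hexamer situation); multi-metal sites bridged by histidines;
an asymmetric unit with surplus chain copies excluded by the assembly (and
a variant where the assembly stamps out identical site copies, exercising
the copy counter); a backbone-only file; and k mutated protein families
for chain-cluster recovery.

Generator defaults place ligands at the characteristic distances of zinc
coordination (S 2.33 Å, N 2.12 Å, O 2.10 Å) with a small uniform jitter
(±0.04 Å), and each seed applies a random rigid rotation and translation
to the whole scene (assembly operators are conjugated accordingly), so a
hundred seeds probe a hundred poses of the same constructed truth.
Residue geometry is simplified: only the atoms the rules consult are
placed precisely (liganding side-chain atoms, enough backbone for protein
typing and sequence neighbours); backbones are laid out on a line well
outside the coordination shell. Written coordinates carry the PDB's three
decimals; all constructed distances and angles keep margins far above the
5·10⁻⁴ Å rounding except the deliberate exact-boundary angle probe, whose
truth is computed from the rounded, as-written geometry. Consequences for
interpretation: passing fixtures demonstrates the correctness of the
*rules*, not robustness to the full messiness of experimental data
(disorder, occupancy pathologies, chain breaks, exotic ligands).

For family fixtures, parents are drawn with pairwise identity < 50% and
each family member carries exactly ⌊rate·L⌋ substitutions of its parent
(rate < 10%, default 5%, L = 60). Because all sequences have equal length
and parents sort first within each family, parents seed the clusters and
every member matches its parent at ≥ 1 − rate, making exact k-cluster
recovery a constructive guarantee rather than a statistical hope.

## Problem sizes

The test suite and the acceptance script run every scenario at 100 seeds,
500 random metal-clustering instances (≤ 12 metals), family recovery for
k = 2..6, and exhaustive Fisher verification for all 2×2 tables with
margins ≤ 30 (one representative per symmetry orbit of row swap, column
swap and transpose, after verifying the implementation's invariance under
those symmetries). The synthetic corpus built end-to-end for the distance
and database statistics contains 55 structures. These sizes make the full
validation run in well under a minute while exercising every code path;
they are choices of this package, and all of them are single-CPU.

## Known limitations

* PDB format only; mmCIF input and crystallographic (SMTRY) symmetry
  expansion are out of scope — sites formed by lattice neighbours that
  the deposited assembly does not include will be missed.
* The angle filter compares atoms within one residue only; whether
  cross-residue shadowing should also be filtered is ambiguous, and the
  within-residue reading is implemented.
* The "-ase" enzyme heuristic is intentionally naive.
* Greedy identity clustering is order-canonical but, like all greedy
  clusterings, need not be optimal for borderline families near the 90%
  threshold.
* The database build holds detected sites in memory for the clustering
  pass; it targets thousands of structures, not the whole archive, on a
  laptop.
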