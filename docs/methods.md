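# Methods

## Design model

Candidates follow a three-part decomposition: a galantamine (GAL)
binding core, a flexible linker, and a terminal aromatic fragment. The
core is norgalantamine attached through its ring nitrogen (the free
base; descriptors are computed without microspecies or protonation-state
enumeration, consistent with the lead's reported molecular formula
C33H36N2O4). Linkers carry two attachment points, written as numbered
dummy atoms in SMILES — `[*:1]` faces the core, `[*:2]` the aromatic —
so assembly is directional and unambiguous. Aromatic fragments carry a
single `[*:1]`. Both junction bonds are single bonds; the synthesized
lead (amide linker `L10` to 2-biphenyl `Ar1a`) confirms single-bond
junctions at both ends.

Assembly is implemented by combining fragment graphs, bonding the
neighbours of the paired dummy atoms, deleting the dummies, and
sanitising/canonicalising with RDKit. Two invariants are enforced and
property-tested: heavy-atom conservation (product atoms = fragment atoms
minus the four dummies) and bonding-order associativity (core–linker
first or linker–aromatic first yields the same canonical product). Mass
is conserved to 1e-6 Da because dummy atoms are massless.

## Library and pairing rules

The packaged registry holds 1 core, 18 linkers and 120 aromatic variants
in 16 groups (16, 22, 9, 15, 2, 2, 3, 14, 17, 13, 2, 1, 1, 1, 1, 1
variants for `Ar1`–`Ar16`). Pairing rules: every group combines with
linkers `L1`–`L10`, except `Ar13`–`Ar16` which use the seven-linker
subset `L1`–`L3`, `L6`–`L8`, `L10`; the four variants `Ar9d`, `Ar9e`,
`Ar9h`, `Ar9j` additionally combine with `L11`–`L18`. Enumeration is
therefore 112×10 + 4×(10+8) + 4×7 = 1220 candidates, with per-group
tallies fixed by the rules. Duplicate canonical structures are retained
(the total is defined by the rules, not by deduplication); a separate
report lists collisions.

Structure provenance is explicit in the registry: the core, `L10`, and
each group's unsubstituted parent variant `a` are real structures of the
named chemotypes (biphenyl, pyridinone, indole, benzimidazole,
phenylpyridazinone, quinolines, pyrazole, phenyl, quinazolinediones,
tetrahydro(iso)quinolines, isoquinoline); the remaining substituent
variants and linkers are distinct, valid placeholder structures because
their exact regiochemistry is not machine-readable from the source
figures. Counting results depend only on registry shape, never on
placeholder chemistry; strict assembly refuses placeholders and directs
users to counting mode.

## Descriptors

Molecular formulas are produced in Hill order by RDKit. Molecular weight
and calculated elemental percents are computed from packaged
conventional atomic weights (H 1.00794, C 12.0107, N 14.0067, O 15.9994,
…), the values classical elemental-analysis calculators use; this
reproduces the lead's printed MW 524.65 and calcd C 75.55 / H 6.92 /
N 5.34 at two decimals. Full precision is kept internally and rounding
happens only at reporting. H-bond counts use the Lipinski definitions —
donors are N/O atoms bearing at least one hydrogen, acceptors are all N
and O atoms — which match the lead's profile (donors: the core's enol
OH and the linker amide NH; acceptors: all six heteroatoms). TPSA is
Ertl's topological method and logP the Wildman–Crippen atomic scheme,
both via RDKit. Measured quantities the pipeline cannot compute (pKa,
logD7.4) are accepted as pass-through annotations only.

## BBB filtering

Passive BBB permeability is approximated by a cascade of transparent
rules rather than trained classifiers: an ellipse in (logP, TPSA) space
(inside-or-on passes; rotation supported, boundary tolerance 1e-9 on the
normalised quadratic form) and closed-interval range rules on any
descriptor column. Consensus semantics are a strict AND — a candidate
must pass every stage — and stage tallies are non-increasing by
construction, while the final survivor *set* is order-invariant. The
shipped default cascade (`bbb_cascade_synthetic.yaml`) is a
package-authored approximation of the known clustering of CNS drugs at
moderate lipophilicity and low polar surface area (ellipse centred at
logP 2.5, TPSA 45 Å², semi-axes 3.5 and 48, plus TPSA ≤ 90 Å²,
MW ≤ 600, HBD ≤ 3); it is labelled synthetic because it does not
reproduce any published classifier's fitted coefficients, and the
published pass counts of externally trained predictors are accordingly
not reproduction targets. The cascade length, parameters and membership
are fully configurable.

## Docking-score triage

Docking scores (higher = better) are ingested from CSV, never computed.
A candidate is excluded when the RMSD between its docked core pose and
the referent ligand pose — computed over matched atom pairs with no
superposition — is strictly greater than the cut (default 1.5 Å);
boundary poses are retained. Survivors are ranked by descending score
with lexicographic candidate-id tie-breaks for reproducibility, then
binned: `n_above_cut` counts scores ≥ the score cut (default 100),
`n_below_referent` counts scores strictly below the referent ligand's
score (default 77.73). The representative lead is the highest-ranked
top-N candidate combining the modal aromatic group, the modal linker and
the unsubstituted "a" variant, with a documented fallback chain —
(1) modal group + modal linker + "a"; (2) modal group + "a";
(3) highest-ranked modal-group member — so selection is total. Modal
ties break by count, then lexicographically.

## Synthetic fixtures

The score-table generator takes an exact-count specification: total
records, number failing the RMSD cut, attained score extrema, counts at
or above the score cut and strictly below the referent, and the fragment
composition of the top N. Scores are drawn uniformly inside half-open
bands ([referent, cut) for the mid band, etc.) so counts are exact;
pose RMSDs are uniform in [0, cut] for survivors and (cut, cut+1] for
excluded records; all randomness comes from `numpy.random.default_rng`
with the spec's seed, making output byte-identical per seed. Feasibility
is validated up front (band counts vs. sizes, extrema vs. band
membership, degenerate ranges) and infeasible specifications are
rejected rather than silently adjusted. The default study-condition
specification is 199 records, 8 excluded, survivor scores spanning
77.40–115.38 with 25 at or above 100 and exactly one below 77.73, and a
top ten with nine modal-group and seven modal-linker members; the
generator maximises the overlap of the two so a joint representative
(the modal group's "a" variant on the modal linker) exists.

What the fixtures do **not** emulate: realistic docking-score
distributions beyond the band structure, correlations between score and
pose RMSD, or chemistry-dependent scores. Passing the triage tests
therefore validates the triage logic — exclusion, ranking, binning,
frequency analysis, selection — not any docking engine.

## Problem sizes and determinism

The full enumeration (1220 candidates) runs in well under a second in
counting mode; the oracle-equivalence property runs 100 randomized small
registries (≤ 4 groups × ≤ 4 variants, ≤ 6 linkers) against a
brute-force triple loop. All tests and the acceptance script are seeded;
re-running with the same configuration and seed reproduces byte-identical
data outputs (timestamps live only in logs).

## Known limitations

- Placeholder fragments make descriptor/BBB stages meaningless for the
  packaged library beyond the explicitly real fragments; those stages
  are exercised on real structures and user-supplied registries.
- The BBB cascade is a rule-based stand-in; its absolute pass rates are
  not comparable to trained predictors.
- No 3D conformers, stereochemistry perception beyond the input SMILES,
  synthetic-accessibility scoring, or protonation-state modelling.
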