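# galfrag

Fragment-based design and virtual-screening triage of galantamine-derived
acetylcholinesterase (AChE) inhibitors.

Galantamine (GAL) is a safe but moderate AChE inhibitor that binds at the
bottom of the enzyme's catalytic gorge. A well-established strategy for
improving its potency is to extend it through a flexible linker to an
aromatic fragment that reaches the peripheral anionic site at the gorge
entrance. `galfrag` implements that design campaign as a reusable,
tested pipeline:

1. **Fragment registry** — a library of attachment-marked SMILES
   fragments: one GAL binding core, two-point linkers `L1`–`L18`, and
   one-point aromatic fragments in groups `Ar1`–`Ar16` whose substituted
   variants carry letter suffixes (`Ar1a` is the unsubstituted parent of
   group `Ar1`), plus pairing rules describing which linker set combines
   with which aromatic group.
2. **Assembly & enumeration** — every candidate is
   `core–linker–aromatic` with single bonds at both junctions; the
   packaged registry and rules enumerate to a 1220-member combinatorial
   library.
3. **Descriptors** — Hill formula, average molecular weight, calculated
   elemental percents, Lipinski H-bond donors/acceptors, Ertl TPSA and
   Wildman–Crippen logP per candidate.
4. **BBB triage** — a configurable cascade of rule-based
   blood–brain-barrier filters (a lipophilicity/polarity ellipse in
   (logP, TPSA) space plus descriptor range rules) combined with strict
   AND semantics.
5. **Docking-score triage & lead selection** — docking scores are
   ingested (never computed): poses deviating more than 1.5 Å from the
   referent ligand pose are excluded, survivors are ranked, binned
   against a score cut (default 100) and against the referent ligand's
   own score (default 77.73), and a representative lead is chosen from
   the fragment composition of the top ten — the highest-ranked
   candidate combining the modal aromatic group, the modal linker, and
   the unsubstituted ("a") variant.

A synthetic-fixture module generates placeholder registries of any shape
and docking score tables with exactly prescribed summary statistics, so
every stage is testable without external engines.

## Worked example

```python
import galfrag as gf

reg, rules = gf.packaged_registry(), gf.packaged_rules()
result = gf.enumerate_library(reg, rules)
print(result.total)                      # 1220
print(result.tally_for("Ar1"))           # 160
print(result.tally_for("Ar9"))           # 202 (17 variants x L1-L10 + 4 x L11-L18)

lead = gf.assemble(reg.core, reg.get("L10"), reg.get("Ar1a"))
ds = gf.compute_descriptors(lead.structure)
print(ds.formula)                        # C33H36N2O4
print(round(ds.mw, 2))                   # 524.65
print(ds.hbd, ds.hba)                    # 2 6
print(ds.elemental)                      # {'C': 75.55, 'H': 6.92, 'N': 5.34, 'O': 12.2}
```

The lead candidate `GAL-L10-Ar1a` is the GAL core N-alkylated with an
ethylene-amide linker to 2-biphenyl (the two donors are the core's enol
OH and the linker's amide NH; all six N/O heteroatoms count as
acceptors).

Triage of a score table with the study's statistics:

```python
records = gf.make_score_table(gf.study_score_spec(seed=1))
report = gf.triage(records)              # rmsd_cut=1.5, score_cut=100, referent=77.73
print(report.n_excluded, report.n_ranked)        # 8 191
print(report.n_above_cut, report.n_below_cut)    # 25 166
from galfrag.triage import provenance_from_ids
prov = provenance_from_ids(report.top_n)
print(gf.select_representative(report.top_n, prov, reg))  # GAL-L10-Ar1a
```

The same pipeline is available from a shell:

```bash
galfrag enumerate                # per-group tally, ends with "total: 1220"
galfrag fixtures --seed 1 --output-dir out
galfrag triage --scores out/scores.csv --output-dir out
galfrag select --scores out/scores.csv
galfrag run-all --scores out/scores.csv --output-dir out
```

## Scope

Docking itself (the scoring function, pose generation), trained
machine-learning BBB predictors, molecular dynamics and wet-lab assays
are out of scope: scores are ingested from CSV, the BBB stage is a
transparent rule-based stand-in, and the synthetic-fixture module
supplies inputs with the right statistical structure. See
`docs/methods.md` for the model, parameter defaults and limitations.
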