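"""Assemble core + linker + aromatic fragments and enumerate the library.

Assembly forms two single bonds — core↔linker at the linker's ``[*:1]``
end and linker↔aromatic at its ``[*:2]`` end — removes the dummy atoms,
sanitises (valence check) and canonicalises the product.  Enumeration
walks every aromatic variant against its group's linker set plus any
variant-level extra pairs and reports per-group tallies; duplicates by
canonical structure are reported, never silently dropped, so the library
total is the count fixed by the pairing rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from rdkit import Chem

from .registry import FragmentRecord, FragmentRegistry, PairingRules, RegistryError

__all__ = [
    "CandidateMolecule",
    "EnumerationResult",
    "AssemblyError",
    "assemble",
    "join_fragments",
    "enumerate_library",
    "dedup_report",
    "write_library_csv",
    "write_library_sdf",
]


class AssemblyError(ValueError):
    """Raised when fragments cannot be joined into a valid molecule."""


@dataclass(frozen=True)
class CandidateMolecule:
    """An assembled core–linker–aromatic derivative.

    ``structure`` is the canonical SMILES of the product (``None`` in
    counting-only enumeration); ``provenance`` records the three source
    fragment ids (core, linker, aromatic).
    """

    candidate_id: str
    linker_id: str
    aromatic_id: str
    group_id: str
    structure: str | None
    provenance: tuple[str, str, str]


def candidate_id_for(linker_id: str, aromatic_id: str) -> str:
    return f"GAL-{linker_id}-{aromatic_id}"


def _find_dummy(mol: Chem.Mol, map_num: int) -> int:
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == map_num:
            return atom.GetIdx()
    raise AssemblyError(f"no attachment marker [*:{map_num}] in fragment")


def join_fragments(a: Chem.Mol, b: Chem.Mol, map_a: int, map_b: int) -> Chem.Mol:
    """Join two fragments with a single bond between the neighbours of the
    named dummy atoms, removing both dummies.

    Remaining attachment markers on either fragment are preserved, so the
    operation composes (core–linker first or linker–aromatic first gives
    the same final product).
    """
    n_a = a.GetNumAtoms()
    combo = Chem.RWMol(Chem.CombineMols(a, b))
    da = _find_dummy(a, map_a)
    db = n_a + _find_dummy(b, map_b)
    nbrs_a = combo.GetAtomWithIdx(da).GetNeighbors()
    nbrs_b = combo.GetAtomWithIdx(db).GetNeighbors()
    if len(nbrs_a) != 1 or len(nbrs_b) != 1:
        raise AssemblyError("attachment dummy must have exactly one neighbour")
    combo.AddBond(nbrs_a[0].GetIdx(), nbrs_b[0].GetIdx(), Chem.BondType.SINGLE)
    for idx in sorted((da, db), reverse=True):
        combo.RemoveAtom(idx)
    product = combo.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:  # rdkit raises several sanitization subclasses
        raise AssemblyError(f"product fails valence/sanitization: {exc}") from exc
    return product


def assemble(
    core: FragmentRecord,
    linker: FragmentRecord,
    aromatic: FragmentRecord,
    strict: bool = True,
) -> CandidateMolecule:
    """Bond core–linker–aromatic into a single candidate molecule.

    The linker's ``[*:1]`` end bonds to the core attachment and its
    ``[*:2]`` end to the aromatic attachment; both junctions are single
    bonds.  Atom conservation is enforced: the product's heavy-atom count
    must equal the fragments' total minus the three dummies.

    Raises
    ------
    AssemblyError
        If roles are wrong, a placeholder fragment is used in strict mode,
        or the bonded product fails valence checks.
    """
    for rec, role in ((core, "core"), (linker, "linker"), (aromatic, "aromatic")):
        if rec.role != role:
            raise AssemblyError(
                f"{rec.fragment_id}: expected role {role}, got {rec.role}"
            )
        if strict and rec.placeholder:
            raise AssemblyError(
                f"{rec.fragment_id} is a placeholder structure; strict "
                "assembly refuses it — use counting mode (mode='count_only') "
                "for workflows that only need totals"
            )
    mols = {r.fragment_id: r.to_mol() for r in (core, linker, aromatic)}
    core_linker = join_fragments(mols[core.fragment_id], mols[linker.fragment_id], 1, 1)
    product = join_fragments(core_linker, mols[aromatic.fragment_id], 2, 1)

    n_dummies = sum(
        1 for m in mols.values() for a in m.GetAtoms() if a.GetAtomicNum() == 0
    )
    n_expected = sum(m.GetNumAtoms() for m in mols.values()) - n_dummies
    if product.GetNumAtoms() != n_expected:
        raise AssemblyError(
            f"atom conservation violated: product has {product.GetNumAtoms()} "
            f"heavy atoms, expected {n_expected}"
        )
    smiles = Chem.MolToSmiles(product)
    return CandidateMolecule(
        candidate_id=candidate_id_for(linker.fragment_id, aromatic.fragment_id),
        linker_id=linker.fragment_id,
        aromatic_id=aromatic.fragment_id,
        group_id=aromatic.group_id,
        structure=smiles,
        provenance=(core.fragment_id, linker.fragment_id, aromatic.fragment_id),
    )


@dataclass
class EnumerationResult:
    """Candidates plus per-group tally of an enumeration run."""

    candidates: list[CandidateMolecule]
    tally: pd.DataFrame  # columns group_id, n_candidates
    total: int

    def tally_for(self, group_id: str) -> int:
        row = self.tally.loc[self.tally["group_id"] == group_id, "n_candidates"]
        return int(row.iloc[0]) if len(row) else 0


def enumerate_library(
    reg: FragmentRegistry,
    rules: PairingRules,
    mode: Literal["count_only", "full"] = "count_only",
) -> EnumerationResult:
    """Enumerate every candidate admitted by the pairing rules.

    Each aromatic variant combines with its group's linker set
    (``default_linkers`` unless overridden) plus any supplementary linkers
    listed for that specific variant in ``extra_pairs``.  Output order is
    deterministic: aromatic group, then variant, then linker in rule order.

    In ``count_only`` mode candidate structures are ``None`` (placeholder
    fragments are admitted); in ``full`` mode every candidate is assembled,
    sanitised and canonicalised, and duplicate canonical structures are
    retained (use :func:`dedup_report` to list collisions).
    """
    rules.validate_against(reg)
    core = reg.core
    candidates: list[CandidateMolecule] = []
    tally_rows: list[dict] = []
    for group in reg.aromatic_groups:
        group_linkers = rules.linkers_for_group(group)
        n_group = 0
        variants = sorted(
            (r for r in reg.aromatics if r.group_id == group),
            key=lambda r: (r.variant, r.fragment_id),
        )
        for arom in variants:
            linker_ids = group_linkers + rules.extra_linkers_for(arom.fragment_id)
            for lid in linker_ids:
                linker = reg.get(lid)
                if mode == "full":
                    cand = assemble(core, linker, arom, strict=True)
                else:
                    cand = CandidateMolecule(
                        candidate_id=candidate_id_for(lid, arom.fragment_id),
                        linker_id=lid,
                        aromatic_id=arom.fragment_id,
                        group_id=group,
                        structure=None,
                        provenance=(core.fragment_id, lid, arom.fragment_id),
                    )
                candidates.append(cand)
                n_group += 1
        tally_rows.append({"group_id": group, "n_candidates": n_group})
    seen: set[str] = set()
    for cand in candidates:
        if cand.candidate_id in seen:
            raise AssemblyError(
                f"duplicate candidate_id {cand.candidate_id!r}: pairing "
                "rules list the same linker twice for one variant"
            )
        seen.add(cand.candidate_id)
    tally = pd.DataFrame(tally_rows, columns=["group_id", "n_candidates"])
    return EnumerationResult(candidates=candidates, tally=tally, total=len(candidates))


def dedup_report(candidates: Iterable[CandidateMolecule]) -> pd.DataFrame:
    """List canonical-structure collisions among assembled candidates.

    Returns a DataFrame (structure, candidate_ids, n) with one row per
    structure shared by more than one candidate.  Candidates without a
    structure (counting mode) are ignored.
    """
    groups: dict[str, list[str]] = {}
    for cand in candidates:
        if cand.structure is not None:
            groups.setdefault(cand.structure, []).append(cand.candidate_id)
    rows = [
        {"structure": smi, "candidate_ids": ";".join(ids), "n": len(ids)}
        for smi, ids in groups.items()
        if len(ids) > 1
    ]
    return pd.DataFrame(rows, columns=["structure", "candidate_ids", "n"])


def write_library_csv(result: EnumerationResult, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "candidate_id": c.candidate_id,
                "linker_id": c.linker_id,
                "aromatic_id": c.aromatic_id,
                "group_id": c.group_id,
                "structure": c.structure if c.structure is not None else "",
            }
            for c in result.candidates
        ]
    )
    df.to_csv(path, index=False)


def write_library_sdf(result: EnumerationResult, path: str | Path) -> int:
    """Write assembled candidates to SDF with provenance properties.

    Returns the number of molecules written; counting-mode candidates
    (no structure) are skipped.
    """
    n = 0
    writer = Chem.SDWriter(str(path))
    try:
        for cand in result.candidates:
            if cand.structure is None:
                continue
            mol = Chem.MolFromSmiles(cand.structure)
            if mol is None:
                continue
            mol.SetProp("_Name", cand.candidate_id)
            mol.SetProp("candidate_id", cand.candidate_id)
            mol.SetProp("linker_id", cand.linker_id)
            mol.SetProp("aromatic_id", cand.aromatic_id)
            mol.SetProp("group_id", cand.group_id)
            writer.write(mol)
            n += 1
    finally:
        writer.close()
    return n
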