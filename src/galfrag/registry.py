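"""Fragment library registry: records, pairing rules, validation, and I/O.

The library follows a core–linker–aromatic decomposition: a single binding
core (galantamine attached through its ring nitrogen), two-attachment-point
linkers named ``L1``–``L18``, and one-attachment-point aromatic fragments
organised into groups ``Ar1``–``Ar16`` whose substituted variants carry
letter suffixes (``Ar1a``, ``Ar1b``, ...).  Variant ``a`` is by convention
the unsubstituted parent structure of its group.

Structures are SMILES with numbered dummy atoms marking attachment points:
``[*:1]`` for the first (core-facing) attachment and ``[*:2]`` for the
second (aromatic-facing) attachment of a linker.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from rdkit import Chem

__all__ = [
    "FragmentRecord",
    "FragmentRegistry",
    "PairingRules",
    "RegistryError",
    "load_registry",
    "save_registry",
    "load_pairing_rules",
    "save_pairing_rules",
    "registry_summary",
    "packaged_registry",
    "packaged_rules",
]

#: Required attachment-point count per fragment role.
ROLE_ATTACHMENTS = {"core": 1, "linker": 2, "aromatic": 1}

LINKER_GROUP = "L"

_DUMMY_RE = re.compile(r"\[\*:(\d+)\]")

REGISTRY_COLUMNS = [
    "fragment_id",
    "role",
    "group_id",
    "variant",
    "structure",
    "n_attachments",
]


class RegistryError(ValueError):
    """Raised for malformed registry files or inconsistent fragment data."""


@dataclass(frozen=True)
class FragmentRecord:
    """One fragment of the library.

    Parameters
    ----------
    fragment_id
        Unique identifier, e.g. ``"L10"`` or ``"Ar1a"``.
    role
        One of ``core``, ``linker``, ``aromatic``.
    group_id
        Group the fragment belongs to (``"Ar1"``; linkers all use ``"L"``).
    variant
        Variant letter(s); empty for the core and for linkers.
    structure
        Attachment-marked SMILES.
    n_attachments
        Number of ``[*:n]`` dummy atoms; fixed by role (core 1, linker 2,
        aromatic 1).
    placeholder
        True when the structure is a stand-in whose exact chemistry is not
        specified by the source library (counting workflows only; strict
        assembly refuses these).
    """

    fragment_id: str
    role: str
    group_id: str
    variant: str
    structure: str
    n_attachments: int
    placeholder: bool = False

    def validate(self, strict: bool = True) -> None:
        if self.role not in ROLE_ATTACHMENTS:
            raise RegistryError(
                f"{self.fragment_id}: unknown role {self.role!r}"
            )
        expected = ROLE_ATTACHMENTS[self.role]
        if self.n_attachments != expected:
            raise RegistryError(
                f"{self.fragment_id}: role {self.role} requires "
                f"{expected} attachment(s), got {self.n_attachments}"
            )
        markers = _DUMMY_RE.findall(self.structure)
        if len(markers) != self.n_attachments:
            raise RegistryError(
                f"{self.fragment_id}: structure has {len(markers)} "
                f"attachment marker(s), expected {self.n_attachments}"
            )
        if sorted(int(m) for m in markers) != list(range(1, expected + 1)):
            raise RegistryError(
                f"{self.fragment_id}: attachment markers must be numbered "
                f"1..{expected}, got {markers}"
            )
        if strict:
            mol = Chem.MolFromSmiles(self.structure)
            if mol is None:
                raise RegistryError(
                    f"{self.fragment_id}: structure does not parse: "
                    f"{self.structure!r}"
                )

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.structure)
        if mol is None:
            raise RegistryError(
                f"{self.fragment_id}: structure does not parse: "
                f"{self.structure!r}"
            )
        return mol


@dataclass
class FragmentRegistry:
    """A validated fragment library with a group index.

    Exactly one record has role ``core``.  ``group_index`` maps each group
    id to the ordered list of its member fragment ids and is rebuilt from
    the records, so it can never dangle.
    """

    records: list[FragmentRecord]
    group_index: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {}
        for rec in self.records:
            if rec.fragment_id in self._by_id:
                raise RegistryError(
                    f"duplicate fragment_id {rec.fragment_id!r}"
                )
            self._by_id[rec.fragment_id] = rec
        cores = [r for r in self.records if r.role == "core"]
        if len(cores) != 1:
            raise RegistryError(
                f"registry must contain exactly one core fragment, "
                f"found {len(cores)}"
            )
        index: dict[str, list[str]] = {}
        for rec in self.records:
            index.setdefault(rec.group_id, []).append(rec.fragment_id)
        self.group_index = index

    @property
    def core(self) -> FragmentRecord:
        return next(r for r in self.records if r.role == "core")

    @property
    def linkers(self) -> list[FragmentRecord]:
        return [r for r in self.records if r.role == "linker"]

    @property
    def aromatics(self) -> list[FragmentRecord]:
        return [r for r in self.records if r.role == "aromatic"]

    @property
    def aromatic_groups(self) -> list[str]:
        seen: list[str] = []
        for r in self.aromatics:
            if r.group_id not in seen:
                seen.append(r.group_id)
        return seen

    def get(self, fragment_id: str) -> FragmentRecord:
        try:
            return self._by_id[fragment_id]
        except KeyError:
            raise RegistryError(f"unknown fragment_id {fragment_id!r}") from None

    def __contains__(self, fragment_id: str) -> bool:
        return fragment_id in self._by_id

    def __len__(self) -> int:
        return len(self.records)

    def validate(self, strict: bool = True) -> None:
        for rec in self.records:
            rec.validate(strict=strict)


@dataclass
class PairingRules:
    """Which linkers combine with which aromatic fragments.

    ``default_linkers`` applies to every aromatic group not named in
    ``group_overrides``.  ``extra_pairs`` adds supplementary linkers to
    individual aromatic *variants* (not groups) on top of the group rule.
    """

    default_linkers: list[str]
    group_overrides: dict[str, list[str]] = field(default_factory=dict)
    extra_pairs: dict[str, list[str]] = field(default_factory=dict)

    def linkers_for_group(self, group_id: str) -> list[str]:
        return list(self.group_overrides.get(group_id, self.default_linkers))

    def extra_linkers_for(self, aromatic_id: str) -> list[str]:
        return list(self.extra_pairs.get(aromatic_id, []))

    def validate_against(self, reg: FragmentRegistry) -> None:
        """Check every referenced id exists in *reg* with the right role."""
        linker_ids = {r.fragment_id for r in reg.linkers}
        aromatic_ids = {r.fragment_id for r in reg.aromatics}
        aromatic_groups = set(reg.aromatic_groups)
        referenced = set(self.default_linkers)
        for ids in self.group_overrides.values():
            referenced.update(ids)
        for ids in self.extra_pairs.values():
            referenced.update(ids)
        missing = referenced - linker_ids
        if missing:
            raise RegistryError(
                f"pairing rules reference unknown linkers: {sorted(missing)}"
            )
        bad_groups = set(self.group_overrides) - aromatic_groups
        if bad_groups:
            raise RegistryError(
                f"group_overrides reference unknown aromatic groups: "
                f"{sorted(bad_groups)}"
            )
        bad_variants = set(self.extra_pairs) - aromatic_ids
        if bad_variants:
            raise RegistryError(
                "extra_pairs must reference aromatic variant ids present in "
                f"the registry; unknown: {sorted(bad_variants)}"
            )


def load_registry(path: str | Path, strict: bool = True) -> FragmentRegistry:
    """Read a registry CSV and return a validated :class:`FragmentRegistry`.

    The file is UTF-8 CSV with header
    ``fragment_id,role,group_id,variant,structure,n_attachments`` and an
    optional trailing ``provenance`` column (``explicit``/``placeholder``).
    In strict mode every structure must parse as SMILES; in non-strict mode
    only attachment-marker syntax is checked, admitting placeholder
    structures for counting-only workflows.
    """
    path = Path(path)
    records: list[FragmentRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing_cols = [c for c in REGISTRY_COLUMNS if c not in header]
        if missing_cols:
            raise RegistryError(
                f"{path}: missing required columns {missing_cols}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = FragmentRecord(
                    fragment_id=row["fragment_id"].strip(),
                    role=row["role"].strip(),
                    group_id=row["group_id"].strip(),
                    variant=row["variant"].strip(),
                    structure=row["structure"].strip(),
                    n_attachments=int(row["n_attachments"]),
                    placeholder=(
                        row.get("provenance", "explicit").strip()
                        == "placeholder"
                    ),
                )
            except (KeyError, ValueError, AttributeError) as exc:
                raise RegistryError(f"{path}: line {lineno}: {exc}") from exc
            try:
                rec.validate(strict=strict)
            except RegistryError as exc:
                raise RegistryError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return FragmentRegistry(records=records)


def save_registry(reg: FragmentRegistry, path: str | Path) -> None:
    """Write *reg* to CSV in the format read by :func:`load_registry`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REGISTRY_COLUMNS + ["provenance"])
        for rec in reg.records:
            writer.writerow(
                [
                    rec.fragment_id,
                    rec.role,
                    rec.group_id,
                    rec.variant,
                    rec.structure,
                    rec.n_attachments,
                    "placeholder" if rec.placeholder else "explicit",
                ]
            )


def load_pairing_rules(path: str | Path) -> PairingRules:
    """Read pairing rules from YAML.

    Keys: ``default_linkers`` (list), ``group_overrides`` (map group id →
    linker-id list), ``extra_pairs`` (map aromatic variant id → linker-id
    list).
    """
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if "default_linkers" not in data:
        raise RegistryError(f"{path}: missing key 'default_linkers'")
    return PairingRules(
        default_linkers=list(data["default_linkers"]),
        group_overrides={
            str(k): list(v) for k, v in (data.get("group_overrides") or {}).items()
        },
        extra_pairs={
            str(k): list(v) for k, v in (data.get("extra_pairs") or {}).items()
        },
    )


def save_pairing_rules(rules: PairingRules, path: str | Path) -> None:
    data = {
        "default_linkers": list(rules.default_linkers),
        "group_overrides": {k: list(v) for k, v in rules.group_overrides.items()},
        "extra_pairs": {k: list(v) for k, v in rules.extra_pairs.items()},
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def registry_summary(reg: FragmentRegistry):
    """Tabulate variant counts: one row per aromatic group plus a linker row.

    Returns a :class:`pandas.DataFrame` with columns ``group_id`` and
    ``n_variants``; aromatic rows sum to the number of aromatic records.
    """
    import pandas as pd

    rows = []
    for group in reg.aromatic_groups:
        n = sum(1 for r in reg.aromatics if r.group_id == group)
        rows.append({"group_id": group, "n_variants": n})
    n_linkers = len(reg.linkers)
    if n_linkers:
        rows.append({"group_id": LINKER_GROUP, "n_variants": n_linkers})
    return pd.DataFrame(rows, columns=["group_id", "n_variants"])


def _data_path(name: str) -> Path:
    return Path(resources.files("galfrag").joinpath("data", name))  # type: ignore[arg-type]


def packaged_registry(strict: bool = True) -> FragmentRegistry:
    """The fragment library shipped with the package (1 core, 18 linkers,
    120 aromatic variants in 16 groups)."""
    return load_registry(_data_path("registry.csv"), strict=strict)


def packaged_rules() -> PairingRules:
    """The pairing rules shipped with the package: L1–L10 by default, a
    seven-linker subset for Ar13–Ar16, and L11–L18 additionally for the
    Ar9 variants d, e, h and j."""
    return load_pairing_rules(_data_path("pairing_rules.yaml"))
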