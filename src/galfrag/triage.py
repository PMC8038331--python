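"""Docking-result triage: pose-RMSD exclusion, ranking, fragment frequency
and representative-lead selection.

Docking scores (higher = better) are ingested from an external engine,
never computed here.  Triage excludes candidates whose core pose deviates
from the referent ligand pose by more than a hard RMSD cut (strictly
greater than; boundary poses are retained), ranks the survivors by score,
bins them against a score cut and against the referent ligand's own
score, and summarises the fragment composition of the top N to pick a
representative lead.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import FragmentRegistry

__all__ = [
    "ScreeningRecord",
    "TriageReport",
    "TriageError",
    "compute_core_rmsd",
    "triage",
    "fragment_frequency",
    "select_representative",
    "load_score_table",
    "save_score_table",
    "parse_candidate_id",
    "provenance_from_ids",
]

#: Triage defaults: pose-RMSD exclusion cut (Å), score bin cut, the
#: referent ligand's docking score, and the size of the top list.
DEFAULT_RMSD_CUT = 1.5
DEFAULT_SCORE_CUT = 100.0
DEFAULT_REFERENT_SCORE = 77.73
DEFAULT_TOP_N = 10


class TriageError(ValueError):
    """Raised for malformed or inconsistent screening inputs."""


@dataclass
class ScreeningRecord:
    """Docking outcome for one candidate.

    ``core_rmsd`` is the RMSD (Å) between the candidate's docked core
    pose and the referent ligand pose, matched atom by atom.  ``excluded``
    and ``rank`` are populated by :func:`triage`; an excluded record never
    carries a rank.
    """

    candidate_id: str
    score: float
    core_rmsd: float
    excluded: bool = False
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.core_rmsd < 0:
            raise TriageError(
                f"{self.candidate_id}: core_rmsd must be >= 0, got {self.core_rmsd}"
            )


@dataclass
class TriageReport:
    """Summary of one triage run."""

    n_input: int
    n_excluded: int
    n_ranked: int
    score_max: float
    score_min: float
    referent_score: float
    n_above_cut: int
    n_below_cut: int
    n_below_referent: int
    top_n: list[str]
    ranked: list[ScreeningRecord] = field(default_factory=list)
    excluded: list[ScreeningRecord] = field(default_factory=list)

    def summary_text(self) -> str:
        pct_above = 100.0 * self.n_above_cut / self.n_ranked if self.n_ranked else 0.0
        pct_below = 100.0 * self.n_below_cut / self.n_ranked if self.n_ranked else 0.0
        lines = [
            f"input records:        {self.n_input}",
            f"excluded (pose RMSD): {self.n_excluded}",
            f"ranked:               {self.n_ranked}",
            f"score range:          {self.score_min:.2f} - {self.score_max:.2f}",
            f"above score cut:      {self.n_above_cut} ({pct_above:.0f}%)",
            f"below score cut:      {self.n_below_cut} ({pct_below:.0f}%)",
            f"below referent ({self.referent_score:.2f}): {self.n_below_referent}",
            "top ranked: " + ", ".join(self.top_n),
        ]
        return "\n".join(lines)


def compute_core_rmsd(coords_a, coords_b) -> float:
    """RMSD (Å) between two equally sized, pre-matched 3D point sets.

    No superposition is performed: the points are taken as matched pairs
    in a common frame, as when comparing a docked pose to a reference
    pose of the same rigid site.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 1:
        raise TriageError(
            f"coordinate sets must be matched Nx3 arrays, got {a.shape} vs {b.shape}"
        )
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def triage(
    records: Sequence[ScreeningRecord],
    rmsd_cut: float = DEFAULT_RMSD_CUT,
    score_cut: float = DEFAULT_SCORE_CUT,
    referent_score: float = DEFAULT_REFERENT_SCORE,
    top_n: int = DEFAULT_TOP_N,
) -> TriageReport:
    """Exclude bad poses, rank by score, and bin against the cuts.

    A record is excluded iff ``core_rmsd`` is strictly greater than
    ``rmsd_cut``.  Survivors are ranked by descending score, ties broken
    by candidate_id so ranking is deterministic.  ``n_above_cut`` counts
    survivors with score ≥ ``score_cut``; ``n_below_referent`` counts
    survivors scoring strictly below the referent ligand.
    """
    if not records:
        raise TriageError("empty screening input")
    if rmsd_cut <= 0:
        raise TriageError(f"rmsd_cut must be > 0, got {rmsd_cut}")
    if top_n < 1:
        raise TriageError(f"top_n must be >= 1, got {top_n}")
    ids = [r.candidate_id for r in records]
    dup = [cid for cid, n in Counter(ids).items() if n > 1]
    if dup:
        raise TriageError(f"duplicate candidate_id(s): {sorted(dup)}")

    excluded = []
    survivors = []
    for rec in records:
        if rec.core_rmsd > rmsd_cut:
            excluded.append(
                ScreeningRecord(rec.candidate_id, rec.score, rec.core_rmsd, excluded=True)
            )
        else:
            survivors.append(rec)
    survivors.sort(key=lambda r: (-r.score, r.candidate_id))
    ranked = [
        ScreeningRecord(r.candidate_id, r.score, r.core_rmsd, excluded=False, rank=i)
        for i, r in enumerate(survivors, start=1)
    ]
    if not ranked:
        raise TriageError("no records survive the pose-RMSD exclusion")
    scores = [r.score for r in ranked]
    n_above = sum(1 for s in scores if s >= score_cut)
    return TriageReport(
        n_input=len(records),
        n_excluded=len(excluded),
        n_ranked=len(ranked),
        score_max=max(scores),
        score_min=min(scores),
        referent_score=referent_score,
        n_above_cut=n_above,
        n_below_cut=len(ranked) - n_above,
        n_below_referent=sum(1 for s in scores if s < referent_score),
        top_n=[r.candidate_id for r in ranked[:top_n]],
        ranked=ranked,
        excluded=excluded,
    )


_CANDIDATE_ID_RE = re.compile(r"^GAL-(?P<linker>[^-]+)-(?P<aromatic>(?P<group>[A-Za-z]+\d*)(?P<variant>[a-z]*))$")


def parse_candidate_id(candidate_id: str) -> tuple[str, str, str]:
    """Split ``GAL-<linker_id>-<aromatic_id>`` into
    (linker_id, group_id, aromatic_id)."""
    m = _CANDIDATE_ID_RE.match(candidate_id)
    if not m:
        raise TriageError(f"candidate_id {candidate_id!r} is not of the form GAL-<L>-<Ar>")
    return m.group("linker"), m.group("group"), m.group("aromatic")


def provenance_from_ids(candidate_ids: Iterable[str]) -> dict[str, tuple[str, str, str]]:
    """Provenance mapping id → (linker_id, group_id, aromatic_id) parsed
    from systematic candidate ids."""
    return {cid: parse_candidate_id(cid) for cid in candidate_ids}


def fragment_frequency(
    top: Sequence[str],
    provenance: Mapping[str, tuple[str, str, str]],
) -> tuple[Counter, Counter]:
    """Aromatic-group and linker frequencies over a top-candidate list.

    Returns (group_id → count, linker_id → count); each counter sums to
    ``len(top)``.
    """
    missing = [cid for cid in top if cid not in provenance]
    if missing:
        raise TriageError(f"missing provenance for: {missing}")
    group_counts: Counter = Counter()
    linker_counts: Counter = Counter()
    for cid in top:
        linker_id, group_id, _ = provenance[cid]
        group_counts[group_id] += 1
        linker_counts[linker_id] += 1
    return group_counts, linker_counts


def _modal(counts: Counter) -> str:
    # deterministic mode: highest count, ties by lexicographic id
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def _variant_of(aromatic_id: str, group_id: str, registry: FragmentRegistry | None) -> str:
    if registry is not None and aromatic_id in registry:
        return registry.get(aromatic_id).variant
    return aromatic_id[len(group_id):]


def select_representative(
    top: Sequence[str],
    provenance: Mapping[str, tuple[str, str, str]],
    registry: FragmentRegistry | None = None,
) -> str:
    """Pick the representative lead from an ordered top list.

    The preferred candidate combines the modal aromatic group, the modal
    linker, and the unsubstituted ("a") variant of that group.  Fallback
    chain when no candidate satisfies all three: (1) modal group + "a"
    variant with any linker; (2) the highest-ranked member of the modal
    group; the list order is taken as rank order throughout.
    """
    if not top:
        raise TriageError("empty top list")
    group_counts, linker_counts = fragment_frequency(top, provenance)
    modal_group = _modal(group_counts)
    modal_linker = _modal(linker_counts)

    def variant(cid: str) -> str:
        linker_id, group_id, aromatic_id = provenance[cid]
        return _variant_of(aromatic_id, group_id, registry)

    # (1) modal group + modal linker + basic variant
    for cid in top:
        linker_id, group_id, _ = provenance[cid]
        if group_id == modal_group and linker_id == modal_linker and variant(cid) == "a":
            return cid
    # (2) modal group + basic variant
    for cid in top:
        _, group_id, _ = provenance[cid]
        if group_id == modal_group and variant(cid) == "a":
            return cid
    # (3) highest-ranked modal-group member
    for cid in top:
        _, group_id, _ = provenance[cid]
        if group_id == modal_group:
            return cid
    raise TriageError("modal group absent from top list")  # unreachable


def load_score_table(path: str | Path) -> list[ScreeningRecord]:
    """Read a score table CSV (candidate_id, score, core_rmsd)."""
    df = pd.read_csv(path)
    required = {"candidate_id", "score", "core_rmsd"}
    missing = required - set(df.columns)
    if missing:
        raise TriageError(f"{path}: missing columns {sorted(missing)}")
    return [
        ScreeningRecord(
            candidate_id=str(row.candidate_id),
            score=float(row.score),
            core_rmsd=float(row.core_rmsd),
        )
        for row in df.itertuples(index=False)
    ]


def save_score_table(records: Sequence[ScreeningRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"candidate_id": r.candidate_id, "score": r.score, "core_rmsd": r.core_rmsd}
            for r in records
        ]
    ).to_csv(path, index=False, float_format="%.6f")


def report_frame(report: TriageReport) -> pd.DataFrame:
    """Ranked records as a report table."""
    rows = [
        {
            "candidate_id": r.candidate_id,
            "score": r.score,
            "core_rmsd": r.core_rmsd,
            "excluded": False,
            "rank": r.rank,
        }
        for r in report.ranked
    ] + [
        {
            "candidate_id": r.candidate_id,
            "score": r.score,
            "core_rmsd": r.core_rmsd,
            "excluded": True,
            "rank": None,
        }
        for r in report.excluded
    ]
    return pd.DataFrame(rows)
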