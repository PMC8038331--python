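"""Synthetic fixtures: placeholder fragment registries and docking score
tables with exactly prescribed summary statistics.

The score-table generator reproduces the count structure a triage run is
expected to see — how many records fail the pose-RMSD cut, how many
survivors score above the score cut or below the referent ligand, the
attained score extrema, and the fragment composition of the top list —
while drawing everything else uniformly at random inside the implied
bands.  Counts are exact by construction; a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field

import numpy as np

from .registry import FragmentRecord, FragmentRegistry
from .triage import ScreeningRecord

__all__ = [
    "ScoreTableSpec",
    "SpecError",
    "make_placeholder_registry",
    "make_score_table",
    "study_score_spec",
    "STUDY_GROUP_SIZES",
]

#: Aromatic-variant counts of the packaged study library, by group.
STUDY_GROUP_SIZES = {
    "Ar1": 16, "Ar2": 22, "Ar3": 9, "Ar4": 15, "Ar5": 2, "Ar6": 2,
    "Ar7": 3, "Ar8": 14, "Ar9": 17, "Ar10": 13, "Ar11": 2, "Ar12": 1,
    "Ar13": 1, "Ar14": 1, "Ar15": 1, "Ar16": 1,
}

_LINKER_KEY = re.compile(r"^L\d+$")


class SpecError(ValueError):
    """Raised when a fixture specification is infeasible or malformed."""


def _variant_letters(n: int) -> list[str]:
    """a, b, ..., z, aa, ab, ... — enough letters for any variant count."""
    letters = []
    alphabet = string.ascii_lowercase
    i = 0
    while len(letters) < n:
        if i < 26:
            letters.append(alphabet[i])
        else:
            letters.append(alphabet[i // 26 - 1] + alphabet[i % 26])
        i += 1
    return letters


def make_placeholder_registry(
    group_sizes: dict[str, int],
    linker_ids: list[str] | None = None,
    seed: int = 0,
) -> FragmentRegistry:
    """Build a registry of syntactically valid, chemically trivial but
    mutually distinct placeholder fragments.

    ``group_sizes`` maps aromatic group id → number of variants; variants
    are lettered ``a``, ``b``, ...  The output is deterministic for a
    fixed seed.
    """
    for g, n in group_sizes.items():
        if n < 0:
            raise SpecError(f"group {g}: negative variant count {n}")
    records = [
        FragmentRecord("CORE", "core", "CORE", "", "[*:1]C", 1, placeholder=True)
    ]
    for i, lid in enumerate(linker_ids or []):
        chain = "C" * (2 + i)
        records.append(
            FragmentRecord(lid, "linker", "L", "", f"[*:1]{chain}[*:2]", 2, placeholder=True)
        )
    for gi, (group, size) in enumerate(group_sizes.items(), start=1):
        for vi, letter in enumerate(_variant_letters(size)):
            smi = "[*:1]" + "C" * gi + "O" + "C" * vi
            records.append(
                FragmentRecord(
                    f"{group}{letter}", "aromatic", group, letter, smi, 1,
                    placeholder=True,
                )
            )
    return FragmentRegistry(records=records)


@dataclass
class ScoreTableSpec:
    """Exact summary statistics a generated score table must satisfy.

    ``top_composition`` maps fragment identifiers to required counts
    within the top ``top_n`` ranked records; keys matching ``L<digits>``
    are linker ids, anything else is an aromatic group id.  Overlap
    between the leading group and leading linker is maximised so a joint
    representative (the modal group's unsubstituted variant on the modal
    linker) exists.
    """

    n_total: int
    n_excluded_rmsd: int
    rmsd_cut: float
    score_min: float
    score_max: float
    n_above_cut: int
    score_cut: float
    referent_score: float
    n_below_referent: int
    top_composition: dict[str, int] = field(default_factory=dict)
    top_n: int = 10
    seed: int = 0

    @property
    def n_ranked(self) -> int:
        return self.n_total - self.n_excluded_rmsd

    def validate(self) -> None:
        if self.n_total < 1:
            raise SpecError("n_total must be >= 1")
        if not 0 <= self.n_excluded_rmsd <= self.n_total:
            raise SpecError("n_excluded_rmsd must lie in [0, n_total]")
        if self.rmsd_cut <= 0:
            raise SpecError("rmsd_cut must be > 0")
        if self.score_min > self.score_max:
            raise SpecError("score_min > score_max")
        ranked = self.n_ranked
        if ranked < 1:
            raise SpecError("at least one record must survive the RMSD cut")
        if not 0 <= self.n_above_cut <= ranked:
            raise SpecError("n_above_cut must lie in [0, n_ranked]")
        if not 0 <= self.n_below_referent <= ranked:
            raise SpecError("n_below_referent must lie in [0, n_ranked]")
        if self.n_above_cut + self.n_below_referent > ranked:
            raise SpecError("band counts exceed n_ranked")
        if self.referent_score >= self.score_cut and (
            ranked - self.n_above_cut - self.n_below_referent
        ) > 0:
            raise SpecError(
                "middle band (referent <= score < cut) requested but "
                "referent_score >= score_cut"
            )
        if ranked == 1 and self.score_min != self.score_max:
            raise SpecError("a single ranked record cannot attain two distinct extrema")
        if ranked > 2 and self.score_min == self.score_max:
            raise SpecError(
                "a degenerate score range cannot hold more than two records "
                "(bands are half-open)"
            )
        # extrema must fall in bands consistent with the requested counts
        if self.n_above_cut > 0 and self.score_max < self.score_cut:
            raise SpecError("n_above_cut > 0 but score_max < score_cut")
        if self.n_above_cut == 0 and self.score_max >= self.score_cut:
            raise SpecError("score_max >= score_cut but n_above_cut == 0")
        if self.n_below_referent > 0 and self.score_min >= self.referent_score:
            raise SpecError("n_below_referent > 0 but score_min >= referent_score")
        if self.n_below_referent == 0 and self.score_min < self.referent_score:
            raise SpecError("score_min < referent_score but n_below_referent == 0")
        if self.n_below_referent == self.n_ranked and self.score_max >= self.referent_score:
            raise SpecError("all ranked below referent but score_max >= referent_score")
        if self.top_n < 1:
            raise SpecError("top_n must be >= 1")
        groups = {k: v for k, v in self.top_composition.items() if not _LINKER_KEY.match(k)}
        linkers = {k: v for k, v in self.top_composition.items() if _LINKER_KEY.match(k)}
        n_top = min(self.top_n, ranked)
        if sum(groups.values()) > n_top or sum(linkers.values()) > n_top:
            raise SpecError("top_composition counts exceed the top list size")
        if any(v < 0 for v in self.top_composition.values()):
            raise SpecError("top_composition counts must be >= 0")


def _band_of(value: float, spec: ScoreTableSpec) -> str:
    if value >= spec.score_cut:
        return "above"
    if value < spec.referent_score:
        return "below_ref"
    return "mid"


def _draw_band(rng, band: str, n: int, spec: ScoreTableSpec) -> list[float]:
    """Uniform draws from one half-open score band; errors if empty."""
    if n == 0:
        return []
    if band == "above":
        low, high = spec.score_cut, spec.score_max
    elif band == "mid":
        low = max(spec.referent_score, spec.score_min)
        high = min(spec.score_cut, spec.score_max)
    else:
        low, high = spec.score_min, min(spec.referent_score, spec.score_max)
    if low >= high:
        raise SpecError(
            f"score band {band!r} is empty ([{low}, {high})) but {n} draw(s) requested"
        )
    return list(rng.uniform(low, high, size=n))


def _top_ids(spec: ScoreTableSpec, n_top: int) -> list[str]:
    """Candidate ids for the top list honouring the composition counts."""
    groups = sorted(
        ((k, v) for k, v in spec.top_composition.items() if not _LINKER_KEY.match(k)),
        key=lambda kv: (-kv[1], kv[0]),
    )
    linkers = sorted(
        ((k, v) for k, v in spec.top_composition.items() if _LINKER_KEY.match(k)),
        key=lambda kv: (-kv[1], kv[0]),
    )
    group_slots: list[str] = []
    for g, n in groups:
        group_slots.extend([g] * n)
    filler = 0
    while len(group_slots) < n_top:
        filler += 1
        group_slots.append(f"Xg{filler}")
    linker_slots: list[str] = []
    for l, n in linkers:
        linker_slots.extend([l] * n)
    filler = 0
    while len(linker_slots) < n_top:
        filler += 1
        linker_slots.append(f"L9{filler:02d}")
    variant_counter: dict[str, int] = {}
    ids = []
    for g, l in zip(group_slots, linker_slots):
        vi = variant_counter.get(g, 0)
        variant_counter[g] = vi + 1
        letter = _variant_letters(vi + 1)[vi]
        ids.append(f"GAL-{l}-{g}{letter}")
    return ids


def make_score_table(spec: ScoreTableSpec) -> list[ScreeningRecord]:
    """Generate a score table satisfying *spec* exactly.

    The returned records reproduce exactly: the total count, the number
    failing the RMSD cut, the score extrema (attained), the number of
    survivors at or above the score cut, the number strictly below the
    referent score, and the top-list fragment composition.  Scores are
    otherwise uniform within their bands; pose RMSDs are uniform in
    [0, cut] for survivors and (cut, cut+1] for excluded records.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ranked_n = spec.n_ranked

    fixed: list[float] = [spec.score_max]
    if ranked_n >= 2:
        fixed.append(spec.score_min)
    remaining = {"above": spec.n_above_cut, "below_ref": spec.n_below_referent}
    remaining["mid"] = ranked_n - spec.n_above_cut - spec.n_below_referent
    for v in fixed:
        band = _band_of(v, spec)
        remaining[band] -= 1
        if remaining[band] < 0:
            raise SpecError(
                f"extremum {v} falls in band {band!r} whose requested count "
                "is too small"
            )
    scores = list(fixed)
    for band in ("above", "mid", "below_ref"):
        scores.extend(_draw_band(rng, band, remaining[band], spec))
    scores.sort(reverse=True)

    n_top = min(spec.top_n, ranked_n)
    ids = _top_ids(spec, n_top)
    for k in range(ranked_n - n_top):
        ids.append(f"GAL-L1-Xr{k + 1}")
    ranked_rmsd = rng.uniform(0.0, spec.rmsd_cut, size=ranked_n)
    records = [
        ScreeningRecord(cid, float(s), float(r))
        for cid, s, r in zip(ids, scores, ranked_rmsd)
    ]
    excl_scores = rng.uniform(spec.score_min, spec.score_max, size=spec.n_excluded_rmsd)
    excl_rmsd = rng.uniform(spec.rmsd_cut + 0.05, spec.rmsd_cut + 1.0, size=spec.n_excluded_rmsd)
    for k in range(spec.n_excluded_rmsd):
        records.append(
            ScreeningRecord(f"GAL-L1-Xx{k + 1}", float(excl_scores[k]), float(excl_rmsd[k]))
        )
    return records


def study_score_spec(seed: int = 0) -> ScoreTableSpec:
    """The study-condition score table: 199 docked candidates, 8 failing
    the 1.5 Å pose cut, survivor scores spanning 77.40–115.38 with 25 at
    or above 100 and a single score below the referent 77.73, and a top
    ten containing nine modal-group and seven modal-linker members."""
    return ScoreTableSpec(
        n_total=199,
        n_excluded_rmsd=8,
        rmsd_cut=1.5,
        score_min=77.40,
        score_max=115.38,
        n_above_cut=25,
        score_cut=100.0,
        referent_score=77.73,
        n_below_referent=1,
        top_composition={"Ar1": 9, "L10": 7},
        top_n=10,
        seed=seed,
    )
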