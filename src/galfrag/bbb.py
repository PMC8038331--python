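"""Rule-based blood–brain-barrier permeability triage.

Passive BBB penetration of small molecules is well approximated by their
lipophilicity and polarity: permeant drugs cluster inside an elliptical
region of the (logP, TPSA) plane, and simple descriptor range rules
(molecular weight, H-bond counts) capture most of the remaining signal.
This module implements that idea as a configurable cascade of filters
combined with strict AND semantics — a candidate survives only if it
passes every stage — mirroring consensus screening with several
predictors.

Two filter kinds are supported:

``ellipse``
    Pass iff the candidate's (logp, tpsa) point lies inside or on a
    rotated ellipse given by center, semi-axes and rotation angle.
``range_rule``
    Pass iff a named descriptor lies within [min, max].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "FilterSpec",
    "FilterVerdict",
    "FilterError",
    "ellipse_classify",
    "range_rule_classify",
    "run_cascade",
    "load_cascade",
    "packaged_cascade",
]

_BOUNDARY_TOL = 1e-9


class FilterError(ValueError):
    """Raised for malformed filter specs or missing descriptors."""


@dataclass(frozen=True)
class FilterSpec:
    """One stage of the BBB cascade.

    For ``kind='ellipse'`` the parameters are ``center_logp``,
    ``center_tpsa``, ``axis_logp``, ``axis_tpsa`` (semi-axes, > 0) and
    optional ``rotation_deg`` (counter-clockwise, logP axis toward TPSA
    axis).  For ``kind='range_rule'`` they are ``descriptor`` (column
    name), ``min`` and ``max``.
    """

    filter_id: str
    kind: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "ellipse":
            for key in ("center_logp", "center_tpsa", "axis_logp", "axis_tpsa"):
                if key not in self.parameters:
                    raise FilterError(f"{self.filter_id}: missing parameter {key!r}")
            if self.parameters["axis_logp"] <= 0 or self.parameters["axis_tpsa"] <= 0:
                raise FilterError(f"{self.filter_id}: ellipse axes must be > 0")
        elif self.kind == "range_rule":
            for key in ("descriptor", "min", "max"):
                if key not in self.parameters:
                    raise FilterError(f"{self.filter_id}: missing parameter {key!r}")
            if self.parameters["min"] > self.parameters["max"]:
                raise FilterError(f"{self.filter_id}: range min > max")
        else:
            raise FilterError(f"{self.filter_id}: unknown filter kind {self.kind!r}")


@dataclass
class FilterVerdict:
    """Per-filter pass flags and their conjunction for one candidate."""

    candidate_id: str
    per_filter: dict[str, bool]
    overall: bool

    def __post_init__(self) -> None:
        assert self.overall == all(self.per_filter.values()) or not self.per_filter


def ellipse_classify(logp: float, tpsa: float, spec: FilterSpec) -> bool:
    """True iff (logp, tpsa) lies inside or on the configured ellipse.

    The point is translated to the ellipse center, rotated by the negative
    of the configured angle, and tested against
    (x/a)² + (y/b)² ≤ 1 (with a hair of tolerance so parametric boundary
    points classify as passes).
    """
    if spec.kind != "ellipse":
        raise FilterError(f"{spec.filter_id}: ellipse_classify needs an ellipse spec")
    p = spec.parameters
    theta = math.radians(p.get("rotation_deg", 0.0))
    dx = logp - p["center_logp"]
    dy = tpsa - p["center_tpsa"]
    x = math.cos(theta) * dx + math.sin(theta) * dy
    y = -math.sin(theta) * dx + math.cos(theta) * dy
    value = (x / p["axis_logp"]) ** 2 + (y / p["axis_tpsa"]) ** 2
    return value <= 1.0 + _BOUNDARY_TOL


def range_rule_classify(value: float, spec: FilterSpec) -> bool:
    """True iff value lies within the configured closed interval."""
    if spec.kind != "range_rule":
        raise FilterError(f"{spec.filter_id}: range_rule_classify needs a range_rule spec")
    return spec.parameters["min"] <= value <= spec.parameters["max"]


def _apply_filter(row: pd.Series, spec: FilterSpec, candidate_id: str) -> bool:
    if spec.kind == "ellipse":
        for col in ("logp", "tpsa"):
            if col not in row or pd.isna(row[col]):
                raise FilterError(
                    f"candidate {candidate_id}: missing descriptor {col!r} "
                    f"required by filter {spec.filter_id}"
                )
        return ellipse_classify(float(row["logp"]), float(row["tpsa"]), spec)
    col = spec.parameters["descriptor"]
    if col not in row or pd.isna(row[col]):
        raise FilterError(
            f"candidate {candidate_id}: missing descriptor {col!r} "
            f"required by filter {spec.filter_id}"
        )
    return range_rule_classify(float(row[col]), spec)


def run_cascade(
    candidates: pd.DataFrame,
    cascade: Sequence[FilterSpec],
) -> tuple[list[FilterVerdict], pd.DataFrame]:
    """Evaluate an ordered filter cascade over a descriptor table.

    ``candidates`` must carry a ``candidate_id`` column plus every
    descriptor any filter references.  Returns per-candidate verdicts
    (every filter evaluated, overall = AND of all) and a stage-tally table
    with the number of survivors after each stage; survivors of stage k
    are by construction the only candidates counted at stage k+1, so the
    tallies are non-increasing.
    """
    if "candidate_id" not in candidates.columns:
        raise FilterError("candidate table must have a candidate_id column")
    verdicts: list[FilterVerdict] = []
    flags: dict[str, list[bool]] = {spec.filter_id: [] for spec in cascade}
    for _, row in candidates.iterrows():
        cid = str(row["candidate_id"])
        per = {}
        for spec in cascade:
            ok = _apply_filter(row, spec, cid)
            per[spec.filter_id] = ok
            flags[spec.filter_id].append(ok)
        verdicts.append(
            FilterVerdict(candidate_id=cid, per_filter=per, overall=all(per.values()))
        )
    tally_rows = []
    alive = [True] * len(verdicts)
    for spec in cascade:
        alive = [a and f for a, f in zip(alive, flags[spec.filter_id])]
        tally_rows.append({"filter_id": spec.filter_id, "n_survivors": sum(alive)})
    tallies = pd.DataFrame(tally_rows, columns=["filter_id", "n_survivors"])
    return verdicts, tallies


def verdicts_frame(verdicts: Iterable[FilterVerdict]) -> pd.DataFrame:
    """Verdicts as a report table: candidate_id, one column per filter,
    overall."""
    rows = []
    for v in verdicts:
        row = {"candidate_id": v.candidate_id}
        row.update(v.per_filter)
        row["overall"] = v.overall
        rows.append(row)
    return pd.DataFrame(rows)


def load_cascade(path: str | Path) -> list[FilterSpec]:
    """Read a cascade config: a YAML list of {filter_id, kind, parameters}."""
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or []
    if not isinstance(data, list):
        raise FilterError(f"{path}: cascade config must be a YAML list")
    return [
        FilterSpec(
            filter_id=str(item["filter_id"]),
            kind=str(item["kind"]),
            parameters=dict(item.get("parameters") or {}),
        )
        for item in data
    ]


def packaged_cascade() -> list[FilterSpec]:
    """The default cascade shipped with the package (a synthetic
    lipophilicity/polarity ellipse plus CNS-typical range rules)."""
    from importlib import resources

    path = Path(resources.files("galfrag").joinpath("data", "bbb_cascade_synthetic.yaml"))  # type: ignore[arg-type]
    return load_cascade(path)
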