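"""Roster, nomination and cohesion-scale survey I/O.

Sociometric data for a small intervention group arrive as three flat files:

* a **roster** listing every enrolled member (the roster method: respondents
  nominate from a fixed, named list, so the node set of every network is the
  full roster regardless of who answered the survey);
* **nominations** — one row per directed tie reported by a respondent (ego)
  toward another member (alter), tagged with a wave label and a relation
  (``advice`` or ``discussion`` name generators);
* **Perceived Cohesion Scale (PCS)** responses — six Likert items (1–7),
  items 1–3 tapping sense of belonging and items 4–6 feelings of morale.

Members who skipped a survey wave are *non-respondents*: they contribute no
outgoing arcs but remain in the node set and may be nominated by others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "RELATIONS",
    "Roster",
    "NominationRecord",
    "SociometricNetwork",
    "PCSResponseSet",
    "SurveyValidationError",
    "parse_roster",
    "parse_nominations",
    "build_network",
    "parse_pcs",
    "write_roster",
    "write_nominations",
    "write_pcs",
    "write_edgelist",
    "read_edgelist",
]

logger = logging.getLogger(__name__)

#: Recognised name-generator relations.
RELATIONS = ("advice", "discussion")

PCS_ITEMS = [f"item{i}" for i in range(1, 7)]


class SurveyValidationError(ValueError):
    """Raised when a survey file violates a roster/nomination invariant."""


def _norm(label: str) -> str:
    """Wave/relation labels are free text, matched case-insensitively."""
    return str(label).strip().lower()


@dataclass(frozen=True)
class Roster:
    """An ordered, fixed list of group members.

    Member order is significant: it defines node indexing everywhere
    downstream (adjacency matrices, report ordering, tie-breaks).
    """

    group_id: str
    members: tuple[tuple[str, str], ...]  # (member_id, display_name)

    def __post_init__(self) -> None:
        ids = [m for m, _ in self.members]
        if len(ids) < 2:
            raise SurveyValidationError(
                f"roster must contain at least 2 members, got {len(ids)}"
            )
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise SurveyValidationError(f"duplicate member ids in roster: {dupes}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.members)

    @property
    def size(self) -> int:
        return len(self.members)

    def display_name(self, member_id: str) -> str:
        for mid, name in self.members:
            if mid == member_id:
                return name
        raise KeyError(member_id)

    def index(self, member_id: str) -> int:
        return self.ids.index(member_id)

    def __contains__(self, member_id: object) -> bool:
        return member_id in self.ids


@dataclass(frozen=True)
class NominationRecord:
    """One validated directed nomination ego→alter at a given wave/relation."""

    wave: str
    relation: str
    ego_id: str
    alter_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "wave", _norm(self.wave))
        object.__setattr__(self, "relation", _norm(self.relation))
        if self.relation not in RELATIONS:
            raise SurveyValidationError(
                f"unknown relation {self.relation!r}; expected one of {RELATIONS}"
            )
        if self.ego_id == self.alter_id:
            raise SurveyValidationError(
                f"self-nomination by {self.ego_id!r} is not permitted"
            )


@dataclass(frozen=True)
class SociometricNetwork:
    """A directed graph over the full roster for one (wave, relation).

    ``arcs`` is the set of ordered (ego_id, alter_id) pairs; ``respondents``
    the members who actually answered the survey at this wave. Invariants:
    no self-loops, every arc's ego is a respondent, and the node set is the
    complete roster irrespective of response (non-respondents may appear
    only as alters).
    """

    roster: Roster
    wave: str
    relation: str
    arcs: frozenset[tuple[str, str]]
    respondents: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "wave", _norm(self.wave))
        object.__setattr__(self, "relation", _norm(self.relation))
        object.__setattr__(self, "arcs", frozenset(self.arcs))
        object.__setattr__(self, "respondents", frozenset(self.respondents))
        unknown = self.respondents - set(self.roster.ids)
        if unknown:
            raise SurveyValidationError(
                f"respondents not on roster: {sorted(unknown)}"
            )
        for ego, alter in self.arcs:
            if ego == alter:
                raise SurveyValidationError(f"self-loop on {ego!r}")
            if ego not in self.roster or alter not in self.roster:
                raise SurveyValidationError(
                    f"arc ({ego!r}, {alter!r}) references a non-roster member"
                )
            if ego not in self.respondents:
                raise SurveyValidationError(
                    f"arc from non-respondent ego {ego!r}"
                )

    @property
    def n(self) -> int:
        return self.roster.size

    @property
    def arc_count(self) -> int:
        return len(self.arcs)

    def has_arc(self, ego: str, alter: str) -> bool:
        return (ego, alter) in self.arcs

    def graph(self):
        """The network as a :class:`networkx.DiGraph` (full roster as nodes,
        ``display_name`` and ``respondent`` node attributes)."""
        import networkx as nx

        g = nx.DiGraph()
        for mid, name in self.roster.members:
            g.add_node(mid, display_name=name, respondent=mid in self.respondents)
        g.add_edges_from(self.arcs)
        return g

    def adjacency(self):
        """Dense 0/1 adjacency matrix in roster order (numpy int array)."""
        import numpy as np

        idx = {m: i for i, m in enumerate(self.roster.ids)}
        a = np.zeros((self.n, self.n), dtype=int)
        for ego, alter in self.arcs:
            a[idx[ego], idx[alter]] = 1
        return a


@dataclass(frozen=True)
class PCSResponseSet:
    """Perceived Cohesion Scale responses for one wave.

    ``rows`` maps member_id -> six item values (int 1–7 or None for missing).
    Items 1–3 form the belonging subscale, items 4–6 the morale subscale.
    """

    wave: str
    rows: tuple[tuple[str, tuple[int | None, ...]], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "wave", _norm(self.wave))
        for mid, items in self.rows:
            if len(items) != 6:
                raise SurveyValidationError(
                    f"PCS row for {mid!r} has {len(items)} items, expected 6"
                )
            for v in items:
                if v is not None and not (1 <= v <= 7):
                    raise SurveyValidationError(
                        f"PCS item value {v} for {mid!r} outside 1–7"
                    )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def complete_rows(self) -> list[tuple[str, tuple[int, ...]]]:
        return [
            (mid, tuple(int(v) for v in items))
            for mid, items in self.rows
            if all(v is not None for v in items)
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [dict(zip(PCS_ITEMS, items), member_id=mid) for mid, items in self.rows]
        )
        return df.set_index("member_id")[PCS_ITEMS].astype("float64")


# ---------------------------------------------------------------------------
# parsing


def _read_csv(source, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(source, sep=delimiter, dtype=str, skipinitialspace=True)
    if df.empty and df.columns.size == 0:
        raise SurveyValidationError("empty file")
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def parse_roster(source, *, group_id: str = "group", delimiter: str = ",") -> Roster:
    """Read a roster CSV (``member_id,display_name``) preserving file order.

    Raises :class:`SurveyValidationError` on duplicate ids or an empty file.
    """
    df = _read_csv(source, delimiter)
    for col in ("member_id", "display_name"):
        if col not in df.columns:
            raise SurveyValidationError(f"roster file missing column {col!r}")
    if len(df) == 0:
        raise SurveyValidationError("roster file contains no members")
    members = tuple(
        (str(r.member_id).strip(), str(r.display_name).strip())
        for r in df.itertuples()
    )
    return Roster(group_id=group_id, members=members)


def parse_nominations(
    source, roster: Roster, *, delimiter: str = ","
) -> list[NominationRecord]:
    """Read a nominations CSV (``wave,relation,ego,alter``) and validate it.

    Exact duplicate rows collapse to one record with a logged warning;
    unknown member ids and self-nominations are errors.
    """
    df = _read_csv(source, delimiter)
    for col in ("wave", "relation", "ego", "alter"):
        if col not in df.columns:
            raise SurveyValidationError(f"nominations file missing column {col!r}")
    records: list[NominationRecord] = []
    seen: set[NominationRecord] = set()
    n_dupes = 0
    for i, row in enumerate(df.itertuples()):
        ego, alter = str(row.ego).strip(), str(row.alter).strip()
        for mid in (ego, alter):
            if mid not in roster:
                raise SurveyValidationError(
                    f"row {i}: member id {mid!r} is not on the roster"
                )
        rec = NominationRecord(
            wave=str(row.wave), relation=str(row.relation), ego_id=ego, alter_id=alter
        )
        if rec in seen:
            n_dupes += 1
            continue
        seen.add(rec)
        records.append(rec)
    if n_dupes:
        logger.warning("dropped %d duplicate nomination row(s)", n_dupes)
    return records


def build_network(
    records: Iterable[NominationRecord],
    roster: Roster,
    wave: str,
    relation: str,
    respondents: Iterable[str],
) -> SociometricNetwork:
    """Assemble the directed network for one (wave, relation).

    Only records matching the requested wave and relation (case-insensitive)
    are used. A record whose ego is not in ``respondents`` signals a
    data-entry inconsistency and raises.
    """
    wave, relation = _norm(wave), _norm(relation)
    respondents = frozenset(respondents)
    arcs = set()
    for rec in records:
        if rec.wave != wave or rec.relation != relation:
            continue
        if rec.ego_id not in respondents:
            raise SurveyValidationError(
                f"nomination by {rec.ego_id!r} who is not marked as a respondent "
                f"at wave {wave!r}"
            )
        arcs.add((rec.ego_id, rec.alter_id))
    return SociometricNetwork(
        roster=roster, wave=wave, relation=relation,
        arcs=frozenset(arcs), respondents=respondents,
    )


def parse_pcs(source, roster: Roster, *, wave: str | None = None,
              delimiter: str = ",") -> PCSResponseSet:
    """Read a PCS CSV (``wave,member_id,item1..item6``).

    Missing items are allowed (empty cells); out-of-range values raise with
    the offending row index. When ``wave`` is given only that wave's rows are
    kept; otherwise the file must contain a single wave.
    """
    df = _read_csv(source, delimiter)
    required = ["wave", "member_id", *PCS_ITEMS]
    for col in required:
        if col not in df.columns:
            raise SurveyValidationError(f"PCS file missing column {col!r}")
    if wave is not None:
        df = df[df["wave"].map(_norm) == _norm(wave)]
        wave_label = _norm(wave)
    else:
        waves = sorted(set(df["wave"].map(_norm)))
        if len(waves) != 1:
            raise SurveyValidationError(
                f"PCS file contains waves {waves}; specify which to load"
            )
        wave_label = waves[0]
    rows = []
    for i, row in enumerate(df.itertuples()):
        mid = str(row.member_id).strip()
        if mid not in roster:
            raise SurveyValidationError(f"row {i}: member id {mid!r} not on roster")
        items: list[int | None] = []
        for item in PCS_ITEMS:
            raw = getattr(row, item)
            if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
                items.append(None)
                continue
            try:
                v = int(str(raw).strip())
            except ValueError as exc:
                raise SurveyValidationError(
                    f"row {i}: non-integer PCS value {raw!r} in {item}"
                ) from exc
            if not 1 <= v <= 7:
                raise SurveyValidationError(
                    f"row {i}: PCS value {v} in {item} outside the 1–7 scale"
                )
            items.append(v)
        rows.append((mid, tuple(items)))
    return PCSResponseSet(wave=wave_label, rows=tuple(rows))


# ---------------------------------------------------------------------------
# writing


def write_roster(roster: Roster, path: str | Path, *, delimiter: str = ",") -> None:
    pd.DataFrame(roster.members, columns=["member_id", "display_name"]).to_csv(
        path, sep=delimiter, index=False
    )


def write_nominations(
    records: Sequence[NominationRecord], path: str | Path, *, delimiter: str = ","
) -> None:
    pd.DataFrame(
        [(r.wave, r.relation, r.ego_id, r.alter_id) for r in records],
        columns=["wave", "relation", "ego", "alter"],
    ).to_csv(path, sep=delimiter, index=False)


def write_pcs(
    responses: Sequence[PCSResponseSet], path: str | Path, *, delimiter: str = ","
) -> None:
    rows = []
    for rs in responses:
        for mid, items in rs.rows:
            rows.append(
                {
                    "wave": rs.wave,
                    "member_id": mid,
                    **{it: ("" if v is None else v) for it, v in zip(PCS_ITEMS, items)},
                }
            )
    pd.DataFrame(rows, columns=["wave", "member_id", *PCS_ITEMS]).to_csv(
        path, sep=delimiter, index=False
    )


def write_edgelist(net: SociometricNetwork, path: str | Path) -> None:
    """Canonical ``ego<TAB>alter`` export, arcs sorted in roster order."""
    order = {m: i for i, m in enumerate(net.roster.ids)}
    lines = [
        f"{e}\t{a}"
        for e, a in sorted(net.arcs, key=lambda p: (order[p[0]], order[p[1]]))
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_edgelist(path: str | Path) -> set[tuple[str, str]]:
    arcs = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        ego, alter = line.split("\t")
        arcs.add((ego, alter))
    return arcs
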