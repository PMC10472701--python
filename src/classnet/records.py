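"""Core data containers: per-student records and per-classroom nomination graphs.

A classroom is the unit of network computation: students nominate best friends
only within their own roster, so the cohort decomposes into independent
directed graphs, one per classroom. Student identifiers are opaque strings
throughout; rosters are ordered lexicographically so that adjacency matrices
and derived metrics are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import IntegrityError

SEXES = ("girl", "boy")
FAMILY_STRUCTURES = ("nuclear", "single_parent", "other")
LOCATIONS = ("urban", "rural")

AP_RANGE = (1.0, 10.0)  # school grade scale
APGAR_RANGE = (0, 25)   # five items scored 0-5 each
FAS_RANGE = (0, 8)      # four items scored 0-2 each


def _is_missing(x) -> bool:
    try:
        return x is None or math.isnan(float(x))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class StudentRecord:
    """One participant's attributes.

    Numeric fields may be NaN on input (missing responses); range checks apply
    only to observed values. Missing values propagate untouched to the
    statistics stage, where each model applies listwise deletion.
    """

    student_id: str
    classroom_id: str
    sex: str
    age: float
    ap: float
    apgar: float
    fas: float
    family_structure: str
    location: str

    def __post_init__(self):
        if not self.student_id:
            raise IntegrityError("student_id must be a non-empty string")
        if not self.classroom_id:
            raise IntegrityError("classroom_id must be a non-empty string")
        if self.sex not in SEXES:
            raise IntegrityError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.family_structure not in FAMILY_STRUCTURES:
            raise IntegrityError(
                f"family_structure must be one of {FAMILY_STRUCTURES}, "
                f"got {self.family_structure!r}"
            )
        if self.location not in LOCATIONS:
            raise IntegrityError(f"location must be one of {LOCATIONS}, got {self.location!r}")
        if not _is_missing(self.ap) and not AP_RANGE[0] <= self.ap <= AP_RANGE[1]:
            raise IntegrityError(f"ap={self.ap} outside {AP_RANGE} for {self.student_id}")
        if not _is_missing(self.apgar) and not APGAR_RANGE[0] <= self.apgar <= APGAR_RANGE[1]:
            raise IntegrityError(f"apgar={self.apgar} outside {APGAR_RANGE} for {self.student_id}")
        if not _is_missing(self.fas) and not FAS_RANGE[0] <= self.fas <= FAS_RANGE[1]:
            raise IntegrityError(f"fas={self.fas} outside {FAS_RANGE} for {self.student_id}")


@dataclass
class ClassroomGraph:
    """Directed nomination graph on one classroom roster.

    ``graph`` holds every roster member as a node (isolates included) and one
    edge per directed nomination ego -> alter. ``students`` maps student_id to
    its :class:`StudentRecord`; it is ``None`` for graphs read from UCINET DL
    files, which carry no attributes.
    """

    classroom_id: str
    graph: nx.DiGraph
    students: Mapping[str, StudentRecord] | None = None

    @property
    def roster(self) -> tuple[str, ...]:
        """Roster in deterministic (lexicographic) order."""
        return tuple(sorted(self.graph.nodes))

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @classmethod
    def from_members(
        cls,
        classroom_id: str,
        members: Iterable[str],
        edges: Iterable[tuple[str, str]],
        students: Mapping[str, StudentRecord] | None = None,
    ) -> "ClassroomGraph":
        g = nx.DiGraph()
        g.add_nodes_from(sorted(members))
        g.add_edges_from(edges)
        out = cls(classroom_id=classroom_id, graph=g, students=students)
        out.validate()
        return out

    def validate(self) -> None:
        roster = set(self.graph.nodes)
        for u, v in self.graph.edges:
            if u == v:
                raise IntegrityError(f"self-nomination {u}->{v} in classroom {self.classroom_id}")
            if u not in roster or v not in roster:
                raise IntegrityError(
                    f"edge {u}->{v} has an endpoint off the roster of classroom "
                    f"{self.classroom_id}"
                )
        if self.students is not None:
            missing = roster - set(self.students)
            if missing:
                raise IntegrityError(
                    f"roster members without attributes in classroom "
                    f"{self.classroom_id}: {sorted(missing)}"
                )

    def ap(self, student_id: str) -> float:
        if self.students is None:
            raise IntegrityError(
                f"classroom {self.classroom_id} carries no attributes (DL import?)"
            )
        return self.students[student_id].ap
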