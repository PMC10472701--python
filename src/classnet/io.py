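"""Reading and writing cohort files and UCINET DL full-matrix graphs.

``students.csv`` columns: student_id, classroom_id, sex, age, ap, apgar, fas,
family_structure, location. ``nominations.csv`` columns: classroom_id,
ego_id, alter_id. Both are UTF-8 with a header row.

Cleaning rules on read: duplicate directed edges are dropped with a logged
warning, self-nominations are dropped with a logged warning, and nominations
referencing unknown students or crossing classrooms raise
:class:`~classnet.errors.IntegrityError`.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd

from .errors import IntegrityError, ParseError, SchemaError
from .records import ClassroomGraph, StudentRecord

logger = logging.getLogger(__name__)

STUDENT_COLUMNS = [
    "student_id",
    "classroom_id",
    "sex",
    "age",
    "ap",
    "apgar",
    "fas",
    "family_structure",
    "location",
]
NOMINATION_COLUMNS = ["classroom_id", "ego_id", "alter_id"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_students(path: str | Path) -> list[StudentRecord]:
    df = pd.read_csv(
        path,
        dtype={"student_id": str, "classroom_id": str},
        float_precision="round_trip",
    )
    _require_columns(df, STUDENT_COLUMNS, path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            StudentRecord(
                student_id=row.student_id,
                classroom_id=row.classroom_id,
                sex=row.sex,
                age=float(row.age) if not _isna(row.age) else math.nan,
                ap=float(row.ap) if not _isna(row.ap) else math.nan,
                apgar=float(row.apgar) if not _isna(row.apgar) else math.nan,
                fas=float(row.fas) if not _isna(row.fas) else math.nan,
                family_structure=row.family_structure,
                location=row.location,
            )
        )
    ids = [r.student_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IntegrityError(f"{path}: duplicate student_id(s) {dupes}")
    return records


def _isna(x) -> bool:
    return pd.isna(x)


def read_cohort(
    students_path: str | Path, nominations_path: str | Path
) -> list[ClassroomGraph]:
    """Build one validated :class:`ClassroomGraph` per classroom."""
    students = read_students(students_path)
    noms = pd.read_csv(
        nominations_path, dtype={"classroom_id": str, "ego_id": str, "alter_id": str}
    )
    _require_columns(noms, NOMINATION_COLUMNS, nominations_path)

    classroom_of = {s.student_id: s.classroom_id for s in students}
    by_class: dict[str, dict[str, StudentRecord]] = {}
    for s in students:
        by_class.setdefault(s.classroom_id, {})[s.student_id] = s

    edges: dict[str, set[tuple[str, str]]] = {cid: set() for cid in by_class}
    n_self = n_dup = 0
    for i, row in enumerate(noms.itertuples(index=False)):
        cid, ego, alter = row.classroom_id, row.ego_id, row.alter_id
        for sid in (ego, alter):
            if sid not in classroom_of:
                raise IntegrityError(
                    f"{nominations_path} row {i}: unknown student {sid!r}"
                )
        if classroom_of[ego] != cid or classroom_of[alter] != cid:
            raise IntegrityError(
                f"{nominations_path} row {i}: nomination {ego}->{alter} does not "
                f"match classroom {cid} (ego in {classroom_of[ego]}, "
                f"alter in {classroom_of[alter]})"
            )
        if ego == alter:
            n_self += 1
            continue
        if (ego, alter) in edges[cid]:
            n_dup += 1
            continue
        edges[cid].add((ego, alter))
    if n_self:
        logger.warning("dropped %d self-nomination(s)", n_self)
    if n_dup:
        logger.warning("dropped %d duplicate nomination(s)", n_dup)

    return [
        ClassroomGraph.from_members(cid, by_class[cid].keys(), edges[cid], by_class[cid])
        for cid in sorted(by_class)
    ]


def graphs_from_cohort(cohort) -> list[ClassroomGraph]:
    """Build validated per-classroom graphs directly from an in-memory cohort."""
    by_class: dict[str, dict[str, StudentRecord]] = {}
    for s in cohort.students:
        by_class.setdefault(s.classroom_id, {})[s.student_id] = s
    edges: dict[str, list[tuple[str, str]]] = {cid: [] for cid in by_class}
    for cid, ego, alter in cohort.nominations:
        edges[cid].append((ego, alter))
    return [
        ClassroomGraph.from_members(cid, by_class[cid].keys(), edges[cid], by_class[cid])
        for cid in sorted(by_class)
    ]


def write_cohort_csv(
    students: list[StudentRecord],
    nominations: list[tuple[str, str, str]],
    students_path: str | Path,
    nominations_path: str | Path,
) -> None:
    sdf = pd.DataFrame(
        [
            {
                "student_id": s.student_id,
                "classroom_id": s.classroom_id,
                "sex": s.sex,
                "age": s.age,
                "ap": s.ap,
                "apgar": s.apgar,
                "fas": s.fas,
                "family_structure": s.family_structure,
                "location": s.location,
            }
            for s in students
        ],
        columns=STUDENT_COLUMNS,
    ).sort_values("student_id")
    ndf = pd.DataFrame(sorted(nominations), columns=NOMINATION_COLUMNS)
    # %.17g keeps write->read the identity on float attributes
    sdf.to_csv(students_path, index=False, float_format="%.17g")
    ndf.to_csv(nominations_path, index=False)


def write_graphs_csv(
    graphs: list[ClassroomGraph], students_path: str | Path, nominations_path: str | Path
) -> None:
    students = [s for g in graphs for s in (g.students or {}).values()]
    noms = [(g.classroom_id, u, v) for g in graphs for u, v in g.graph.edges]
    write_cohort_csv(students, noms, students_path, nominations_path)


# ---------------------------------------------------------------------------
# UCINET DL full-matrix dialect
# ---------------------------------------------------------------------------

def write_dl_matrix(graph: ClassroomGraph, path: str | Path) -> None:
    """Write the adjacency as a UCINET DL full-matrix file (roster order)."""
    graph.validate()
    roster = graph.roster
    lines = [f"dl n={len(roster)} format=fullmatrix", "labels:", ",".join(roster), "data:"]
    for u in roster:
        row = ["1" if graph.graph.has_edge(u, v) else "0" for v in roster]
        lines.append(" ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_dl_matrix(path: str | Path) -> ClassroomGraph:
    """Read a DL full-matrix file; the result carries no student attributes.

    The classroom id is taken from the file stem.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("empty DL file", line=1)
    header = lines[0].strip().lower().split()
    if not header or header[0] != "dl":
        raise ParseError(f"expected 'dl' header, got {lines[0]!r}", line=1)
    n = None
    fmt = None
    for tok in header[1:]:
        if tok.startswith("n="):
            try:
                n = int(tok[2:])
            except ValueError:
                raise ParseError(f"bad node count {tok!r}", line=1) from None
        elif tok.startswith("format="):
            fmt = tok.split("=", 1)[1]
    if n is None:
        raise ParseError("header missing n=<count>", line=1)
    if fmt != "fullmatrix":
        raise ParseError(f"unsupported format {fmt!r} (only fullmatrix)", line=1)

    labels: list[str] | None = None
    data_rows: list[list[str]] = []
    mode = None
    for lineno, raw in enumerate(lines[1:], start=2):
        stripped = raw.strip()
        if not stripped:
            continue
        low = stripped.lower()
        if low == "labels:":
            mode = "labels"
            labels = []
            continue
        if low == "data:":
            mode = "data"
            continue
        if mode == "labels":
            labels.extend(t.strip() for t in stripped.replace(",", " ").split())
        elif mode == "data":
            data_rows.append((stripped, lineno))
        else:
            raise ParseError(f"unexpected content {stripped!r}", line=lineno)

    if labels is None:
        labels = [f"n{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise ParseError(f"expected {n} labels, found {len(labels)}")
    if len(data_rows) != n:
        raise ParseError(f"expected {n} data rows, found {len(data_rows)}")

    edges = []
    for i, (row, lineno) in enumerate(data_rows):
        values = row.split()
        if len(values) != n:
            raise ParseError(f"expected {n} entries, found {len(values)}", line=lineno)
        for j, v in enumerate(values):
            if v not in ("0", "1"):
                raise ParseError(f"non-binary entry {v!r}", line=lineno)
            if v == "1":
                if i == j:
                    raise ParseError("self-tie on matrix diagonal", line=lineno)
                edges.append((labels[i], labels[j]))

    return ClassroomGraph.from_members(path.stem, labels, edges, students=None)
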