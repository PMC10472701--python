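import math

import numpy as np
import pytest
from hypothesis import settings

from classnet.records import ClassroomGraph, StudentRecord

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

# The worked-example classroom: 5 students, AP attached, 6 nominations.
FIXTURE_EDGES = [("A", "B"), ("A", "C"), ("B", "A"), ("C", "D"), ("D", "C"), ("E", "A")]
FIXTURE_AP = {"A": 7.0, "B": 7.5, "C": 6.0, "D": 8.0, "E": 7.0}


def make_student(student_id, classroom_id="c1", ap=7.0, sex="girl", **kw):
    defaults = dict(
        age=14, apgar=14.0, fas=2.0, family_structure="nuclear", location="urban"
    )
    defaults.update(kw)
    return StudentRecord(
        student_id=student_id, classroom_id=classroom_id, sex=sex, ap=ap, **defaults
    )


def make_graph(members, edges, ap=None, classroom_id="c1"):
    students = {
        m: make_student(m, classroom_id=classroom_id, ap=(ap or {}).get(m, 7.0))
        for m in members
    }
    return ClassroomGraph.from_members(classroom_id, members, edges, students)


def random_digraph(rng, n, p=0.4, classroom_id="c1"):
    members = [f"{classroom_id}s{i:02d}" for i in range(n)]
    adj = rng.random((n, n)) < p
    np.fill_diagonal(adj, False)
    edges = [(members[i], members[j]) for i, j in zip(*np.nonzero(adj))]
    ap = {m: float(np.round(rng.uniform(1, 10), 2)) for m in members}
    return make_graph(members, edges, ap, classroom_id=classroom_id)


@pytest.fixture
def fixture_graph():
    return make_graph(list("ABCDE"), FIXTURE_EDGES, FIXTURE_AP)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
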