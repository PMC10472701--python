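"""Tests for the synthetic cohort generator."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import truncnorm

from classnet.errors import ConfigError
from classnet.generate import (
    GeneratorConfig,
    apply_peer_influence,
    generate_attributes,
    generate_cohort,
    generate_nominations,
)


def small_config(**kw):
    defaults = dict(n_classrooms=4, class_size_range=(10, 14), seed=0)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.mark.parametrize(
    "field,value",
    [
        ("prop_girls", 1.2),
        ("prop_urban", -0.1),
        ("family_structure_probs", (0.5, 0.5, 0.5)),
        ("class_size_range", (2, 10)),
        ("ap_sd", 0.0),
        ("noise_sd", -1.0),
        ("age_range", (10, 17)),
        ("influence_mode", "telepathy"),
    ],
)
def test_invalid_config_names_field(field, value):
    cfg = dataclasses.replace(GeneratorConfig(), **{field: value})
    with pytest.raises(ConfigError):
        cfg.validate()


def test_degenerate_proportions(rng):
    cfg = small_config(prop_girls=1.0)
    assert all(s.sex == "girl" for s in generate_attributes(cfg, rng))
    cfg = small_config(prop_girls=0.0)
    assert all(s.sex == "boy" for s in generate_attributes(cfg, rng))


def test_zero_variance_ap_limit(rng):
    cfg = small_config(ap_mean=7.3, ap_sd=1e-12)
    aps = [s.ap for s in generate_attributes(cfg, rng)]
    assert np.allclose(aps, 7.3)


def test_attribute_ranges(rng):
    students = generate_attributes(small_config(), rng)
    for s in students:
        assert 1.0 <= s.ap <= 10.0
        assert 0 <= s.apgar <= 25 and float(s.apgar).is_integer()
        assert 0 <= s.fas <= 8 and float(s.fas).is_integer()
        assert 12 <= s.age <= 17


def test_ap_mean_matches_truncated_normal(rng):
    """Sample mean within 3 SE of the truncated-normal mean (numeric oracle)."""
    cfg = GeneratorConfig(n_classrooms=32, class_size_range=(24, 27), ap_mean=7.3, ap_sd=0.7, seed=5)
    students = generate_attributes(cfg, np.random.default_rng(5))
    a, b = (1 - 7.3) / 0.7, (10 - 7.3) / 0.7
    mu, var = truncnorm.stats(a, b, loc=7.3, scale=0.7, moments="mv")
    aps = np.array([s.ap for s in students])
    assert abs(aps.mean() - mu) < 3 * np.sqrt(var / len(aps))


def test_tie_probability_limits(rng):
    students = generate_attributes(small_config(n_classrooms=1), rng)
    none = generate_nominations(students, small_config(tie_intercept=-50.0), rng)
    assert none == []
    full = generate_nominations(
        students, small_config(tie_intercept=50.0, homophily_coef=0.0), rng
    )
    k = len(students)
    assert len(full) == k * (k - 1)


def test_classroom_too_small(rng):
    students = generate_attributes(small_config(), rng)[:2]
    with pytest.raises(ConfigError):
        generate_nominations(students, small_config(), rng)


def test_homophily_coefficient_shrinks_ap_distance():
    """Realized ties join more AP-similar dyads than the dyad pool (Monte-Carlo)."""
    rng = np.random.default_rng(7)
    cfg = small_config(homophily_coef=-2.0, samesex_coef=0.0, reciprocity_coef=0.0)
    tie_d, all_d = [], []
    for _ in range(200):
        students = generate_attributes(small_config(n_classrooms=1), rng)
        ap = {s.student_id: s.ap for s in students}
        edges = generate_nominations(students, cfg, rng)
        tie_d += [abs(ap[u] - ap[v]) for u, v in edges]
        ids = list(ap)
        all_d += [abs(ap[u] - ap[v]) for u in ids for v in ids if u != v]
    assert np.mean(tie_d) < np.mean(all_d)


def test_reciprocity_coefficient_raises_reciprocation():
    def mutual_rate(coef, seed):
        rng = np.random.default_rng(seed)
        total_mutual = total_edges = 0
        for _ in range(100):
            students = generate_attributes(small_config(n_classrooms=1), rng)
            edges = set(generate_nominations(students, small_config(reciprocity_coef=coef), rng))
            total_mutual += sum(1 for u, v in edges if (v, u) in edges)
            total_edges += len(edges)
        return total_mutual / total_edges

    assert mutual_rate(2.0, 11) > mutual_rate(0.0, 11)


def test_cohort_invariants_and_reproducibility():
    cfg = small_config(seed=42)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    a.validate()
    assert [s.ap for s in a.students] == [s.ap for s in b.students]
    assert a.nominations == b.nominations
    classroom_of = {s.student_id: s.classroom_id for s in a.students}
    for cid, ego, alter in a.nominations:
        assert ego != alter
        assert classroom_of[ego] == cid == classroom_of[alter]


def test_assimilation_null_effect():
    cfg = small_config(influence_mode="assimilation", peer_effect_beta=0.0, noise_sd=0.05)
    base = generate_cohort(dataclasses.replace(cfg, influence_mode="none"))
    out = apply_peer_influence(base, cfg, np.random.default_rng(1))
    ap0 = np.array([s.ap for s in base.students])
    ap1 = np.array([s.ap for s in out.students])
    # distribution unchanged up to the injected noise
    assert abs(ap1.mean() - ap0.mean()) < 0.05
    assert np.all(np.abs(ap1 - ap1.mean().round(6)) < 1.0)


def test_assimilation_deterministic_limit():
    """noise->0, beta=1, alpha=0: every non-isolate's AP equals friends' mean AP."""
    cfg = small_config(influence_mode="assimilation", peer_effect_beta=1.0, noise_sd=1e-12)
    base = generate_cohort(dataclasses.replace(cfg, influence_mode="none"))
    out = apply_peer_influence(base, cfg, np.random.default_rng(2), alpha=0.0)
    ap0 = {s.student_id: s.ap for s in base.students}
    friends = {}
    for _, ego, alter in base.nominations:
        friends.setdefault(ego, []).append(ap0[alter])
    for s in out.students:
        if s.student_id in friends:
            expected = np.mean([ap0[a] for a in map(str, [])] or friends[s.student_id])
            assert s.ap == pytest.approx(np.clip(expected, 1, 10), abs=1e-6)
        else:
            assert s.ap == ap0[s.student_id]


def test_environment_mode_slope_sanity():
    """Pooled OLS of AP on friends' mean AP lands near the configured slope."""
    cfg = GeneratorConfig(seed=9)  # defaults: environment, beta=0.8
    cohort = generate_cohort(cfg)
    ap = {s.student_id: s.ap for s in cohort.students}
    sums, counts = {}, {}
    for _, ego, alter in cohort.nominations:
        sums[ego] = sums.get(ego, 0.0) + ap[alter]
        counts[ego] = counts.get(ego, 0) + 1
    x = np.array([sums[e] / counts[e] for e in sums])
    y = np.array([ap[e] for e in sums])
    slope = np.polyfit(x, y, 1)[0]
    assert slope == pytest.approx(0.8, abs=0.15)


def test_environment_mode_requires_multiple_classrooms():
    cfg = small_config(n_classrooms=1, influence_mode="environment")
    with pytest.raises(ConfigError):
        generate_cohort(cfg)


def test_isolates_keep_ap():
    cfg = small_config(tie_intercept=-50.0, influence_mode="environment")
    base = generate_cohort(dataclasses.replace(cfg, influence_mode="none"))
    out = apply_peer_influence(base, cfg, np.random.default_rng(3))
    assert [s.ap for s in out.students] == [s.ap for s in base.students]
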