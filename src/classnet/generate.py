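"""Synthetic classroom cohorts with known ground truth.

The study population this generator emulates is a cross-sectional sample of
~800 adolescents (ages 12-17) spread over ~32 classrooms, each student
nominating any number of best friends within their own classroom roster.
Defaults reproduce the observed marginals: ~53% girls, ~79% urban schools,
academic performance (AP) approximately N(7.2, 0.7) truncated to the 1-10
grade scale, mean out-degree ~9 and egocentric reciprocity ~0.40.

Two things are generated:

1. **Attributes** -- sex, age, AP, family-function (Apgar, 0-25), family
   affluence (FAS, 0-8), family structure and school location, drawn
   independently per student (location per classroom, since it is a school
   attribute).
2. **Nominations** -- a two-pass logistic dyad model. Pass 1 gives every
   ordered pair (i, j) a tie with probability
   ``logistic(tie_intercept + homophily_coef*|AP_i-AP_j| + samesex_coef*1[sex_i=sex_j])``;
   pass 2 revisits each absent tie whose reverse tie exists and upgrades it
   with the same logit plus ``reciprocity_coef``. Independent dyads keep
   generation O(n^2) per classroom and bit-reproducible; transitivity arises
   only incidentally.

Peer effects come in two flavours (``influence_mode``):

* ``"environment"`` (default) -- ``peer_effect_beta`` is defined as the
  population regression slope of a student's AP on the mean AP of the
  friends they nominated. It is realized through fixed, evenly spaced
  classroom academic environments whose spread is calibrated in closed form
  (see docs/methods.md); this makes the slope recoverable by the downstream
  OLS pipeline, which is the point of a parameter-recovery experiment.
* ``"assimilation"`` -- a literal one-shot influence step: each student's AP
  is redrawn once towards the pre-update mean AP of their nominated friends.
  Mechanistically transparent, but the one-shot update makes the observable
  regression slope smaller than ``peer_effect_beta`` (errors-in-variables);
  kept for mechanism-level experiments.
* ``"none"`` -- selection only; AP stays as drawn.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit
from scipy.stats import norm, truncnorm

from .errors import ConfigError
from .records import AP_RANGE, APGAR_RANGE, FAS_RANGE, StudentRecord

INFLUENCE_MODES = ("none", "environment", "assimilation")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_classrooms: int = 32
    class_size_range: tuple[int, int] = (20, 31)
    prop_girls: float = 0.527
    prop_urban: float = 0.79
    # (nuclear, single_parent, other)
    family_structure_probs: tuple[float, float, float] = (0.6675, 0.2530, 0.0795)
    age_range: tuple[int, int] = (12, 17)
    ap_mean: float = 7.2
    ap_sd: float = 0.7
    apgar_mean: float = 14.1
    apgar_sd: float = 4.1
    fas_mean: float = 1.85
    fas_sd: float = 1.6
    # tie model (log-odds); calibrated to mean out-degree ~8.9, reciprocity ~0.40
    tie_intercept: float = -0.45
    homophily_coef: float = -0.5
    samesex_coef: float = 0.4
    reciprocity_coef: float = -2.4
    # peer effect
    peer_effect_beta: float = 0.8
    noise_sd: float = 0.5
    influence_mode: str = "environment"
    seed: int = 0

    def validate(self) -> None:
        if self.n_classrooms < 1:
            raise ConfigError("n_classrooms must be >= 1")
        lo, hi = self.class_size_range
        if lo < 3 or hi < lo:
            raise ConfigError("class_size_range must satisfy 3 <= lo <= hi")
        for name in ("prop_girls", "prop_urban"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        probs = self.family_structure_probs
        if len(probs) != 3 or any(p < 0 for p in probs):
            raise ConfigError("family_structure_probs must be 3 non-negative values")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError("family_structure_probs must sum to 1 within 1e-9")
        a_lo, a_hi = self.age_range
        if not (12 <= a_lo <= a_hi <= 17):
            raise ConfigError("age_range must be an integer interval within [12, 17]")
        if not AP_RANGE[0] <= self.ap_mean <= AP_RANGE[1]:
            raise ConfigError(f"ap_mean must be in {AP_RANGE}")
        if self.ap_sd <= 0:
            raise ConfigError("ap_sd must be > 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.apgar_sd < 0 or self.fas_sd < 0:
            raise ConfigError("apgar_sd and fas_sd must be >= 0")
        if self.influence_mode not in INFLUENCE_MODES:
            raise ConfigError(f"influence_mode must be one of {INFLUENCE_MODES}")
        if self.influence_mode == "environment" and not 0.0 <= self.peer_effect_beta < 1.0:
            raise ConfigError(
                "peer_effect_beta must be in [0, 1) for influence_mode='environment'"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        kwargs = dict(d)
        for key in ("class_size_range", "family_structure_probs", "age_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown generator fields: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class Cohort:
    """Students plus nominations, with the generating configuration attached."""

    students: list[StudentRecord]
    nominations: list[tuple[str, str, str]]  # (classroom_id, ego_id, alter_id)
    truth: GeneratorConfig

    def validate(self) -> None:
        classroom_of = {s.student_id: s.classroom_id for s in self.students}
        seen = set()
        for cid, ego, alter in self.nominations:
            if ego == alter:
                raise ConfigError(f"self-nomination {ego} in classroom {cid}")
            if classroom_of.get(ego) != cid or classroom_of.get(alter) != cid:
                raise ConfigError(f"nomination {ego}->{alter} crosses classroom {cid}")
            if (ego, alter) in seen:
                raise ConfigError(f"duplicate nomination {ego}->{alter}")
            seen.add((ego, alter))


def generate_attributes(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[StudentRecord]:
    """Draw one attribute record per student for every classroom.

    AP is truncated-normal on [1, 10]; Apgar and FAS are rounded normal draws
    clamped to their instrument ranges (item sums are integers); age is
    uniform on ``age_range``; location is drawn once per classroom.
    """
    config.validate()
    records: list[StudentRecord] = []
    lo, hi = config.class_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_classrooms)
    a = (AP_RANGE[0] - config.ap_mean) / config.ap_sd
    b = (AP_RANGE[1] - config.ap_mean) / config.ap_sd
    for c, size in enumerate(sizes, start=1):
        cid = f"c{c:02d}"
        location = "urban" if rng.random() < config.prop_urban else "rural"
        sex = np.where(rng.random(size) < config.prop_girls, "girl", "boy")
        age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=size)
        ap = truncnorm.ppf(rng.random(size), a, b, loc=config.ap_mean, scale=config.ap_sd)
        apgar = np.clip(
            np.rint(rng.normal(config.apgar_mean, config.apgar_sd, size)), *APGAR_RANGE
        )
        fas = np.clip(np.rint(rng.normal(config.fas_mean, config.fas_sd, size)), *FAS_RANGE)
        fam = rng.choice(
            ["nuclear", "single_parent", "other"], size=size, p=config.family_structure_probs
        )
        for i in range(size):
            records.append(
                StudentRecord(
                    student_id=f"{cid}s{i + 1:02d}",
                    classroom_id=cid,
                    sex=str(sex[i]),
                    age=int(age[i]),
                    ap=float(ap[i]),
                    apgar=float(apgar[i]),
                    fas=float(fas[i]),
                    family_structure=str(fam[i]),
                    location=location,
                )
            )
    return records


def generate_nominations(
    students: list[StudentRecord], config: GeneratorConfig, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Two-pass logistic tie model within one classroom.

    Returns the directed edge list (ego_id, alter_id), lexicographically
    sorted. No self-ties, no duplicates; there is no cap on out-degree,
    mirroring unlimited nominations.
    """
    k = len(students)
    if k < 3:
        raise ConfigError(f"classroom needs >= 3 students, got {k}")
    ids = [s.student_id for s in students]
    ap = np.array([s.ap for s in students])
    sex = np.array([s.sex for s in students])
    d_ap = np.abs(ap[:, None] - ap[None, :])
    same_sex = (sex[:, None] == sex[None, :]).astype(float)
    logit = config.tie_intercept + config.homophily_coef * d_ap + config.samesex_coef * same_sex
    p1 = expit(logit)
    adj = rng.random((k, k)) < p1
    np.fill_diagonal(adj, False)
    # pass 2: absent ties whose reverse exists may be upgraded
    candidates = (~adj) & adj.T
    p2 = expit(logit + config.reciprocity_coef)
    adj |= candidates & (rng.random((k, k)) < p2)
    np.fill_diagonal(adj, False)
    egos, alters = np.nonzero(adj)
    return sorted((ids[i], ids[j]) for i, j in zip(egos, alters))


def _out_degrees(cohort: Cohort) -> dict[str, int]:
    d = {s.student_id: 0 for s in cohort.students}
    for _, ego, _ in cohort.nominations:
        d[ego] += 1
    return d


def apply_peer_influence(
    cohort: Cohort,
    config: GeneratorConfig,
    rng: np.random.Generator,
    alpha: float | None = None,
) -> Cohort:
    """Re-draw AP once according to ``config.influence_mode``.

    Students with zero out-neighbors keep their AP in every mode. The final
    AP is clamped to the 1-10 grade scale.

    ``environment`` assigns classroom c the fixed effect ``sqrt(T) * z_c``
    where ``z_c`` are evenly spaced standard-normal quantiles (standardized,
    weighted by non-isolate counts) and ``T = beta/(1-beta) * noise_sd^2 *
    mean(1/d_i)`` over non-isolates; a student's AP becomes
    ``ap_mean + theta_c + e_i``, ``e_i ~ N(0, noise_sd)``. This makes the
    population slope of AP on friends' mean AP equal ``peer_effect_beta``.

    ``assimilation`` sets ``AP_i' = alpha + beta * M_i + e_i`` with ``M_i``
    the pre-update mean AP of out-neighbors; ``alpha`` defaults to the value
    preserving the marginal AP mean and may be overridden.
    """
    config.validate()
    if config.influence_mode == "none":
        return cohort
    beta = config.peer_effect_beta
    degrees = _out_degrees(cohort)
    students = cohort.students
    ap = np.array([s.ap for s in students])
    d = np.array([degrees[s.student_id] for s in students])
    updated = d > 0
    if not updated.any():
        return cohort  # nobody nominated anybody; influence has no channel

    if config.influence_mode == "assimilation":
        idx = {s.student_id: i for i, s in enumerate(students)}
        friend_sum = np.zeros(len(students))
        for _, ego, alter in cohort.nominations:
            friend_sum[idx[ego]] += ap[idx[alter]]
        mean_friends = np.where(updated, friend_sum / np.maximum(d, 1), np.nan)
        if alpha is None:
            alpha = float(np.mean(ap[updated]) - beta * np.mean(mean_friends[updated]))
        new_ap = np.where(
            updated,
            alpha + beta * mean_friends + rng.normal(0.0, config.noise_sd, len(students)),
            ap,
        )
    elif config.influence_mode == "environment":
        classrooms = sorted({s.classroom_id for s in students})
        if beta > 0 and len(classrooms) < 2:
            raise ConfigError("influence_mode='environment' with beta > 0 needs >= 2 classrooms")
        inv_d = 1.0 / d[updated]
        spread = beta / (1.0 - beta) * config.noise_sd**2 * float(np.mean(inv_d))
        n_c = len(classrooms)
        z = norm.ppf((np.arange(n_c) + 0.5) / n_c)
        # standardize with non-isolate counts as weights so the student-level
        # population variance of the environment equals `spread` exactly
        cls_index = {cid: i for i, cid in enumerate(classrooms)}
        member_cls = np.array([cls_index[s.classroom_id] for s in students])
        w = np.bincount(member_cls[updated], minlength=n_c).astype(float)
        if beta > 0:
            mu_z = np.average(z, weights=w)
            sd_z = np.sqrt(np.average((z - mu_z) ** 2, weights=w))
            z = (z - mu_z) / sd_z
        theta = np.sqrt(spread) * z
        new_ap = np.where(
            updated,
            config.ap_mean + theta[member_cls] + rng.normal(0.0, config.noise_sd, len(students)),
            ap,
        )
    else:  # pragma: no cover - validate() excludes this
        raise ConfigError(f"unknown influence_mode {config.influence_mode!r}")

    new_ap = np.clip(new_ap, *AP_RANGE)
    new_students = [
        dataclasses.replace(s, ap=float(new_ap[i])) for i, s in enumerate(students)
    ]
    return Cohort(students=new_students, nominations=cohort.nominations, truth=cohort.truth)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full cohort: attributes, nominations, then peer influence.

    A single seed drives three independent stage streams (attributes, ties,
    influence) so that reruns are bit-identical.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    attr_ss, tie_ss, infl_ss = ss.spawn(3)
    students = generate_attributes(config, np.random.default_rng(attr_ss))

    by_class: dict[str, list[StudentRecord]] = {}
    for s in students:
        by_class.setdefault(s.classroom_id, []).append(s)
    tie_rng = np.random.default_rng(tie_ss)
    nominations: list[tuple[str, str, str]] = []
    for cid in sorted(by_class):
        for ego, alter in generate_nominations(by_class[cid], config, tie_rng):
            nominations.append((cid, ego, alter))

    cohort = Cohort(students=students, nominations=nominations, truth=config)
    if config.influence_mode != "none":
        cohort = apply_peer_influence(cohort, config, np.random.default_rng(infl_ss))
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write students.csv, nominations.csv and truth.json into ``outdir``."""
    from .io import write_cohort_csv  # avoid import cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "students": outdir / "students.csv",
        "nominations": outdir / "nominations.csv",
        "truth": outdir / "truth.json",
    }
    write_cohort_csv(cohort.students, cohort.nominations, paths["students"], paths["nominations"])
    paths["truth"].write_text(json.dumps(cohort.truth.to_dict(), indent=2) + "\n")
    return paths
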