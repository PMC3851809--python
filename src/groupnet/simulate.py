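"""Synthetic rosters, networks, wave pairs and PCS responses.

Everything the tool consumes can be generated here, so the full pipeline is
testable and demonstrable without any external data. The headline generator
is *census-exact*: it places exactly the requested numbers of mutual and
asymmetric dyads (uniformly at random among the eligible dyads) rather than
sampling ties independently, so a generated network's density and
reciprocity are deterministic functions of the requested census — worked
examples are reproducible to the digit, run to run.

The demo fixture emulates the shape of a small pilot group: 11 members, 8
of whom respond at the first measurement wave and 7 at the second, sparse
directed ties that grow between waves, a pre-existing pair forming its own
subgroup early on, four members who never engage, and near-ceiling
cohesion-scale responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .survey_io import (
    NominationRecord,
    PCSResponseSet,
    Roster,
    SociometricNetwork,
)

__all__ = [
    "DyadCensusSpec",
    "TwoWaveSpec",
    "PCSSimSpec",
    "make_roster",
    "simulate_dyad_census",
    "simulate_two_waves",
    "simulate_pcs",
    "network_to_records",
    "pilot_demo",
]

_DEMO_NAMES = (
    "Alma", "Brianna", "Carmen", "Dawn", "Erica", "Faith",
    "Michelle", "Natalie", "Olivia", "Priya", "Tammy", "Violet",
    "Wendy", "Yolanda", "Zoe",
)


@dataclass(frozen=True)
class DyadCensusSpec:
    """Exact MAN census to realise: ``mutual`` mutual and ``asymmetric``
    one-way dyads on ``n`` nodes, the rest null."""

    n: int
    mutual: int
    asymmetric: int
    seed: int

    def __post_init__(self) -> None:
        if self.mutual < 0 or self.asymmetric < 0:
            raise ValueError("dyad counts must be non-negative")
        if self.mutual + self.asymmetric > self.n * (self.n - 1) // 2:
            raise ValueError(
                f"census infeasible: {self.mutual}+{self.asymmetric} dyads "
                f"requested but only {self.n * (self.n - 1) // 2} exist"
            )


@dataclass(frozen=True)
class TwoWaveSpec:
    """Two-wave evolution: wave 2 keeps each wave-1 arc with
    ``retention_prob`` and forms each absent arc with ``formation_prob``."""

    baseline: DyadCensusSpec
    retention_prob: float
    formation_prob: float
    seed: int
    respondents_w1: tuple[str, ...] | None = None
    respondents_w2: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for p in (self.retention_prob, self.formation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class PCSSimSpec:
    """One-factor PCS generator: item = round(latent * loading + noise),
    truncated to the 1–7 response scale (a high ``latent_mean`` produces the
    ceiling effect typical of socially desirable responding)."""

    n_respondents: int
    latent_mean: float
    latent_sd: float
    loadings: tuple[float, ...]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.loadings) != 6:
            raise ValueError("exactly 6 loadings required")
        if any(not 0.0 <= l <= 1.0 for l in self.loadings):
            raise ValueError("loadings must be in [0, 1]")


def make_roster(n: int, group_id: str = "group") -> Roster:
    """A synthetic roster of ``n`` members with ids "1".."n"."""
    members = tuple(
        (str(i + 1), _DEMO_NAMES[i] if i < len(_DEMO_NAMES) else f"Member{i + 1}")
        for i in range(n)
    )
    return Roster(group_id=group_id, members=members)


def simulate_dyad_census(
    spec: DyadCensusSpec,
    *,
    roster: Roster | None = None,
    wave: str = "wave1",
    relation: str = "advice",
    respondents: tuple[str, ...] | None = None,
    alters: tuple[str, ...] | None = None,
) -> SociometricNetwork:
    """Generate a network realising ``spec`` exactly.

    Mutual and asymmetric dyads are chosen uniformly among eligible dyads;
    asymmetric directions are uniform among eligible egos. ``respondents``
    restricts who may *send* ties (mutual dyads then need both endpoints to
    be respondents); ``alters`` optionally restricts who may be named at
    all, which keeps chosen members entirely out of the tie structure.
    """
    roster = roster if roster is not None else make_roster(spec.n)
    if roster.size != spec.n:
        raise ValueError("roster size does not match spec.n")
    resp = frozenset(respondents) if respondents is not None else frozenset(roster.ids)
    allowed = frozenset(alters) if alters is not None else frozenset(roster.ids)
    rng = np.random.default_rng(spec.seed)
    ids = roster.ids
    eligible = [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if ids[i] in allowed and ids[j] in allowed
        and (ids[i] in resp or ids[j] in resp)
    ]
    mutual_ok = [d for d in eligible if d[0] in resp and d[1] in resp]
    if spec.mutual > len(mutual_ok):
        raise ValueError(
            f"census infeasible: {spec.mutual} mutual dyads requested but only "
            f"{len(mutual_ok)} dyads have two eligible respondents"
        )
    m_idx = rng.choice(len(mutual_ok), size=spec.mutual, replace=False)
    mutual = {mutual_ok[i] for i in m_idx}
    remaining = [d for d in eligible if d not in mutual]
    if spec.asymmetric > len(remaining):
        raise ValueError(
            f"census infeasible: {spec.asymmetric} asymmetric dyads requested "
            f"but only {len(remaining)} eligible dyads remain"
        )
    a_idx = rng.choice(len(remaining), size=spec.asymmetric, replace=False)
    arcs: set[tuple[str, str]] = set()
    for u, v in mutual:
        arcs.add((u, v))
        arcs.add((v, u))
    for i in a_idx:
        u, v = remaining[i]
        egos = [x for x in (u, v) if x in resp]
        ego = egos[int(rng.integers(len(egos)))] if len(egos) > 1 else egos[0]
        alter = v if ego == u else u
        arcs.add((ego, alter))
    return SociometricNetwork(
        roster=roster, wave=wave, relation=relation,
        arcs=frozenset(arcs), respondents=frozenset(resp),
    )


def simulate_two_waves(
    spec: TwoWaveSpec,
    *,
    roster: Roster | None = None,
    waves: tuple[str, str] = ("wave1", "wave2"),
    relation: str = "advice",
) -> tuple[SociometricNetwork, SociometricNetwork]:
    """Baseline census network plus an evolved second wave.

    Wave 2 keeps each wave-1 arc with ``retention_prob`` and adds each
    absent arc with ``formation_prob``; arcs whose ego is not a wave-2
    respondent are impossible (non-respondents send nothing).
    """
    roster = roster if roster is not None else make_roster(spec.baseline.n)
    net1 = simulate_dyad_census(
        spec.baseline, roster=roster, wave=waves[0], relation=relation,
        respondents=spec.respondents_w1,
    )
    resp2 = (
        tuple(spec.respondents_w2) if spec.respondents_w2 is not None else roster.ids
    )
    rng = np.random.default_rng(spec.seed)
    arcs2: set[tuple[str, str]] = set()
    for ego in roster.ids:
        for alter in roster.ids:
            if ego == alter or ego not in resp2:
                continue
            p = spec.retention_prob if net1.has_arc(ego, alter) else spec.formation_prob
            if rng.random() < p:
                arcs2.add((ego, alter))
    net2 = SociometricNetwork(
        roster=roster, wave=waves[1], relation=relation,
        arcs=frozenset(arcs2), respondents=frozenset(resp2),
    )
    return net1, net2


def simulate_pcs(
    spec: PCSSimSpec,
    *,
    wave: str = "wave1",
    member_ids: tuple[str, ...] | None = None,
) -> PCSResponseSet:
    """One-factor Likert responses with rounding and 1–7 truncation."""
    rng = np.random.default_rng(spec.seed)
    ids = (
        tuple(member_ids)
        if member_ids is not None
        else tuple(str(i + 1) for i in range(spec.n_respondents))
    )
    if len(ids) != spec.n_respondents:
        raise ValueError("member_ids length must equal n_respondents")
    latent = rng.normal(spec.latent_mean, spec.latent_sd, size=spec.n_respondents)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_respondents, 6))
    raw = latent[:, None] * np.asarray(spec.loadings)[None, :] + noise
    items = np.clip(np.rint(raw), 1, 7).astype(int)
    rows = tuple((mid, tuple(int(v) for v in items[i])) for i, mid in enumerate(ids))
    return PCSResponseSet(wave=wave, rows=rows)


def network_to_records(net: SociometricNetwork) -> list[NominationRecord]:
    """Flatten a network back to nomination records (roster-ordered)."""
    order = {m: i for i, m in enumerate(net.roster.ids)}
    return [
        NominationRecord(wave=net.wave, relation=net.relation, ego_id=e, alter_id=a)
        for e, a in sorted(net.arcs, key=lambda p: (order[p[0]], order[p[1]]))
    ]


def pilot_demo(seed: int = 7) -> dict:
    """A deterministic pilot-shaped demo dataset.

    An 11-member group measured at weeks four and twelve. Eight members
    respond at week four and seven at week twelve; members 2, 4, 5 and 6
    are never nominated and never respond after enrolment, so they are
    isolates throughout. Members 7 and 8 arrive with a pre-existing mutual
    tie and no other connections at week four (a separate subgroup). The
    advice network grows from a (3 mutual, 3 asymmetric) census — 9 arcs,
    density 9/110 — to (7, 6) — 20 arcs, density 20/110; the sparser
    discussion network grows from (0, 3) to (1, 4). PCS responses sit near
    the scale ceiling at both waves.
    """
    roster = make_roster(11, group_id="demo")
    resp1 = ("1", "3", "6", "7", "8", "9", "10", "11")
    resp2 = ("1", "3", "7", "8", "9", "10", "11")
    # Week-4 advice: hand-laid census (3 mutual, 3 asymmetric), four
    # isolates (2, 4, 5, 6) and the pre-existing pair 7-8 off on its own.
    advice1 = SociometricNetwork(
        roster=roster, wave="week4", relation="advice",
        arcs=frozenset({
            ("7", "8"), ("8", "7"),
            ("1", "3"), ("3", "1"),
            ("9", "10"), ("10", "9"),
            ("1", "9"), ("3", "10"), ("11", "1"),
        }),
        respondents=frozenset(resp1),
    )
    active2 = resp2  # isolates stay out of the tie structure at week 12
    advice2 = simulate_dyad_census(
        DyadCensusSpec(n=11, mutual=7, asymmetric=6, seed=seed),
        roster=roster, wave="week12", relation="advice",
        respondents=resp2, alters=active2,
    )
    discussion1 = simulate_dyad_census(
        DyadCensusSpec(n=11, mutual=0, asymmetric=3, seed=seed + 1),
        roster=roster, wave="week4", relation="discussion",
        respondents=resp1, alters=("1", "3", "7", "8", "9", "10", "11"),
    )
    discussion2 = simulate_dyad_census(
        DyadCensusSpec(n=11, mutual=1, asymmetric=4, seed=seed + 2),
        roster=roster, wave="week12", relation="discussion",
        respondents=resp2, alters=active2,
    )
    pcs1 = simulate_pcs(
        PCSSimSpec(
            n_respondents=8, latent_mean=6.1, latent_sd=0.6,
            loadings=(1.0,) * 6, noise_sd=0.6, seed=seed + 3,
        ),
        wave="week4", member_ids=resp1,
    )
    pcs2 = simulate_pcs(
        PCSSimSpec(
            n_respondents=7, latent_mean=6.6, latent_sd=0.5,
            loadings=(1.0,) * 6, noise_sd=0.6, seed=seed + 4,
        ),
        wave="week12", member_ids=resp2,
    )
    return {
        "roster": roster,
        "respondents": {"week4": resp1, "week12": resp2},
        "networks": {
            ("week4", "advice"): advice1,
            ("week12", "advice"): advice2,
            ("week4", "discussion"): discussion1,
            ("week12", "discussion"): discussion2,
        },
        "pcs": {"week4": pcs1, "week12": pcs2},
    }
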