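"""Whole-network and individual sociometric diagnostics.

All metrics operate on a :class:`~groupnet.survey_io.SociometricNetwork`
whose node set is the *full* roster — non-respondents stay in every
denominator, so printed values for a partially-responding group are
depressed relative to the respondent subgraph, deliberately.

Conventions (the monitoring protocol names metrics, not formulas, so the
exact definitions are fixed here and documented in the methods note):

* density            arcs / n(n-1)
* reciprocity        arc-based 2M/A and dyad-based non-null M/(M+S), where a
                     MAN dyad census counts M mutual, S asymmetric, N null
                     unordered pairs; the dyad-based value is the headline
* components         weak components among non-isolate nodes; reported as the
                     *excess* count beyond one (0 = no splintering)
* centralization     Freeman's general index sum(c_max - c_i) / max, with the
                     maximum attained by the (mutual) star, for total degree,
                     in-degree, out-degree, closeness and betweenness
* transitivity       percent of ordered two-paths i->j->k (i != k) closed by
                     an arc i->k
* cohesion           compactness: mean of reciprocal directed geodesic
                     distances over ordered pairs, unreachable pairs count 0

Ratios with a zero denominator are *undefined* and returned as ``None``,
never coerced to 0; downstream diagnostics treat them as "cannot evaluate".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import pandas as pd

from .survey_io import SociometricNetwork

__all__ = [
    "DyadCensus",
    "MetricsPanel",
    "CENTRALIZATION_KINDS",
    "dyad_census",
    "density",
    "isolates",
    "degree_table",
    "reciprocity",
    "components",
    "centralization",
    "transitivity_percent",
    "cohesion_compactness",
    "metrics_panel",
    "panel_row",
    "panels_to_frame",
    "round3",
]

CENTRALIZATION_KINDS = ("degree", "indegree", "outdegree", "closeness", "betweenness")


def round3(x: float | None) -> float | None:
    """Presentation rounding: 3 decimals, half-up (0.0825 -> 0.083)."""
    if x is None:
        return None
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), ROUND_HALF_UP))


@dataclass(frozen=True)
class DyadCensus:
    """MAN census of unordered node pairs: mutual / asymmetric / null."""

    mutual: int
    asymmetric: int
    null: int

    @property
    def dyads(self) -> int:
        return self.mutual + self.asymmetric + self.null

    @property
    def arcs(self) -> int:
        return 2 * self.mutual + self.asymmetric


@dataclass(frozen=True)
class MetricsPanel:
    """The full diagnostic vector for one network, unrounded."""

    wave: str
    relation: str
    n: int
    arc_count: int
    density: float
    isolate_ids: tuple[str, ...]
    degree_rows: tuple[tuple[str, int, int, int], ...]  # (id, in, out, total)
    reciprocity_arc: float | None
    reciprocity_nonnull: float | None
    excess_components: int
    component_membership: tuple[tuple[str, ...], ...]
    centralization_degree: float
    centralization_indegree: float
    centralization_outdegree: float
    centralization_closeness: float
    centralization_betweenness: float
    transitivity_pct: float | None
    cohesion_compactness: float

    @property
    def isolate_count(self) -> int:
        return len(self.isolate_ids)

    def degree_of(self, member_id: str) -> tuple[int, int, int]:
        for mid, din, dout, dtot in self.degree_rows:
            if mid == member_id:
                return din, dout, dtot
        raise KeyError(member_id)


def dyad_census(net: SociometricNetwork) -> DyadCensus:
    """Classify every unordered pair as mutual, asymmetric or null."""
    ids = net.roster.ids
    m = a = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ij = net.has_arc(ids[i], ids[j])
            ji = net.has_arc(ids[j], ids[i])
            if ij and ji:
                m += 1
            elif ij or ji:
                a += 1
    total = len(ids) * (len(ids) - 1) // 2
    return DyadCensus(mutual=m, asymmetric=a, null=total - m - a)


def density(net: SociometricNetwork) -> float:
    """Arcs present over the n(n-1) possible arcs (self-loops excluded)."""
    n = net.n
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return net.arc_count / (n * (n - 1))


def isolates(net: SociometricNetwork) -> list[str]:
    """Members with neither incoming nor outgoing ties, in roster order."""
    touched = {m for arc in net.arcs for m in arc}
    return [m for m in net.roster.ids if m not in touched]


def degree_table(net: SociometricNetwork) -> list[tuple[str, int, int, int]]:
    """Per-member (in, out, total) degree rows in roster order."""
    din = {m: 0 for m in net.roster.ids}
    dout = {m: 0 for m in net.roster.ids}
    for ego, alter in net.arcs:
        dout[ego] += 1
        din[alter] += 1
    return [(m, din[m], dout[m], din[m] + dout[m]) for m in net.roster.ids]


def reciprocity(net: SociometricNetwork) -> tuple[float | None, float | None]:
    """(arc-based, dyad-based non-null) reciprocity.

    Arc-based: share of arcs that are reciprocated, 2M / (2M + S).
    Non-null dyad-based: mutual dyads over non-null dyads, M / (M + S) —
    the headline value the monitoring thresholds refer to.
    Both are ``None`` when their denominator is zero.
    """
    c = dyad_census(net)
    arc_based = (2 * c.mutual / c.arcs) if c.arcs else None
    nonnull = c.mutual + c.asymmetric
    dyad_based = (c.mutual / nonnull) if nonnull else None
    return arc_based, dyad_based


def components(net: SociometricNetwork) -> tuple[int, list[tuple[str, ...]]]:
    """Weakly connected components among non-isolate members.

    Returns ``(excess, membership)`` where excess is the component count
    beyond one (0 for a single connected group or an empty network) and
    membership lists each component's ids in roster order, largest first.
    Isolates are excluded here — they are a separate diagnostic.
    """
    iso = set(isolates(net))
    g = net.graph().to_undirected()
    g.remove_nodes_from(iso)
    order = {m: i for i, m in enumerate(net.roster.ids)}
    comps = [
        tuple(sorted(c, key=order.__getitem__))
        for c in nx.connected_components(g)
    ]
    comps.sort(key=lambda c: (-len(c), order[c[0]]))
    return max(0, len(comps) - 1), comps


def _closeness_scores(net: SociometricNetwork) -> dict[str, float]:
    """Wasserman–Faust closeness on outward directed distances.

    c_i = (r_i / (n-1)) * (r_i / sum of d(i,j) over the r_i reachable j);
    0 for a node that reaches no one. Restricting to reachable nodes keeps
    the score defined in the disconnected networks typical of early waves.
    """
    g = net.graph()
    n = net.n
    scores = {}
    for node in net.roster.ids:
        dists = nx.single_source_shortest_path_length(g, node)
        dists.pop(node, None)
        r = len(dists)
        scores[node] = (r / (n - 1)) * (r / sum(dists.values())) if r else 0.0
    return scores


def centralization(net: SociometricNetwork, kind: str) -> float:
    """Freeman centralization: how concentrated centrality is on one member.

    ``kind`` is one of ``degree`` (total in+out), ``indegree``,
    ``outdegree``, ``closeness``, ``betweenness``. Each variant is
    normalized by its maximum over digraphs of the same size (attained by a
    star) so the index lies in [0, 1]: 0 for perfectly even centrality
    (e.g. a cycle), 1 for a star.
    """
    n = net.n
    if n < 3:
        return 0.0
    if kind == "degree":
        scores = {m: t for m, _i, _o, t in degree_table(net)}
        denom = 2 * (n - 1) * (n - 2)  # mutual star: centre 2(n-1), leaves 2
    elif kind == "indegree":
        scores = {m: i for m, i, _o, _t in degree_table(net)}
        denom = (n - 1) ** 2
    elif kind == "outdegree":
        scores = {m: o for m, _i, o, _t in degree_table(net)}
        denom = (n - 1) ** 2
    elif kind == "closeness":
        scores = _closeness_scores(net)
        # mutual star: centre 1, each leaf (n-1)/(2n-3)
        denom = (n - 1) * (n - 2) / (2 * n - 3)
    elif kind == "betweenness":
        scores = nx.betweenness_centrality(net.graph(), normalized=True)
        denom = n - 1  # mutual star: centre 1 after (n-1)(n-2) normalization
    else:
        raise ValueError(
            f"unknown centralization kind {kind!r}; expected one of "
            f"{CENTRALIZATION_KINDS}"
        )
    c_max = max(scores.values())
    num = sum(c_max - c for c in scores.values())
    return min(1.0, max(0.0, num / denom))


def transitivity_percent(net: SociometricNetwork) -> float | None:
    """Fraction of directed two-paths i->j->k (i != k) closed by i->k.

    ``None`` when the network contains no such two-paths. Two-paths through
    a mutual dyad (i = k) are excluded — closure through a 2-cycle is not a
    triad.
    """
    paths = closed = 0
    succ: dict[str, set[str]] = {m: set() for m in net.roster.ids}
    for ego, alter in net.arcs:
        succ[ego].add(alter)
    for i in net.roster.ids:
        for j in succ[i]:
            for k in succ[j]:
                if k == i:
                    continue
                paths += 1
                if k in succ[i]:
                    closed += 1
    return closed / paths if paths else None


def cohesion_compactness(net: SociometricNetwork) -> float:
    """Compactness: mean reciprocal directed geodesic distance.

    Averages 1/d(i, j) over all ordered pairs of roster members, with
    unreachable pairs contributing 0 (1/inf). 1.0 for a complete digraph,
    0.0 for an empty one.
    """
    n = net.n
    if n < 2:
        raise ValueError("cohesion undefined for fewer than 2 nodes")
    g = net.graph()
    total = 0.0
    for node in net.roster.ids:
        dists = nx.single_source_shortest_path_length(g, node)
        total += sum(1.0 / d for t, d in dists.items() if t != node)
    return total / (n * (n - 1))


def metrics_panel(net: SociometricNetwork) -> MetricsPanel:
    """Compute the full diagnostic panel. Values are exact (unrounded);
    rounding happens only at presentation via :func:`round3`."""
    arc_based, nonnull = reciprocity(net)
    excess, membership = components(net)
    return MetricsPanel(
        wave=net.wave,
        relation=net.relation,
        n=net.n,
        arc_count=net.arc_count,
        density=density(net),
        isolate_ids=tuple(isolates(net)),
        degree_rows=tuple(degree_table(net)),
        reciprocity_arc=arc_based,
        reciprocity_nonnull=nonnull,
        excess_components=excess,
        component_membership=tuple(membership),
        centralization_degree=centralization(net, "degree"),
        centralization_indegree=centralization(net, "indegree"),
        centralization_outdegree=centralization(net, "outdegree"),
        centralization_closeness=centralization(net, "closeness"),
        centralization_betweenness=centralization(net, "betweenness"),
        transitivity_pct=transitivity_percent(net),
        cohesion_compactness=cohesion_compactness(net),
    )


def panel_row(panel: MetricsPanel) -> dict:
    """One presentation row (3-decimal half-up rounding, blank undefined)."""
    return {
        "wave": panel.wave,
        "relation": panel.relation,
        "size": panel.n,
        "density": round3(panel.density),
        "reciprocity_nonnull": round3(panel.reciprocity_nonnull),
        "centralization": round3(panel.centralization_degree),
        "transitivity_pct": round3(panel.transitivity_pct),
        "cohesion": round3(panel.cohesion_compactness),
    }


def panels_to_frame(panels: list[MetricsPanel]) -> pd.DataFrame:
    """Diagnostic table, one row per (wave, relation)."""
    return pd.DataFrame([panel_row(p) for p in panels])
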