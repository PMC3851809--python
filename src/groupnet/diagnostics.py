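"""Threshold evaluation and the action report for the group leader.

The monitoring protocol is deliberately mechanical: each diagnostic has a
pre-registered threshold, every violation maps to a fixed, numbered menu of
teaching methods, and the report names the specific participants each method
should involve ("Connect Tammy with any of these members", "Make sure
Michelle and Natalie do not form a separate subgroup"). Fixing thresholds
and branching logic in advance removes subjectivity and lets the tool be
applied consistently across many groups.

Reports are deterministic: identical inputs render byte-identical text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .metrics import MetricsPanel, round3
from .survey_io import Roster, SociometricNetwork

__all__ = [
    "METRIC_ORDER",
    "ThresholdRule",
    "ThresholdConfig",
    "NodeTargets",
    "DiagnosticFinding",
    "ActionReport",
    "default_thresholds",
    "load_thresholds",
    "load_teaching_methods",
    "evaluate_thresholds",
    "identify_targets",
    "generate_action_report",
]

#: Metrics in report order; every threshold config must cover all of them.
METRIC_ORDER = (
    "isolates",
    "degree",
    "reciprocity",
    "components",
    "density",
    "centralization",
    "transitivity",
    "cohesion",
)

LEADER_INSTRUCTION = (
    "Implement at least two of the recommendations above during each "
    "subsequent group session."
)
NO_CHANGE_INSTRUCTION = (
    "All diagnostics met their thresholds: do not alter your teaching "
    "methods."
)


@dataclass(frozen=True)
class ThresholdRule:
    """One pass/flag rule: eq / gt / lt exact bounds, or an open band."""

    metric: str
    comparator: str  # eq | gt | lt | band
    value: float | None = None
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.comparator not in ("eq", "gt", "lt", "band"):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.comparator == "band":
            if self.lower is None or self.upper is None:
                raise ValueError(f"band rule for {self.metric} needs lower/upper")
        elif self.value is None:
            raise ValueError(f"rule for {self.metric} needs a value")

    def passes(self, observed: float) -> bool:
        if self.comparator == "eq":
            return observed == self.value
        if self.comparator == "gt":
            return observed > self.value
        if self.comparator == "lt":
            return observed < self.value
        return self.lower < observed < self.upper

    def describe(self) -> str:
        if self.comparator == "eq":
            return f"should equal {self.value:g}"
        if self.comparator == "gt":
            return f"should be > {self.value:g}"
        if self.comparator == "lt":
            return f"should be < {self.value:g}"
        return f"should be > {self.lower:g} and < {self.upper:g}"


@dataclass(frozen=True)
class ThresholdConfig:
    """The complete rule set, one :class:`ThresholdRule` per metric."""

    rules: tuple[ThresholdRule, ...]

    def __post_init__(self) -> None:
        names = [r.metric for r in self.rules]
        missing = [m for m in METRIC_ORDER if m not in names]
        if missing:
            raise ValueError(f"threshold config missing metric(s): {missing}")
        unknown = [m for m in names if m not in METRIC_ORDER]
        if unknown:
            raise ValueError(f"threshold config has unknown metric(s): {unknown}")

    def rule(self, metric: str) -> ThresholdRule:
        for r in self.rules:
            if r.metric == metric:
                return r
        raise KeyError(metric)


def _config_from_mapping(raw: dict) -> ThresholdConfig:
    rules = []
    for metric, spec in raw.items():
        rules.append(
            ThresholdRule(
                metric=metric,
                comparator=spec["comparator"],
                value=spec.get("value"),
                lower=spec.get("lower"),
                upper=spec.get("upper"),
            )
        )
    return ThresholdConfig(rules=tuple(rules))


def default_thresholds() -> ThresholdConfig:
    """The shipped defaults (isolates = 0, degree > 1, reciprocity > 0.50,
    excess components = 0, 0.15 < density < 0.50, centralization < 0.25,
    transitivity > 0.30, cohesion > 0.25)."""
    raw = yaml.safe_load(
        resources.files("groupnet.data").joinpath("thresholds.yaml").read_text()
    )
    return _config_from_mapping(raw)


def load_thresholds(path: str | Path) -> ThresholdConfig:
    """Load a threshold config from a YAML file shaped like the default."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return _config_from_mapping(raw)


def load_teaching_methods() -> dict[str, list[str]]:
    """The shipped numbered method templates per metric (1-based order)."""
    return yaml.safe_load(
        resources.files("groupnet.data").joinpath("teaching_methods.yaml").read_text()
    )


@dataclass(frozen=True)
class NodeTargets:
    """Participant-level targets feeding the report's name substitution."""

    isolate_ids: tuple[str, ...]
    low_degree_ids: tuple[str, ...]          # total degree <= 1, roster order
    hub_ids: tuple[str, ...]                 # maximum total degree, roster order
    unreciprocated: tuple[tuple[str, str], ...]  # (ego, alter): arc one-way
    component_membership: tuple[tuple[str, ...], ...]
    central_id: str | None                   # max total degree, roster tie-break
    central_betweenness_id: str | None       # reported when it differs
    open_triads: tuple[tuple[str, str, str], ...]  # (i, j, k): i->j->k, no i->k


@dataclass(frozen=True)
class DiagnosticFinding:
    """Outcome of one metric vs its rule."""

    metric: str
    observed: float | None
    rule: ThresholdRule
    status: str  # pass | flag | cannot_evaluate
    node_ids: tuple = ()

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "observed": self.observed,
            "rule": self.rule.describe(),
            "status": self.status,
            "targets": [list(t) if isinstance(t, tuple) else t for t in self.node_ids],
        }


@dataclass(frozen=True)
class ActionReport:
    """The deliverable handed to the group leader."""

    group_id: str
    wave: str
    relation: str
    findings: tuple[DiagnosticFinding, ...]
    recommendations: tuple[tuple[str, int, str], ...]  # (metric, number, text)
    notes: tuple[str, ...]
    leader_instruction: str
    map_reference: str | None = None

    def to_markdown(self) -> str:
        lines = [
            f"# Action report — group {self.group_id}, "
            f"{self.relation} network, {self.wave}",
            "",
            "## Diagnostics",
            "",
            "| Metric | Observed | Threshold | Status |",
            "|---|---|---|---|",
        ]
        for f in self.findings:
            obs = "undefined" if f.observed is None else f"{round3(f.observed):g}"
            lines.append(
                f"| {f.metric} | {obs} | {f.rule.describe()} | {f.status} |"
            )
        lines += ["", "## Recommendations", ""]
        if self.recommendations:
            for metric, number, text in self.recommendations:
                lines.append(f"- **{metric} {number}.** {text}")
        else:
            lines.append("- No changes recommended.")
        for note in self.notes:
            lines.append(f"- *Note:* {note}")
        lines += ["", f"**Instruction to group leader:** {self.leader_instruction}"]
        if self.map_reference:
            lines += ["", f"Network map: {self.map_reference}"]
        return "\n".join(lines) + "\n"

    def to_text(self) -> str:
        lines = [
            f"ACTION REPORT — group {self.group_id}, {self.relation} network, "
            f"{self.wave}",
            "",
        ]
        for f in self.findings:
            obs = "undefined" if f.observed is None else f"{round3(f.observed):g}"
            lines.append(
                f"  {f.metric:<14} {obs:>9}  ({f.rule.describe()})  -> {f.status}"
            )
        lines.append("")
        if self.recommendations:
            lines.append("Recommendations:")
            for metric, number, text in self.recommendations:
                lines.append(f"  [{metric} {number}] {text}")
        else:
            lines.append("Recommendations: none.")
        for note in self.notes:
            lines.append(f"  Note: {note}")
        lines += ["", self.leader_instruction]
        return "\n".join(lines) + "\n"

    def findings_json(self) -> str:
        return json.dumps(
            {
                "group_id": self.group_id,
                "wave": self.wave,
                "relation": self.relation,
                "findings": [f.to_dict() for f in self.findings],
                "recommendations": [
                    {"metric": m, "method": n, "text": t}
                    for m, n, t in self.recommendations
                ],
                "leader_instruction": self.leader_instruction,
            },
            indent=2,
        )


def identify_targets(net: SociometricNetwork, panel: MetricsPanel) -> NodeTargets:
    """Locate the participants each flagged metric should act on.

    Hubs and the central member are chosen by maximum total degree with ties
    broken by roster order; the betweenness-central member is reported
    alongside when it differs (relative degree/closeness/betweenness values
    identify central nodes).
    """
    degrees = {m: t for m, _i, _o, t in panel.degree_rows}
    max_deg = max(degrees.values()) if degrees else 0
    hubs = tuple(m for m in net.roster.ids if degrees[m] == max_deg and max_deg > 0)
    low = tuple(m for m in net.roster.ids if degrees[m] <= 1)
    order = {m: i for i, m in enumerate(net.roster.ids)}
    unrec = tuple(
        sorted(
            ((e, a) for e, a in net.arcs if (a, e) not in net.arcs),
            key=lambda p: (order[p[0]], order[p[1]]),
        )
    )
    central = hubs[0] if hubs else None
    central_btw = None
    if central is not None:
        import networkx as nx

        btw = nx.betweenness_centrality(net.graph(), normalized=True)
        best = max(btw.values())
        if best > 0:
            cand = min((m for m, v in btw.items() if v == best), key=order.__getitem__)
            if cand != central:
                central_btw = cand
    succ: dict[str, set[str]] = {m: set() for m in net.roster.ids}
    for e, a in net.arcs:
        succ[e].add(a)
    triads = tuple(
        sorted(
            (
                (i, j, k)
                for i in net.roster.ids
                for j in succ[i]
                for k in succ[j]
                if k != i and k not in succ[i]
            ),
            key=lambda t: (order[t[0]], order[t[1]], order[t[2]]),
        )
    )
    return NodeTargets(
        isolate_ids=panel.isolate_ids,
        low_degree_ids=low,
        hub_ids=hubs,
        unreciprocated=unrec,
        component_membership=panel.component_membership,
        central_id=central,
        central_betweenness_id=central_btw,
        open_triads=triads,
    )


def evaluate_thresholds(
    panel: MetricsPanel, config: ThresholdConfig, targets: NodeTargets | None = None
) -> list[DiagnosticFinding]:
    """Compare every configured metric against its rule.

    Returns one finding per metric in :data:`METRIC_ORDER`. Undefined
    observations yield ``cannot_evaluate``. The degree rule is applied per
    member (every member's total degree must satisfy it); its observed value
    is the minimum total degree.
    """
    degrees = [t for _m, _i, _o, t in panel.degree_rows]
    observed: dict[str, float | None] = {
        "isolates": panel.isolate_count,
        "degree": min(degrees),
        "reciprocity": panel.reciprocity_nonnull,
        "components": panel.excess_components,
        "density": panel.density,
        "centralization": panel.centralization_degree,
        "transitivity": panel.transitivity_pct,
        "cohesion": panel.cohesion_compactness,
    }
    findings = []
    for metric in METRIC_ORDER:
        rule = config.rule(metric)
        obs = observed[metric]
        if obs is None:
            status = "cannot_evaluate"
        else:
            status = "pass" if rule.passes(obs) else "flag"
        node_ids: tuple = ()
        if targets is not None and status == "flag":
            node_ids = {
                "isolates": targets.isolate_ids,
                "degree": targets.low_degree_ids,
                "reciprocity": targets.unreciprocated,
                "components": targets.component_membership,
                "centralization": (targets.central_id,) if targets.central_id else (),
                "transitivity": targets.open_triads,
            }.get(metric, ())
        findings.append(
            DiagnosticFinding(
                metric=metric, observed=obs, rule=rule, status=status,
                node_ids=tuple(node_ids),
            )
        )
    return findings


def _fmt_names(roster: Roster, ids) -> str:
    return ", ".join(roster.display_name(m) for m in ids)


def _substitutions(roster: Roster, targets: NodeTargets, group_id: str) -> dict:
    name = roster.display_name
    hub = name(targets.hub_ids[0]) if targets.hub_ids else "a well-connected member"
    pairings = (
        "; ".join(f"{name(i)} with {hub}" for i in targets.isolate_ids)
        or "(no isolates)"
    )
    comps = targets.component_membership
    bridges = (
        "; ".join(
            f"{name(comps[i][0])} with {name(comps[j][0])}"
            for i in range(len(comps))
            for j in range(i + 1, len(comps))
        )
        or "(single component)"
    )
    subgroups = ", ".join("{" + _fmt_names(roster, c) + "}" for c in comps) or "(none)"
    triads = targets.open_triads[:5]
    open_triads = (
        "; ".join(f"connect {name(i)} and {name(k)} (both linked with {name(j)})"
                  for i, j, k in triads)
        + ("; …" if len(targets.open_triads) > 5 else "")
    ) or "(no open triads)"
    central = name(targets.central_id) if targets.central_id else "(none)"
    if targets.central_betweenness_id:
        central += f" (by betweenness: {name(targets.central_betweenness_id)})"
    return {
        "group": group_id,
        "isolates": _fmt_names(roster, targets.isolate_ids) or "(none)",
        "pairings": pairings,
        "low_degree": _fmt_names(roster, targets.low_degree_ids) or "(none)",
        "hubs": _fmt_names(roster, targets.hub_ids) or "(none)",
        "dyads": ", ".join(
            f"{name(e)}→{name(a)}" for e, a in targets.unreciprocated
        ) or "(none)",
        "bridges": bridges,
        "subgroups": subgroups,
        "central": central,
        "open_triads": open_triads,
    }


def generate_action_report(
    findings: list[DiagnosticFinding],
    targets: NodeTargets,
    roster: Roster,
    config: ThresholdConfig,
    *,
    wave: str,
    relation: str,
    map_reference: str | None = None,
) -> ActionReport:
    """Render the leader-facing report.

    Every flagged metric contributes its full numbered method menu with
    participant names substituted; if nothing is flagged the report carries
    the explicit no-change instruction. ``cannot_evaluate`` findings add an
    explanatory note, never a recommendation.
    """
    methods = load_teaching_methods()
    subs = _substitutions(roster, targets, roster.group_id)
    recommendations: list[tuple[str, int, str]] = []
    notes: list[str] = []
    metric_to_methods = {
        "isolates": "isolates",
        "degree": "low_degree",
        "reciprocity": "reciprocity",
        "components": "components",
        "density": "density",
        "centralization": "centralization",
        "transitivity": "transitivity",
        "cohesion": "cohesion",
    }
    for f in findings:
        if f.status == "cannot_evaluate":
            notes.append(
                f"{f.metric} could not be evaluated (undefined on this "
                f"network, e.g. no eligible ties); no recommendation issued."
            )
            continue
        if f.status != "flag":
            continue
        for number, template in enumerate(methods[metric_to_methods[f.metric]], 1):
            recommendations.append((f.metric, number, template.format(**subs)))
    instruction = LEADER_INSTRUCTION if recommendations else NO_CHANGE_INSTRUCTION
    return ActionReport(
        group_id=roster.group_id,
        wave=wave,
        relation=relation,
        findings=tuple(findings),
        recommendations=tuple(recommendations),
        notes=tuple(notes),
        leader_instruction=instruction,
        map_reference=map_reference,
    )
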