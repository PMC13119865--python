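"""Short-run treatment-pathway decision trees for an exacerbation episode.

Both arms share one topology: a first-line treatment (antibiotics alone, or
steroids plus antibiotics, split by the arm's probability of receiving
antibiotics), up to two further treatment rounds for non-responders, then a
hospital-admission stage whose survivors are fully or partially recovered.
The arms differ only in the antibiotic probability (1 - test sensitivity in
the tested arm vs clinical judgement in usual care), the arm-specific
improvement probabilities, the admission-stage probabilities, and the test
unit cost, which enters the tested arm exactly once at the root.

Expected episode cost and utility payoff are obtained by rollback; terminal
outcomes also yield the severity distribution (mild / moderate / severe /
dead) that seeds the lifetime cohort model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np

from .params import ParameterSet

SEVERITY_CLASSES = ("mild", "moderate", "severe_full", "severe_partial", "dead")

# probability reference: ("param", dotted-path) | ("const", x) | ("complement", ref)
ProbRef = tuple


def resolve_prob(ref: ProbRef, params: ParameterSet) -> float:
    kind = ref[0]
    if kind == "const":
        return float(ref[1])
    if kind == "param":
        try:
            return params.probabilities[ref[1]].mean
        except KeyError:
            raise ValueError(f"unresolved probability reference {ref[1]!r}") from None
    if kind == "complement":
        return 1.0 - resolve_prob(ref[1], params)
    raise ValueError(f"unknown probability reference kind {kind!r}")


@dataclass
class TreeNode:
    kind: str                     # "chance" | "terminal"
    label: str
    branches: list[tuple[ProbRef, "TreeNode"]] = field(default_factory=list)
    costs: list[tuple[str, float]] = field(default_factory=list)  # (cost key, quantity)
    severity: str | None = None   # terminal only, one of SEVERITY_CLASSES

    def __post_init__(self) -> None:
        if self.kind == "terminal":
            if self.severity not in SEVERITY_CLASSES:
                raise ValueError(f"terminal {self.label!r} needs a severity class")
            if self.branches:
                raise ValueError(f"terminal {self.label!r} cannot have branches")
        elif self.kind != "chance":
            raise ValueError(f"unknown node kind {self.kind!r}")

    def to_dict(self) -> dict[str, Any]:
        doc: dict[str, Any] = {"kind": self.kind, "label": self.label}
        if self.costs:
            doc["costs"] = [{"item": k, "quantity": q} for k, q in self.costs]
        if self.kind == "terminal":
            doc["severity"] = self.severity
        else:
            doc["branches"] = [
                {"probability": _ref_to_doc(ref), "child": child.to_dict()}
                for ref, child in self.branches
            ]
        return doc

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "TreeNode":
        costs = [(c["item"], float(c["quantity"])) for c in doc.get("costs", [])]
        if doc["kind"] == "terminal":
            return cls("terminal", doc["label"], costs=costs, severity=doc["severity"])
        branches = [
            (_ref_from_doc(b["probability"]), cls.from_dict(b["child"]))
            for b in doc["branches"]
        ]
        return cls("chance", doc["label"], branches=branches, costs=costs)


def _ref_to_doc(ref: ProbRef) -> Any:
    if ref[0] == "complement":
        return {"complement": _ref_to_doc(ref[1])}
    return {ref[0]: ref[1]}


def _ref_from_doc(doc: Any) -> ProbRef:
    (key, value), = doc.items()
    if key == "complement":
        return ("complement", _ref_from_doc(value))
    return (key, value)


@dataclass
class ArmExpectation:
    expected_cost: float
    expected_payoff: float
    severity_distribution: dict[str, float]

    @property
    def death_probability(self) -> float:
        return self.severity_distribution["dead"]


def _terminal_payoff(severity: str, params: ParameterSet) -> float:
    if severity == "dead":
        return 0.0
    if severity in ("mild", "moderate", "severe_full"):
        return params.utilities["fully_recovered"].value
    return params.utilities["partially_recovered"].value


def _binary(label: str, p_yes: ProbRef, yes: TreeNode, no: TreeNode,
            costs: list[tuple[str, float]] | None = None) -> TreeNode:
    return TreeNode("chance", label,
                    branches=[(p_yes, yes), (("complement", p_yes), no)],
                    costs=costs or [])


def build_arm_tree(arm: str, params: ParameterSet) -> TreeNode:
    """Construct the pathway tree for ``arm`` ("intervention" or "control")."""
    if arm not in ("intervention", "control"):
        raise ValueError(f"unknown arm {arm!r}")
    cfg = params.tree
    ae_split = float(cfg.get("second_line_ae_split", 0.5))
    recovery_split = float(cfg.get("full_recovery_after_admission", 0.5))

    def admitted() -> TreeNode:
        survivor = _binary(
            "recovery after admission",
            ("const", recovery_split),
            TreeNode("terminal", "fully recovered after admission",
                     severity="severe_full"),
            TreeNode("terminal", "partially recovered after admission",
                     severity="severe_partial"),
        )
        return _binary(
            "outcome of admission",
            ("param", "shared.mortality_after_admission"),
            TreeNode("terminal", "died in hospital", severity="dead"),
            survivor,
            costs=[("copd_hospital_stay", 1.0)],
        )

    def admission_gate(hosp_ref: ProbRef, extra_costs=None) -> TreeNode:
        community = TreeNode(
            "terminal", "severe, managed in community", severity="severe_partial",
            costs=[("home_visit", 1.0), ("community_nurse_follow_up", 1.0)],
        )
        return _binary("hospital admission", hosp_ref, admitted(), community,
                       costs=list(extra_costs or []))

    def admission_stage(first_line: str) -> TreeNode:
        if arm == "intervention":
            key = ("hospitalisation.intervention_ab" if first_line == "ab"
                   else "hospitalisation.intervention_st_ab")
            return admission_gate(("param", key))
        viral_costs = ([("alternative_antibiotics", 1.0)]
                       if cfg.get("control_viral_alt_antibiotics", False) else [])
        return _binary(
            "infection type",
            ("const", float(cfg.get("p_bacterial_control", 0.5))),
            admission_gate(("param", "hospitalisation.control_bacterial")),
            admission_gate(("param", "hospitalisation.control_viral"),
                           extra_costs=viral_costs),
        )

    def third_line(first_line: str) -> TreeNode:
        return _binary(
            "third treatment",
            ("param", "shared.improve_third_treatment"),
            TreeNode("terminal", "recovered after third treatment",
                     severity="moderate"),
            admission_stage(first_line),
            costs=[("gp_consultation", 1.0), ("prescription", 1.0),
                   ("antibiotic_course", 1.0), ("steroid_course", 1.0)],
        )

    second_ab_ae = _binary(
        "second treatment: antibiotics with A&E attendance",
        ("param", f"{arm}.improve_second_ab_ae"),
        TreeNode("terminal", "recovered after second treatment (ab & AE)",
                 severity="moderate"),
        third_line("ab"),
        costs=[("ae_without_admission", 1.0), ("prescription", 1.0),
               ("antibiotic_course", 1.0)],
    )
    second_ab = _binary(
        "second treatment: repeat antibiotics",
        ("param", f"{arm}.improve_second_ab"),
        TreeNode("terminal", "recovered after second antibiotics",
                 severity="moderate"),
        third_line("ab"),
        costs=[("gp_consultation", 1.0), ("prescription", 1.0),
               ("antibiotic_course", 1.0)],
    )
    ab_first = _binary(
        "improve after initial antibiotics",
        ("param", f"{arm}.improve_initial_antibiotics"),
        TreeNode("terminal", "recovered after initial antibiotics",
                 severity="mild"),
        _binary("second-line route", ("const", ae_split), second_ab_ae, second_ab),
        costs=[("gp_consultation", 1.0), ("prescription", 1.0),
               ("antibiotic_course", 1.0)],
    )
    second_st_ab = _binary(
        "second treatment: steroids and antibiotics",
        ("param", f"{arm}.improve_second_st_ab"),
        TreeNode("terminal", "recovered after second treatment (st & ab)",
                 severity="moderate"),
        third_line("st_ab"),
        costs=[("gp_consultation", 1.0), ("prescription", 1.0),
               ("antibiotic_course", 1.0), ("steroid_course", 1.0)],
    )
    st_ab_first = _binary(
        "improve after initial steroids and antibiotics",
        ("param", f"{arm}.improve_initial_st_ab"),
        TreeNode("terminal", "recovered after initial steroids and antibiotics",
                 severity="mild"),
        second_st_ab,
        costs=[("gp_consultation", 1.0), ("prescription", 1.0),
               ("antibiotic_course", 1.0), ("steroid_course", 1.0)],
    )

    root_costs = [("rp21_test", 1.0)] if arm == "intervention" else []
    return _binary(
        f"{arm}: first-line treatment",
        ("param", f"{arm}.antibiotics_initial"),
        ab_first,
        st_ab_first,
        costs=root_costs,
    )


def _node_cost(node: TreeNode, params: ParameterSet) -> float:
    total = 0.0
    for key, quantity in node.costs:
        try:
            total += params.costs[key].mean * quantity
        except KeyError:
            raise ValueError(f"unresolved cost reference {key!r}") from None
    return total


def rollback(tree: TreeNode, params: ParameterSet) -> ArmExpectation:
    """Expected cost, expected utility payoff and severity distribution.

    Computed bottom-up: a chance node's expectation is its incremental cost
    plus the probability-weighted expectations of its children.  Zero-
    probability branches are pruned; branch probabilities must sum to 1.
    """

    def visit(node: TreeNode) -> tuple[float, float, np.ndarray]:
        cost_here = _node_cost(node, params)
        if node.kind == "terminal":
            dist = np.zeros(len(SEVERITY_CLASSES))
            dist[SEVERITY_CLASSES.index(node.severity)] = 1.0
            return cost_here, _terminal_payoff(node.severity, params), dist
        probs = [resolve_prob(ref, params) for ref, _ in node.branches]
        if any(p < -1e-12 or p > 1 + 1e-12 for p in probs):
            raise ValueError(f"{node.label}: branch probability outside [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError(
                f"{node.label}: branch probabilities sum to {sum(probs)!r}, not 1"
            )
        cost = cost_here
        payoff = 0.0
        dist = np.zeros(len(SEVERITY_CLASSES))
        for p, (_, child) in zip(probs, node.branches):
            if p == 0.0:
                continue
            c_cost, c_payoff, c_dist = visit(child)
            cost += p * c_cost
            payoff += p * c_payoff
            dist += p * c_dist
        return cost, payoff, dist

    cost, payoff, dist = visit(tree)
    return ArmExpectation(
        expected_cost=cost,
        expected_payoff=payoff,
        severity_distribution=dict(zip(SEVERITY_CLASSES, dist)),
    )


def severity_distribution(
    exp: ArmExpectation,
    stage_mix,
    entry_states: dict[str, str] | None = None,
):
    """Markov entry distribution over the 10 cohort states.

    Short-run classes are mapped onto exacerbation-severity entry states
    (``entry_states``; by default mild -> mild, moderate and severe ->
    moderate) and spread across GOLD II/III/IV by ``stage_mix``; episode
    deaths enter the absorbing dead state.
    """
    from .markov import STATES, state_index

    mix = np.asarray(stage_mix, dtype=float)
    if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("stage mix must be 3 nonnegative values summing to 1")
    mapping = {"mild": "mild", "moderate": "moderate", "severe": "moderate"}
    if entry_states:
        mapping.update(entry_states)

    entry = np.zeros(len(STATES))
    dist = exp.severity_distribution
    class_to_severity = {
        "mild": mapping["mild"],
        "moderate": mapping["moderate"],
        "severe_full": mapping["severe"],
        "severe_partial": mapping["severe"],
    }
    for cls, severity in class_to_severity.items():
        for stage, weight in zip(("stage_2", "stage_3", "stage_4"), mix):
            entry[state_index(severity, stage)] += dist[cls] * weight
    entry[-1] = dist["dead"]
    return entry


def iter_paths(tree: TreeNode, params: ParameterSet) -> Iterator[tuple[float, float, str, list[str]]]:
    """Yield every root-to-leaf path as (probability, cost, severity, labels)."""
    stack = [(tree, 1.0, 0.0, [])]
    while stack:
        node, prob, cost, labels = stack.pop()
        cost = cost + _node_cost(node, params)
        labels = labels + [node.label]
        if node.kind == "terminal":
            yield prob, cost, node.severity, labels
            continue
        for ref, child in node.branches:
            p = resolve_prob(ref, params)
            if p > 0.0:
                stack.append((child, prob * p, cost, labels))


def count_cost_refs(tree: TreeNode, key: str) -> int:
    """Number of nodes referencing cost item ``key`` (structural audit)."""
    n = sum(1 for item, _ in tree.costs if item == key)
    for _, child in tree.branches:
        n += count_cost_refs(child, key)
    return n


def render_pathways(tree: TreeNode, params: ParameterSet) -> str:
    """Human-readable pathway listing for audit."""
    lines = []
    for prob, cost, severity, labels in iter_paths(tree, params):
        lines.append(
            f"p={prob:.6f}  cost=£{cost:.2f}  outcome={severity}  :: "
            + " -> ".join(labels)
        )
    return "\n".join(sorted(lines, reverse=True))
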