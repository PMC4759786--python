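"""Boolean model of the lactate-mediated neuroprotective cascade.

The protective pathway is a chain of qualitative activation steps:
extracellular L-lactate is taken up and converted to pyruvate by LDH;
pyruvate enters mitochondria through the mitochondrial pyruvate
carrier (MPC) and fuels ATP synthesis; ATP is released through
pannexin channels, stimulates metabotropic P2Y2 purinergic receptors
in an autocrine/paracrine loop, which activates PI3K and finally opens
ATP-sensitive potassium (K_ATP) channels.  The resulting
hyperpolarisation lowers excitability during the glutamate insult --
that is the protected state.

No kinetics are modelled: every node is Boolean (AND over its required
inputs), which is exactly the resolution of the protected /
not-protected readout the pharmacology supports.  Interventions map
named agents onto nodes:

- *activators* drive their target node regardless of upstream state
  (e.g. UTPgS drives the P2Y2 node directly);
- *inhibitors* clamp their target false (e.g. LY294002 on PI3K);
- *degraders* (apyrase) empty the extracellular ATP pool unless a
  hydrolysis-resistant agonist (ATPgS) sustains it.

NMDA-receptor antagonists (APV, MK801) are handled by a dedicated
upstream rule: they remove the excitotoxic insult itself, so the
outcome is protective without engaging the cascade.

Side branches that purinergic stimulation also touches -- adenylate
cyclase/cAMP and the MAPK pathway -- are modelled as dead ends (their
blockade leaves protection intact), as are the P2Y1 and adenosine (P1)
receptors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

PROTECTED_NODE = "protected"
INSULT_NODE = "NMDA_R"

#: Backbone of the protective cascade, upstream -> downstream.
BACKBONE = (
    "Lactate_in", "LDH_pyruvate", "MPC_transport", "mito_ATP",
    "pannexin_release", "ATP_ext", "P2_P2Y2", "PI3K", "KATP_open",
    PROTECTED_NODE,
)

#: Receptor / messenger nodes with no route to the protected state.
DEAD_ENDS = ("P2Y1", "P1_adenosine", "AC_cAMP", "MAPK",
             "D_lactate_pool", "glucose_pool")


@dataclass(frozen=True)
class Intervention:
    """How one named agent acts on the network."""

    target: str
    action: str                      # activate | inhibit | degrade
    apyrase_resistant: bool = False

    def __post_init__(self) -> None:
        if self.action not in ("activate", "inhibit", "degrade"):
            raise ValueError(f"unknown action {self.action!r}")


#: Registry of every recognised agent.  Substrates and agonists
#: activate their entry node; blockers clamp their target; apyrase
#: degrades the extracellular ATP pool.
AGENT_MAP: Mapping[str, Intervention] = {
    # substrates
    "L-Lactate": Intervention("Lactate_in", "activate"),
    "Pyruvate": Intervention("MPC_transport", "activate"),   # bypasses LDH
    "D-Lactate": Intervention("D_lactate_pool", "activate"),  # not metabolised
    "D-Glucose": Intervention("glucose_pool", "activate"),    # no protective ATP pool
    # agonists
    "ATPgS": Intervention("ATP_ext", "activate", apyrase_resistant=True),
    "UTPgS": Intervention("P2_P2Y2", "activate"),
    "2MeSADP": Intervention("P2Y1", "activate"),
    "Adenosine": Intervention("P1_adenosine", "activate"),
    # blockers
    "UK5099": Intervention("MPC_transport", "inhibit"),
    "PPADS": Intervention("P2_P2Y2", "inhibit"),
    "MRS2179": Intervention("P2Y1", "inhibit"),
    "Probenecid": Intervention("pannexin_release", "inhibit"),
    "Carbenoxolone": Intervention("pannexin_release", "inhibit"),
    "Apyrase": Intervention("ATP_ext", "degrade"),
    "LY294002": Intervention("PI3K", "inhibit"),
    "SQ22536": Intervention("AC_cAMP", "inhibit"),
    "U0126": Intervention("MAPK", "inhibit"),
    "Glibenclamide": Intervention("KATP_open", "inhibit"),
    "APV": Intervention(INSULT_NODE, "inhibit"),
    "MK801": Intervention(INSULT_NODE, "inhibit"),
}

SUBSTRATES = frozenset({"L-Lactate", "Pyruvate", "D-Lactate", "D-Glucose"})
AGONISTS = frozenset({"ATPgS", "UTPgS", "2MeSADP", "Adenosine"})
BLOCKERS = frozenset({"UK5099", "PPADS", "MRS2179", "Probenecid", "Carbenoxolone",
                      "Apyrase", "LY294002", "SQ22536", "U0126", "Glibenclamide",
                      "APV", "MK801"})


@dataclass(frozen=True)
class Condition:
    """One pharmacological condition: sets of agents applied together."""

    condition_id: str
    substrates: frozenset[str] = frozenset()
    agonists: frozenset[str] = frozenset()
    blockers: frozenset[str] = frozenset()
    observed_significance: str | None = None   # fixture metadata: ns/*/**/***
    observed_pct_id: float | None = None
    observed_sem: float | None = None
    n_cult: int | None = None
    n_cell: int | None = None

    def __post_init__(self) -> None:
        for name, allowed, kind in ((self.substrates, SUBSTRATES, "substrate"),
                                    (self.agonists, AGONISTS, "agonist"),
                                    (self.blockers, BLOCKERS, "blocker")):
            unknown = set(name) - allowed
            if unknown:
                raise ValueError(f"unknown {kind}(s): {sorted(unknown)}")

    @property
    def agents(self) -> frozenset[str]:
        return self.substrates | self.agonists | self.blockers

    @property
    def observed_protected(self) -> bool | None:
        """Fixture readout: a significant ID-rate reduction = protected."""
        if self.observed_significance is None:
            return None
        return self.observed_significance != "ns"


@dataclass
class CascadeModel:
    """Directed Boolean activation network with intervention state.

    Node attributes: ``driven`` (an external activator feeds the node),
    ``clamped`` (an inhibitor forces it false), ``degraded`` (apyrase
    empties the pool unless a resistant drive is present) and
    ``resistant_drive``.
    """

    graph: nx.DiGraph

    def copy(self) -> "CascadeModel":
        return CascadeModel(self.graph.copy())


def build_default_model() -> CascadeModel:
    """The default lactate -> ATP -> P2Y2 -> PI3K -> K_ATP network.

    The backbone is a single activation chain; P2Y1, adenosine (P1),
    cAMP and MAPK nodes hang off it (or stand alone) without a route to
    ``protected``; the NMDA-receptor node carries the insult and is
    true by default.
    """
    g = nx.DiGraph()
    for node in (*BACKBONE, *DEAD_ENDS, INSULT_NODE):
        g.add_node(node, driven=False, clamped=False, degraded=False,
                   resistant_drive=False)
    for up, down in zip(BACKBONE[:-1], BACKBONE[1:]):
        g.add_edge(up, down)
    # purinergic stimulation also engages cAMP and MAPK side branches
    g.add_edge("P2_P2Y2", "AC_cAMP")
    g.add_edge("P2_P2Y2", "MAPK")
    # the insult is present unless an NMDA antagonist removes it
    g.nodes[INSULT_NODE]["driven"] = True
    return CascadeModel(g)


def apply_condition(model: CascadeModel, condition: Condition) -> CascadeModel:
    """Return a copy of the model with the condition's agents applied.

    Activators set ``driven`` on their target, inhibitors set
    ``clamped``, apyrase sets ``degraded`` on the extracellular ATP
    pool; apyrase-resistant activators additionally set
    ``resistant_drive`` so they survive degradation.
    """
    out = model.copy()
    g = out.graph
    for agent in sorted(condition.agents):
        iv = AGENT_MAP.get(agent)
        if iv is None:
            raise ValueError(f"unknown agent {agent!r}")
        if iv.target not in g:
            raise ValueError(f"agent {agent!r} targets missing node {iv.target!r}")
        attrs = g.nodes[iv.target]
        if iv.action == "activate":
            attrs["driven"] = True
            if iv.apyrase_resistant:
                attrs["resistant_drive"] = True
        elif iv.action == "inhibit":
            attrs["clamped"] = True
        else:  # degrade
            attrs["degraded"] = True
    return out


def evaluate_states(model: CascadeModel) -> dict[str, bool]:
    """Fixed-point Boolean evaluation in topological order.

    A node is true when it is not clamped and either an external
    activator drives it or all of its parents are true (AND semantics;
    sources with no drive stay false).  A degraded node is true only
    under a degradation-resistant drive.
    """
    g = model.graph
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("cascade model must be acyclic")
    state: dict[str, bool] = {}
    for node in nx.topological_sort(g):
        a = g.nodes[node]
        if a["clamped"]:
            state[node] = False
        elif a["degraded"]:
            state[node] = bool(a["resistant_drive"])
        else:
            parents = list(g.predecessors(node))
            upstream = bool(parents) and all(state[p] for p in parents)
            state[node] = bool(a["driven"]) or upstream
    return state


def evaluate_protection(model: CascadeModel) -> bool:
    """Protected outcome: K_ATP opens, or the insult itself is blocked."""
    state = evaluate_states(model)
    return state[PROTECTED_NODE] or not state[INSULT_NODE]


def predict_condition(condition: Condition,
                      model: CascadeModel | None = None) -> bool:
    base = model or build_default_model()
    return evaluate_protection(apply_condition(base, condition))


def predict_table(conditions: Sequence[Condition],
                  model: CascadeModel | None = None) -> pd.DataFrame:
    """Predict protected / not-protected for a list of conditions.

    When a condition carries an observed significance annotation, the
    report compares the prediction against it (significant reduction of
    the ID rate = protected).
    """
    base = model or build_default_model()
    rows = []
    for cond in conditions:
        pred = predict_condition(cond, base)
        obs = cond.observed_protected
        rows.append({
            "condition_id": cond.condition_id,
            "predicted": "protected" if pred else "not-protected",
            "observed_significance": cond.observed_significance,
            "observed_protected": obs,
            "match": (pred == obs) if obs is not None else None,
            "observed_pct_id": cond.observed_pct_id,
            "observed_sem": cond.observed_sem,
        })
    return pd.DataFrame(rows, columns=["condition_id", "predicted",
                                       "observed_significance",
                                       "observed_protected", "match",
                                       "observed_pct_id", "observed_sem"])


def condition_from_dict(d: Mapping) -> Condition:
    return Condition(
        condition_id=d["condition_id"],
        substrates=frozenset(d.get("substrates", ())),
        agonists=frozenset(d.get("agonists", ())),
        blockers=frozenset(d.get("blockers", ())),
        observed_significance=d.get("observed_significance"),
        observed_pct_id=d.get("observed_pct_id"),
        observed_sem=d.get("observed_sem"),
        n_cult=d.get("n_cult"),
        n_cell=d.get("n_cell"),
    )


def load_condition_panel(path=None) -> list[Condition]:
    """Load the packaged panel of 24 benchmark pharmacological conditions.

    The panel covers the Mg2+-free control and 23 intervention
    conditions, annotated with the observed ID-response rates and the
    significance of their reduction versus control.
    """
    if path is None:
        text = resources.files("phasetox.data").joinpath(
            "condition_panel.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return [condition_from_dict(d) for d in json.loads(text)]
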