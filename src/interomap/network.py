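"""Assembly and topology of the structurally resolved PPI network.

Accepted interolog candidates are merged into unordered protein-pair edges;
each edge keeps its supporting templates (best Z first) and the union of
template-mapped contacting residues on both proteins, sub-typed and flagged
for conservation. Degree-distribution exponents are fitted either by the
discrete power-law MLE or by a legacy log-log least-squares slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .scoring import CandidateInteraction

HUMAN_SPECIES_LABELS = frozenset({"human", "homo sapiens", "hsapiens", "9606"})


@dataclass
class ResidueContact:
    """Annotation of one contacting residue on one protein of an edge."""

    position: int
    kinds: set[str] = field(default_factory=set)
    conserved: bool = False


@dataclass
class SupportingTemplate:
    template_id: str
    z: float
    species: str
    human_template: bool


@dataclass
class InteractionEdge:
    """An unordered PPI edge with structural support.

    ``contacts_a``/``contacts_b`` map 1-based residue positions of
    ``protein_a``/``protein_b`` (lexicographically ordered ids) to their
    contact annotations, unioned over all supporting templates.
    """

    protein_a: str
    protein_b: str
    templates: list[SupportingTemplate] = field(default_factory=list)
    contacts_a: dict[int, ResidueContact] = field(default_factory=dict)
    contacts_b: dict[int, ResidueContact] = field(default_factory=dict)

    @property
    def best_z(self) -> float:
        return self.templates[0].z

    @property
    def human_template_any(self) -> bool:
        return any(t.human_template for t in self.templates)

    def contacts_of(self, protein_id: str) -> dict[int, ResidueContact]:
        if protein_id == self.protein_a:
            return self.contacts_a
        if protein_id == self.protein_b:
            return self.contacts_b
        raise KeyError(protein_id)


@dataclass
class Network:
    """A structurally resolved PPI network."""

    edges: list[InteractionEdge] = field(default_factory=list)
    isolated_nodes: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> list[str]:
        seen = set(self.isolated_nodes)
        for e in self.edges:
            seen.add(e.protein_a)
            seen.add(e.protein_b)
        return sorted(seen)

    def edge_index(self) -> dict[tuple[str, str], InteractionEdge]:
        return {(e.protein_a, e.protein_b): e for e in self.edges}

    def edges_of(self, protein_id: str) -> list[InteractionEdge]:
        return [e for e in self.edges if protein_id in (e.protein_a, e.protein_b)]

    def contact_positions(self, protein_id: str) -> dict[int, ResidueContact]:
        """Union contact annotation of one protein over all its edges."""
        merged: dict[int, ResidueContact] = {}
        for e in self.edges_of(protein_id):
            for pos, rc in e.contacts_of(protein_id).items():
                tgt = merged.setdefault(pos, ResidueContact(position=pos))
                tgt.kinds |= rc.kinds
                tgt.conserved = tgt.conserved or rc.conserved
        return merged

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.protein_a,
                e.protein_b,
                n_templates=len(e.templates),
                best_z=e.best_z,
                human_template_any=e.human_template_any,
            )
        return g


@dataclass
class DegreeExponent:
    gamma: float
    method: str
    xmin: int
    n_tail: int
    diagnostics: dict = field(default_factory=dict)


def _is_human(species: str) -> bool:
    return species.strip().lower() in HUMAN_SPECIES_LABELS


def assemble_network(
    interactions: Iterable[CandidateInteraction],
    template_species: dict[str, str] | None = None,
    allow_self: bool = False,
) -> Network:
    """Merge accepted candidates into a network of unordered edges.

    ``template_species`` maps template_id to the template's source taxon for
    the human/non-human flag; when absent the candidate's own species pair is
    not used (the template flag defaults to non-human). Duplicate pairs from
    different templates merge; supporting templates sort by descending Z.
    """
    template_species = template_species or {}
    by_pair: dict[tuple[str, str], InteractionEdge] = {}
    for cand in interactions:
        if not cand.accepted:
            continue
        a, b = sorted((cand.protein_a_id, cand.protein_b_id))
        if a == b and not allow_self:
            continue
        edge = by_pair.setdefault(pair_key := (a, b), InteractionEdge(a, b))
        species = template_species.get(cand.template_id, "unknown")
        edge.templates.append(
            SupportingTemplate(cand.template_id, cand.z, species, _is_human(species))
        )
        flipped = cand.protein_a_id != a  # candidate side A landed on protein_b
        for ac in cand.contacts:
            for side, pos, kind, cons in (
                ("a", ac.cand_pos_a, ac.kind, ac.pos_a in cand.conserved_a),
                ("b", ac.cand_pos_b, ac.kind, ac.pos_b in cand.conserved_b),
            ):
                if pos is None:
                    continue
                store = edge.contacts_b if (side == "a") == flipped else edge.contacts_a
                rc = store.setdefault(pos, ResidueContact(position=pos))
                rc.kinds.add(kind)
                rc.conserved = rc.conserved or cons
    edges = []
    for key in sorted(by_pair):
        edge = by_pair[key]
        edge.templates.sort(key=lambda t: (-t.z, t.template_id))
        # deduplicate identical template support from re-assembly
        seen: set[tuple[str, float]] = set()
        uniq = []
        for t in edge.templates:
            sig = (t.template_id, round(t.z, 12))
            if sig not in seen:
                seen.add(sig)
                uniq.append(t)
        edge.templates = uniq
        edges.append(edge)
    return Network(edges=edges)


def largest_component(network: Network) -> Network:
    """Induced sub-network on the largest connected component.

    Size ties break toward the component containing the lexicographically
    smallest protein id.
    """
    if not network.edges and not network.isolated_nodes:
        return Network()
    g = network.to_networkx()
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    keep = comps[0]
    return Network(
        edges=[e for e in network.edges if e.protein_a in keep],
        isolated_nodes={n for n in network.isolated_nodes if n in keep and len(keep) == 1},
    )


def degree_exponent(
    network_or_degrees: Network | Sequence[int],
    method: str = "mle",
    xmin: int = 1,
    include_self_loops: bool = False,
) -> DegreeExponent:
    """Fit the scale-free exponent gamma of the degree distribution.

    ``mle`` maximizes the exact discrete (Hurwitz-zeta) power-law
    likelihood over degrees >= xmin; ``mle_approx`` is the closed-form
    continuous-proxy estimator gamma = 1 + n / sum(ln(k_i / (xmin - 0.5))),
    which is materially biased at small xmin; ``loglog_ls`` negates the
    least-squares slope of log P(k) vs log k over the observed degrees (the
    legacy graphical method).
    """
    if isinstance(network_or_degrees, Network):
        g = network_or_degrees.to_networkx()
        if not include_self_loops:
            g.remove_edges_from(nx.selfloop_edges(g))
        degrees = [d for _, d in g.degree()]
    else:
        degrees = list(network_or_degrees)
    tail = np.array([k for k in degrees if k >= xmin], dtype=float)
    if tail.size < 10:
        raise ValueError("need at least 10 nodes with degree >= xmin")
    if np.all(tail == tail[0]):
        raise ValueError("degenerate degree distribution: all degrees equal")
    if method == "mle":
        from scipy.optimize import minimize_scalar
        from scipy.special import zeta

        sum_log = float(np.log(tail).sum())
        nll = lambda g: tail.size * np.log(zeta(g, xmin)) + g * sum_log
        opt = minimize_scalar(nll, bounds=(1.0001, 20.0), method="bounded")
        gamma = float(opt.x)
        se = (gamma - 1.0) / np.sqrt(tail.size)
        return DegreeExponent(
            gamma, "mle", xmin, int(tail.size),
            {"stderr": se, "nll": float(opt.fun)},
        )
    if method == "mle_approx":
        denom = float(np.log(tail / (xmin - 0.5)).sum())
        gamma = 1.0 + tail.size / denom
        se = (gamma - 1.0) / np.sqrt(tail.size)
        return DegreeExponent(gamma, "mle_approx", xmin, int(tail.size), {"stderr": se})
    if method == "loglog_ls":
        ks, counts = np.unique(tail, return_counts=True)
        pk = counts / counts.sum()
        slope, intercept = np.polyfit(np.log(ks), np.log(pk), 1)
        return DegreeExponent(
            -float(slope), "loglog_ls", xmin, int(tail.size), {"intercept": float(intercept)}
        )
    raise ValueError(f"unknown method {method!r}")


EDGE_TSV_COLUMNS = ["protein_a", "protein_b", "n_templates", "best_z", "human_template_any"]


def write_edge_tsv(network: Network, stream: IO[str] | str) -> None:
    rows = [
        {
            "protein_a": e.protein_a,
            "protein_b": e.protein_b,
            "n_templates": len(e.templates),
            "best_z": f"{e.best_z:.6f}",
            "human_template_any": int(e.human_template_any),
        }
        for e in network.edges
    ]
    pd.DataFrame(rows, columns=EDGE_TSV_COLUMNS).to_csv(stream, sep="\t", index=False)


def read_edge_tsv(stream: IO[str] | str) -> pd.DataFrame:
    return pd.read_csv(stream, sep="\t")


def write_graphml(network: Network, path: str) -> None:
    nx.write_graphml(network.to_networkx(), path)
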