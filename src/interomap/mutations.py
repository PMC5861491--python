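"""Placement of disease mutations relative to structural interfaces.

An in-frame (missense) mutation is classified by whether it falls in an
interacting domain (a Pfam/SCOP region containing at least one
template-mapped contacting residue of the protein), on a contacting residue,
and — within contacts — whether the contact forms a hydrogen bond and/or
sits in a conserved PPI-family column. Truncating mutations ('*') pass
through unclassified.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import pandas as pd

from .network import Network
from .structures import DomainRegion

_NOTATION = re.compile(r"^([A-Z])(\d+)([A-Z*])$")
_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class Mutation:
    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    label: str = ""
    category: str = "in_frame"  # or "truncating"
    origin: str = "germline"  # or "somatic"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.category == "in_frame" and self.wt_aa == self.mut_aa:
            raise ValueError("in-frame point mutation must change the residue")


@dataclass
class MutationClassification:
    mutation: Mutation
    in_interacting_domain: dict[str, bool] = field(default_factory=dict)
    in_noninteracting_domain: bool = False
    contacting: bool = False
    hbond_forming: bool = False
    conserved: bool = False
    neither: bool = False
    note: str = ""

    @property
    def rejected(self) -> bool:
        return self.note.startswith("rejected")


def parse_mutation(
    text: str, protein_id: str, label: str = "", origin: str = "germline"
) -> Mutation:
    """Parse short mutation notation like ``S252W`` or ``Q12*``."""
    m = _NOTATION.match(text.strip())
    if m is None:
        raise ValueError(f"malformed mutation notation: {text!r}")
    wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    if wt not in _AA or (mut != "*" and mut not in _AA):
        raise ValueError(f"malformed mutation notation: {text!r}")
    return Mutation(
        protein_id=protein_id,
        position=pos,
        wt_aa=wt,
        mut_aa=mut,
        label=label,
        category="truncating" if mut == "*" else "in_frame",
        origin=origin,
    )


def load_mutations(stream: IO[str] | str) -> list[Mutation]:
    """Read a mutation TSV: protein_id, notation, label, origin."""
    df = pd.read_csv(
        stream,
        sep="\t",
        header=None,
        names=["protein_id", "notation", "label", "origin"],
        comment="#",
        dtype=str,
    ).fillna("")
    return [
        parse_mutation(r.notation, r.protein_id, r.label, r.origin or "germline")
        for r in df.itertuples(index=False)
    ]


def interacting_domains(
    protein_id: str,
    network: Network,
    domain_regions: Sequence[DomainRegion],
) -> tuple[list[DomainRegion], list[DomainRegion]]:
    """Split a protein's domain regions into interacting / non-interacting.

    A region is *interacting* when it contains at least one template-mapped
    contacting residue of the protein on some edge.
    """
    regions = [r for r in domain_regions if r.protein_id == protein_id]
    contact_positions = set(network.contact_positions(protein_id))
    inter, non = [], []
    for r in regions:
        if any(p in r for p in contact_positions):
            inter.append(r)
        else:
            non.append(r)
    return inter, non


def classify_mutation(
    mutation: Mutation,
    network: Network,
    domain_regions: Sequence[DomainRegion] = (),
    sequences: dict[str, str] | None = None,
    wt_check: bool = False,
    hbond_includes_electrostatic: bool = True,
) -> MutationClassification:
    """Classify one mutation's placement relative to the interface.

    Electrostatic contacts group with the hydrogen-bond class by default,
    mirroring the merged hydrogen-bond/electrostatic energy term.
    """
    cls = MutationClassification(mutation=mutation)
    if mutation.category == "truncating":
        cls.note = "truncating"
        return cls
    pid, pos = mutation.protein_id, mutation.position
    if sequences and pid in sequences:
        seq = sequences[pid]
        if pos > len(seq):
            cls.note = "rejected: position beyond sequence length"
            return cls
        if wt_check and seq[pos - 1] != mutation.wt_aa:
            cls.note = (
                f"rejected: wild-type mismatch ({mutation.wt_aa} vs {seq[pos - 1]})"
            )
            return cls
    if pid not in set(network.nodes):
        cls.note = "unmapped"
        return cls

    contacts = network.contact_positions(pid)
    cls.contacting = pos in contacts
    if cls.contacting:
        rc = contacts[pos]
        hb_kinds = {"hbond", "electrostatic"} if hbond_includes_electrostatic else {"hbond"}
        cls.hbond_forming = bool(rc.kinds & hb_kinds)
        cls.conserved = rc.conserved
        cls.neither = not cls.hbond_forming and not cls.conserved

    inter, non = interacting_domains(pid, network, domain_regions)
    for db in ("Pfam", "SCOP"):
        cls.in_interacting_domain[db] = any(pos in r for r in inter if r.domain_db == db)
    in_any_inter = any(cls.in_interacting_domain.values())
    cls.in_noninteracting_domain = (not in_any_inter) and any(pos in r for r in non)
    return cls


def classification_table(classifications: Iterable[MutationClassification]) -> pd.DataFrame:
    """Flatten classifications into one row per mutation for enrichment."""
    rows = []
    for c in classifications:
        m = c.mutation
        rows.append(
            {
                "protein_id": m.protein_id,
                "notation": f"{m.wt_aa}{m.position}{m.mut_aa}",
                "label": m.label,
                "origin": m.origin,
                "category": m.category,
                "in_interacting_domain_Pfam": int(c.in_interacting_domain.get("Pfam", False)),
                "in_interacting_domain_SCOP": int(c.in_interacting_domain.get("SCOP", False)),
                "in_noninteracting_domain": int(c.in_noninteracting_domain),
                "contacting": int(c.contacting),
                "hbond_forming": int(c.hbond_forming),
                "conserved": int(c.conserved),
                "neither": int(c.neither),
                "note": c.note,
            }
        )
    return pd.DataFrame(rows)
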