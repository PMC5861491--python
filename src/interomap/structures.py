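"""Dimer structural templates: PDB parsing, interface contacts, domain regions.

A template is a two-chain complex whose inter-chain residue contacts define
the binding interface that interolog mapping transfers onto homologous pairs.
Contacts are detected from heavy-atom distances and sub-typed as
hydrogen-bond, electrostatic, or van der Waals; the distance definitions are
conventional (the originating method publishes only the contact classes, not
the cutoffs) and are exposed as parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: default closest heavy-atom distance defining an inter-chain contact (A)
DEFAULT_CONTACT_CUTOFF = 4.5
#: default donor-acceptor heavy-atom distance for a hydrogen bond (A)
DEFAULT_HBOND_CUTOFF = 3.5

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}
_WATER = {"HOH", "WAT", "DOD"}

# Heavy-atom donor/acceptor sets (backbone N donor, backbone O/OXT acceptor).
# No angle criterion: template coordinates generally lack hydrogens.
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "TRP": {"NE1"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
_CHARGED_ATOMS = {
    "ASP": ({"OD1", "OD2"}, -1),
    "GLU": ({"OE1", "OE2"}, -1),
    "LYS": ({"NZ"}, +1),
    "ARG": ({"NE", "NH1", "NH2"}, +1),
}

CONTACT_KINDS = ("hbond", "electrostatic", "vdw")


@dataclass
class Residue:
    """One observed residue of a template chain.

    ``seq_index`` is the 1-based position in the chain's gap-free observed
    sequence; the PDB author number is kept only as reporting metadata.
    """

    chain_id: str
    seq_index: int
    aa: str
    atoms: list[tuple[str, str, float, float, float]]
    resname: str = "UNK"
    author_number: str = ""

    def __post_init__(self) -> None:
        if self.seq_index < 1:
            raise ValueError("seq_index must be >= 1")
        if not self.atoms:
            raise ValueError("residue must carry at least one atom")

    def heavy_atoms(self) -> list[tuple[str, str, float, float, float]]:
        return [a for a in self.atoms if a[1].upper() != "H"]

    def coords(self, names: Iterable[str] | None = None) -> np.ndarray:
        sel = self.heavy_atoms()
        if names is not None:
            names = set(names)
            sel = [a for a in sel if a[0] in names]
        return np.array([a[2:5] for a in sel], dtype=float).reshape(-1, 3)


@dataclass
class Contact:
    """An inter-chain residue contact, sub-typed by interaction class."""

    pos_a: int
    pos_b: int
    kind: str
    min_dist: float

    def __post_init__(self) -> None:
        if self.kind not in CONTACT_KINDS:
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.min_dist <= 0:
            raise ValueError("min_dist must be positive")


@dataclass
class TemplateComplex:
    """A two-chain dimer template with derived sequences and contacts."""

    template_id: str
    species: str
    chain_a: list[Residue]
    chain_b: list[Residue]
    contacts: list[Contact] = field(default_factory=list)

    @property
    def seq_a(self) -> str:
        return "".join(r.aa for r in self.chain_a)

    @property
    def seq_b(self) -> str:
        return "".join(r.aa for r in self.chain_b)


@dataclass
class DomainRegion:
    """A Pfam/SCOP domain assignment on a protein (1-based inclusive)."""

    protein_id: str
    domain_db: str
    domain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("require 1 <= start <= end")
        if self.domain_db not in ("Pfam", "SCOP"):
            raise ValueError(f"unknown domain_db {self.domain_db!r}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


def _chain_residues(chain) -> list[Residue]:
    out: list[Residue] = []
    for res in chain:
        hetfield = res.id[0]
        if hetfield != " " or res.resname.strip() in _WATER:
            continue
        aa = _THREE_TO_ONE.get(res.resname.strip().upper(), "X")
        atoms = []
        for atom in res:  # disordered atoms yield highest-occupancy altloc
            x, y, z = (float(c) for c in atom.coord)
            atoms.append((atom.get_name(), (atom.element or "?").upper(), x, y, z))
        if not atoms:
            continue
        out.append(
            Residue(
                chain_id=chain.id,
                seq_index=len(out) + 1,
                aa=aa,
                atoms=atoms,
                resname=res.resname.strip().upper(),
                author_number=f"{res.id[1]}{res.id[2].strip()}",
            )
        )
    return out


def parse_structure(
    stream: IO[str] | str,
    chain_pair: Sequence[str],
    template_id: str = "template",
    species: str = "unknown",
) -> TemplateComplex:
    """Parse a two-chain template from PDB-format text.

    Residues are ordered as encountered; the first model is used; HETATM
    records and waters are ignored; alternate locations resolve to the
    highest-occupancy conformer; non-standard residues become 'X'.
    """
    if len(chain_pair) != 2:
        raise ValueError("chain_pair must name exactly two chains")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(template_id, stream)
    model = next(iter(structure), None)
    if model is None:
        raise ValueError("no model in PDB input")
    chains = {c.id: c for c in model}
    residues = []
    for cid in chain_pair:
        if cid not in chains:
            raise ValueError(f"chain not found: {cid!r}")
        res = _chain_residues(chains[cid])
        if not res:
            raise ValueError(f"chain {cid!r} has zero standard residues")
        residues.append(res)
    return TemplateComplex(
        template_id=template_id,
        species=species,
        chain_a=residues[0],
        chain_b=residues[1],
    )


def _is_hbond_pair(res_a: Residue, res_b: Residue, cutoff: float) -> bool:
    for donor_res, acc_res in ((res_a, res_b), (res_b, res_a)):
        donors = {"N"} | _SIDECHAIN_DONORS.get(donor_res.resname, set())
        acceptors = {"O", "OXT"} | _SIDECHAIN_ACCEPTORS.get(acc_res.resname, set())
        dc = donor_res.coords(donors)
        ac = acc_res.coords(acceptors)
        if dc.size and ac.size and cdist(dc, ac).min() <= cutoff:
            return True
    return False


def _is_salt_pair(res_a: Residue, res_b: Residue, cutoff: float) -> bool:
    ca = _CHARGED_ATOMS.get(res_a.resname)
    cb = _CHARGED_ATOMS.get(res_b.resname)
    if ca is None or cb is None or ca[1] * cb[1] >= 0:
        return False
    xa = res_a.coords(ca[0])
    xb = res_b.coords(cb[0])
    return bool(xa.size and xb.size and cdist(xa, xb).min() <= cutoff)


def extract_contacts(
    complex: TemplateComplex,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
) -> list[Contact]:
    """Detect inter-chain residue contacts and classify their type.

    A contact is any residue pair with closest heavy-atom distance within
    ``contact_cutoff``; it is *hbond* when a donor-acceptor heavy-atom pair
    lies within ``hbond_cutoff``, else *electrostatic* for oppositely charged
    residues with charged atoms within ``hbond_cutoff``, else *vdw*.
    'X' residues (non-standard) never form contacts.
    """
    if not complex.chain_a or not complex.chain_b:
        raise ValueError("both chains must be non-empty")
    if not 0 < hbond_cutoff <= contact_cutoff:
        raise ValueError("require 0 < hbond_cutoff <= contact_cutoff")
    contacts: list[Contact] = []
    coords_b = [r.coords() for r in complex.chain_b]
    for ra in complex.chain_a:
        if ra.aa == "X":
            continue
        xa = ra.coords()
        if not xa.size:
            continue
        for rb, xb in zip(complex.chain_b, coords_b):
            if rb.aa == "X" or not xb.size:
                continue
            d = float(cdist(xa, xb).min())
            if d > contact_cutoff:
                continue
            if _is_hbond_pair(ra, rb, hbond_cutoff):
                kind = "hbond"
            elif _is_salt_pair(ra, rb, hbond_cutoff):
                kind = "electrostatic"
            else:
                kind = "vdw"
            contacts.append(Contact(ra.seq_index, rb.seq_index, kind, d))
    contacts.sort(key=lambda c: (c.pos_a, c.pos_b))
    return contacts


def load_domain_regions(stream: IO[str] | str) -> list[DomainRegion]:
    """Load 5-column domain TSV (protein_id, domain_db, domain_id, start, end).

    Rows with start > end are rejected with a warning; overlapping or
    adjacent regions of the same (protein, db, accession) are merged.
    """
    df = pd.read_csv(
        stream,
        sep="\t",
        header=None,
        names=["protein_id", "domain_db", "domain_id", "start", "end"],
        comment="#",
        dtype=str,
    )
    regions: list[DomainRegion] = []
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            logger.warning("rejecting domain row with non-integer span: %s", row)
            continue
        if row.domain_db not in ("Pfam", "SCOP"):
            raise ValueError(f"unknown domain_db {row.domain_db!r}")
        if start > end:
            logger.warning("rejecting domain row with start > end: %s", row)
            continue
        regions.append(DomainRegion(row.protein_id, row.domain_db, row.domain_id, start, end))

    merged: dict[tuple[str, str, str], list[list[int]]] = {}
    for r in sorted(regions, key=lambda r: (r.protein_id, r.domain_db, r.domain_id, r.start)):
        key = (r.protein_id, r.domain_db, r.domain_id)
        spans = merged.setdefault(key, [])
        if spans and r.start <= spans[-1][1] + 1:
            spans[-1][1] = max(spans[-1][1], r.end)
        else:
            spans.append([r.start, r.end])
    out = [
        DomainRegion(pid, db, did, s, e)
        for (pid, db, did), spans in sorted(merged.items())
        for s, e in spans
    ]
    # distinct accessions of one db should not overlap on one protein; warn only
    by_pdb: dict[tuple[str, str], list[DomainRegion]] = {}
    for r in out:
        by_pdb.setdefault((r.protein_id, r.domain_db), []).append(r)
    for (pid, db), rs in by_pdb.items():
        rs = sorted(rs, key=lambda r: r.start)
        for r1, r2 in zip(rs, rs[1:]):
            if r2.start <= r1.end and r1.domain_id != r2.domain_id:
                logger.warning(
                    "overlapping %s regions %s/%s on %s kept unmerged",
                    db, r1.domain_id, r2.domain_id, pid,
                )
    return out
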