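"""Interface scoring of interolog candidates against a structural template.

Every cross-pair of the two homolog families is scored with

    E_tot = E_vdw + E_SF + E_sim + E_cons

where E_vdw and E_SF are residue-pair contact potentials evaluated on the
candidate residues aligned onto the template's van der Waals and
hydrogen-bond/electrostatic contacts, E_sim is the substitution similarity of
candidate vs template residues over the aligned contact positions of both
sides (gap-penalized), and E_cons is a couple-conservation bonus counting
contacts whose two candidate residues conform to conserved columns of the
family alignments. A candidate is accepted as a PPI when its E_tot stands at
Z >= z_min (default 3.0) above a background of randomly drawn database
sequence pairs scored through the identical path.

The original method's calibrated energy functions are not published in full;
the tables shipped here are a documented knowledge-based surrogate and are
fully swappable (see :class:`PotentialTable`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .homology import HomologFamily, SequenceDB, _make_aligner
from .structures import Contact, TemplateComplex

logger = logging.getLogger(__name__)

DEFAULT_Z_MIN = 3.0


@dataclass
class ScoringConfig:
    """Tunable parameters of candidate scoring and acceptance."""

    z_min: float = DEFAULT_Z_MIN
    n_bg: int = 200
    seed: int = 0
    c_min: float = 0.7
    w_cons: float = 1.0
    gap_penalty: float = -4.0
    matrix_name: str = "BLOSUM62"
    open_gap: int = 11
    extend_gap: int = 1


def _read_potential_file(text: str) -> dict[tuple[str, str], float]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    table: dict[tuple[str, str], float] = {}
    for line in lines[1:]:
        parts = line.split()
        row = parts[0]
        for col, val in zip(header, parts[1:]):
            table[(row, col)] = float(val)
    for (a, b), v in table.items():
        if abs(table[(b, a)] - v) > 1e-9:
            raise ValueError(f"potential table not symmetric at ({a},{b})")
    return table


@dataclass
class PotentialTable:
    """Residue-pair score tables for E_vdw / E_SF and the E_sim similarity."""

    vdw: dict[tuple[str, str], float]
    sf: dict[tuple[str, str], float]
    sim: dict[tuple[str, str], float]

    @classmethod
    def default(cls, matrix_name: str = "BLOSUM62") -> "PotentialTable":
        pkg = resources.files("interomap.data")
        vdw = _read_potential_file((pkg / "vdw_potential.tsv").read_text())
        sf = _read_potential_file((pkg / "sf_potential.tsv").read_text())
        mat = substitution_matrices.load(matrix_name)
        sim = {
            (a, b): float(mat[a, b])
            for a in mat.alphabet
            for b in mat.alphabet
            if a.isalpha() and b.isalpha()
        }
        return cls(vdw=vdw, sf=sf, sim=sim)

    def vdw_score(self, a: str, b: str) -> float:
        return self.vdw.get((a, b), 0.0)

    def sf_score(self, a: str, b: str) -> float:
        return self.sf.get((a, b), 0.0)

    def sim_score(self, a: str, b: str) -> float:
        return self.sim.get((a, b), 0.0)


@dataclass
class TemplateAlignment:
    """Global alignment of a candidate sequence onto a template chain."""

    template_row: str
    candidate_row: str
    score: float
    template_seq: str
    candidate_seq: str

    def __post_init__(self) -> None:
        if len(self.template_row) != len(self.candidate_row):
            raise ValueError("alignment rows must have equal length")

    def mapping(self) -> dict[int, int | None]:
        """1-based template position -> 1-based candidate position (None = gap)."""
        out: dict[int, int | None] = {}
        tpos = cpos = 0
        for t, c in zip(self.template_row, self.candidate_row):
            if c != "-":
                cpos += 1
            if t != "-":
                tpos += 1
                out[tpos] = cpos if c != "-" else None
        return out

    def projected_row(self) -> str:
        """Candidate residues at template columns (insertions dropped)."""
        return "".join(
            c for t, c in zip(self.template_row, self.candidate_row) if t != "-"
        )


def align_to_template(
    candidate: str,
    template_chain: str,
    matrix_name: str = "BLOSUM62",
    open_gap: int = 11,
    extend_gap: int = 1,
) -> TemplateAlignment:
    """Global affine-gap alignment of a candidate onto a template chain.

    The first optimal alignment in the aligner's deterministic enumeration
    order is used, so equal-score ties resolve identically across runs.
    """
    if not candidate or not template_chain:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(matrix_name, open_gap, extend_gap, "global")
    best = aligner.align(template_chain, candidate)[0]
    blocks_t, blocks_c = best.aligned
    trow: list[str] = []
    crow: list[str] = []
    prev_t = prev_c = 0
    for (ts, te), (cs, ce) in zip(blocks_t, blocks_c):
        trow += [template_chain[prev_t:ts], "-" * (cs - prev_c), template_chain[ts:te]]
        crow += ["-" * (ts - prev_t), candidate[prev_c:cs], candidate[cs:ce]]
        prev_t, prev_c = te, ce
    trow += [template_chain[prev_t:], "-" * (len(candidate) - prev_c)]
    crow += ["-" * (len(template_chain) - prev_t), candidate[prev_c:]]
    return TemplateAlignment(
        template_row="".join(trow),
        candidate_row="".join(crow),
        score=float(best.score),
        template_seq=template_chain,
        candidate_seq=candidate,
    )


@dataclass
class AlignedContact:
    """A template contact carried through both candidate alignments."""

    pos_a: int
    pos_b: int
    kind: str
    template_aa_a: str
    template_aa_b: str
    cand_aa_a: str | None
    cand_aa_b: str | None
    cand_pos_a: int | None
    cand_pos_b: int | None

    @property
    def gapped(self) -> bool:
        return self.cand_pos_a is None or self.cand_pos_b is None


def map_template_contacts(
    align_a: TemplateAlignment,
    align_b: TemplateAlignment,
    contacts: Sequence[Contact],
) -> list[AlignedContact]:
    """Map each template contact through both pairwise alignments."""
    map_a, map_b = align_a.mapping(), align_b.mapping()
    out: list[AlignedContact] = []
    for c in contacts:
        if c.pos_a not in map_a or c.pos_b not in map_b:
            raise ValueError(
                f"contact ({c.pos_a},{c.pos_b}) outside template sequence: "
                "template library inconsistency"
            )
        pa, pb = map_a[c.pos_a], map_b[c.pos_b]
        out.append(
            AlignedContact(
                pos_a=c.pos_a,
                pos_b=c.pos_b,
                kind=c.kind,
                template_aa_a=align_a.template_seq[c.pos_a - 1],
                template_aa_b=align_b.template_seq[c.pos_b - 1],
                cand_aa_a=align_a.candidate_seq[pa - 1] if pa else None,
                cand_aa_b=align_b.candidate_seq[pb - 1] if pb else None,
                cand_pos_a=pa,
                cand_pos_b=pb,
            )
        )
    return out


@dataclass
class ScoreBreakdown:
    """The four energy terms and their exact sum."""

    e_vdw: float
    e_sf: float
    e_sim: float
    e_cons: float
    e_tot: float = field(init=False)

    def __post_init__(self) -> None:
        self.e_tot = self.e_vdw + self.e_sf + self.e_sim + self.e_cons


def score_candidate(
    aligned_contacts: Sequence[AlignedContact],
    conserved_a: set[int],
    conserved_b: set[int],
    potentials: PotentialTable,
    gap_penalty: float = -4.0,
    w_cons: float = 1.0,
) -> ScoreBreakdown:
    """Score one candidate pair's aligned contacts.

    A contact gapped on either side contributes only ``gap_penalty`` to
    E_sim. E_cons rewards contacts whose template columns are conserved on
    both sides *and* whose candidate residues conform to the template
    (couple-conserved contacts). Unknown residues ('X') score 0 everywhere.
    """
    e_vdw = e_sf = e_sim = 0.0
    n_cons = 0
    for ac in aligned_contacts:
        if ac.gapped:
            e_sim += gap_penalty
            continue
        aa, ab = ac.cand_aa_a, ac.cand_aa_b
        if ac.kind == "vdw":
            e_vdw += potentials.vdw_score(aa, ab)
        else:  # hbond or electrostatic
            e_sf += potentials.sf_score(aa, ab)
        e_sim += potentials.sim_score(ac.template_aa_a, aa)
        e_sim += potentials.sim_score(ac.template_aa_b, ab)
        if (
            ac.pos_a in conserved_a
            and ac.pos_b in conserved_b
            and aa == ac.template_aa_a
            and ab == ac.template_aa_b
        ):
            n_cons += 1
    return ScoreBreakdown(e_vdw=e_vdw, e_sf=e_sf, e_sim=e_sim, e_cons=w_cons * n_cons)


def zscore(candidate_score: float, background: Sequence[float]) -> float:
    """Standardized score against a background sample (sd with n-1)."""
    bg = np.asarray(background, dtype=float)
    if bg.size < 30:
        raise ValueError("background must contain at least 30 scores")
    sd = float(bg.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate background: zero standard deviation")
    return (candidate_score - float(bg.mean())) / sd


def column_conservation(msa: Sequence[str], template_row: int = 0) -> np.ndarray:
    """Per-column fraction of non-gap non-template rows matching the template.

    Columns with no informative rows (single-row alignment, or all non-template
    rows gapped) get fraction 0.0, i.e. not conserved.
    """
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[template_row])
    if any(len(row) != width for row in msa):
        raise ValueError("alignment rows must have equal length")
    fractions = np.zeros(width)
    others = [row for i, row in enumerate(msa) if i != template_row]
    for j in range(width):
        t = msa[template_row][j]
        col = [row[j] for row in others if row[j] != "-"]
        if col and t != "-":
            fractions[j] = sum(1 for c in col if c == t) / len(col)
    return fractions


@dataclass
class CandidateInteraction:
    """A scored homolog cross-pair for one template."""

    template_id: str
    protein_a_id: str
    protein_b_id: str
    species_a: str
    species_b: str
    breakdown: ScoreBreakdown
    z: float
    accepted: bool
    contacts: list[AlignedContact] = field(default_factory=list)
    conserved_a: set[int] = field(default_factory=set)
    conserved_b: set[int] = field(default_factory=set)


@dataclass
class PPIFamily:
    """Accepted interologs of one template with template-anchored MSAs."""

    template_id: str
    accepted: list[CandidateInteraction]
    msa_a: list[str]
    msa_b: list[str]
    row_ids_a: list[str]
    row_ids_b: list[str]
    conservation_a: np.ndarray
    conservation_b: np.ndarray
    conserved_a: set[int]
    conserved_b: set[int]


def _family_context(
    family: HomologFamily,
    template_seq: str,
    db: SequenceDB,
    config: ScoringConfig,
) -> tuple[dict[str, TemplateAlignment], list[str], list[str]]:
    alignments: dict[str, TemplateAlignment] = {}
    rows = [template_seq]
    ids = ["<template>"]
    for hit in family.members:
        sid = hit.subject_id
        if sid in alignments:
            continue
        aln = align_to_template(
            db.sequence(sid), template_seq,
            config.matrix_name, config.open_gap, config.extend_gap,
        )
        alignments[sid] = aln
        rows.append(aln.projected_row())
        ids.append(sid)
    return alignments, rows, ids


def infer_family_ppis(
    template: TemplateComplex,
    family_a: HomologFamily,
    family_b: HomologFamily,
    db: SequenceDB,
    config: ScoringConfig | None = None,
    potentials: PotentialTable | None = None,
) -> tuple[list[CandidateInteraction], PPIFamily | None]:
    """Score all family-A' x family-B' cross-pairs and accept at Z >= z_min.

    The Z background is ``config.n_bg`` sequence pairs drawn uniformly at
    random (seeded) from the whole database and pushed through the identical
    align-map-score path. Conservation context comes from the family-wide
    template-anchored alignments; the returned family restricts the MSAs to
    proteins participating in accepted pairs.
    """
    config = config or ScoringConfig()
    potentials = potentials or PotentialTable.default(config.matrix_name)
    if not family_a.members or not family_b.members:
        logger.info(
            "template %s: empty homolog family (%d x %d), no candidates",
            template.template_id, len(family_a), len(family_b),
        )
        return [], None

    aligns_a, msa_a, ids_a = _family_context(family_a, template.seq_a, db, config)
    aligns_b, msa_b, ids_b = _family_context(family_b, template.seq_b, db, config)
    cons_frac_a = column_conservation(msa_a)
    cons_frac_b = column_conservation(msa_b)
    conserved_a = {i + 1 for i, f in enumerate(cons_frac_a) if f >= config.c_min}
    conserved_b = {i + 1 for i, f in enumerate(cons_frac_b) if f >= config.c_min}

    def score_pair(aln_a: TemplateAlignment, aln_b: TemplateAlignment):
        mapped = map_template_contacts(aln_a, aln_b, template.contacts)
        bd = score_candidate(
            mapped, conserved_a, conserved_b, potentials,
            gap_penalty=config.gap_penalty, w_cons=config.w_cons,
        )
        return mapped, bd

    # background: random DB pairs through the same scoring path
    rng = np.random.default_rng(config.seed)
    bg_align_a: dict[str, TemplateAlignment] = dict(aligns_a)
    bg_align_b: dict[str, TemplateAlignment] = dict(aligns_b)
    bg_scores: list[float] = []
    ids = [pid for pid, _, _ in db.records]
    for _ in range(config.n_bg):
        pa = ids[int(rng.integers(len(ids)))]
        pb = ids[int(rng.integers(len(ids)))]
        if pa not in bg_align_a:
            bg_align_a[pa] = align_to_template(
                db.sequence(pa), template.seq_a,
                config.matrix_name, config.open_gap, config.extend_gap,
            )
        if pb not in bg_align_b:
            bg_align_b[pb] = align_to_template(
                db.sequence(pb), template.seq_b,
                config.matrix_name, config.open_gap, config.extend_gap,
            )
        _, bd = score_pair(bg_align_a[pa], bg_align_b[pb])
        bg_scores.append(bd.e_tot)

    candidates: list[CandidateInteraction] = []
    for sa in family_a.subject_ids():
        for sb in family_b.subject_ids():
            mapped, bd = score_pair(aligns_a[sa], aligns_b[sb])
            z = zscore(bd.e_tot, bg_scores)
            candidates.append(
                CandidateInteraction(
                    template_id=template.template_id,
                    protein_a_id=sa,
                    protein_b_id=sb,
                    species_a=db.species(sa),
                    species_b=db.species(sb),
                    breakdown=bd,
                    z=z,
                    accepted=z >= config.z_min,
                    contacts=mapped,
                    conserved_a=conserved_a,
                    conserved_b=conserved_b,
                )
            )

    accepted = [c for c in candidates if c.accepted]
    keep_a = {c.protein_a_id for c in accepted}
    keep_b = {c.protein_b_id for c in accepted}
    fam = PPIFamily(
        template_id=template.template_id,
        accepted=accepted,
        msa_a=[msa_a[0]] + [r for r, i in zip(msa_a[1:], ids_a[1:]) if i in keep_a],
        msa_b=[msa_b[0]] + [r for r, i in zip(msa_b[1:], ids_b[1:]) if i in keep_b],
        row_ids_a=["<template>"] + [i for i in ids_a[1:] if i in keep_a],
        row_ids_b=["<template>"] + [i for i in ids_b[1:] if i in keep_b],
        conservation_a=cons_frac_a,
        conservation_b=cons_frac_b,
        conserved_a=conserved_a,
        conserved_b=conserved_b,
    )
    return candidates, fam
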