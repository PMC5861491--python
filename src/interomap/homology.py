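"""Homolog families of template chains from a sequence database.

The primary ingest path is standard 12-column BLAST tabular output; a
self-contained Smith-Waterman search with Karlin-Altschul E-values is
provided so the pipeline runs without an external aligner. E-values from the
internal search use published *ungapped* (lambda, K) parameters and are
therefore approximate relative to gapped BLASTP statistics; the family
threshold (E <= 1e-10, inclusive) is the same either way.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_MAX = 1e-10

# Ungapped Karlin-Altschul parameters (lambda, K) per substitution matrix.
KARLIN_ALTSCHUL: dict[str, tuple[float, float]] = {
    "BLOSUM62": (0.3176, 0.134),
    "BLOSUM80": (0.3430, 0.177),
    "BLOSUM45": (0.2291, 0.0924),
    "PAM250": (0.2252, 0.0868),
}


@dataclass
class SequenceDB:
    """An in-memory protein sequence database with species tags."""

    records: list[tuple[str, str, str]]  # (protein_id, species, sequence)
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for i, (pid, _species, seq) in enumerate(self.records):
            if pid in self._index:
                raise ValueError(f"duplicate protein id {pid!r}")
            if not seq:
                raise ValueError(f"empty sequence for {pid!r}")
            self._index[pid] = i

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def sequence(self, protein_id: str) -> str:
        return self.records[self._index[protein_id]][2]

    def species(self, protein_id: str) -> str:
        return self.records[self._index[protein_id]][1]

    @property
    def total_residues(self) -> int:
        return sum(len(seq) for _, _, seq in self.records)


def read_fasta(stream: IO[str] | str, species_field: int = 1) -> SequenceDB:
    """Read a FASTA database; species taken from a '|'-delimited header field.

    ``species_field`` is the 0-based index into the '|'-split header id
    (default 1, i.e. the second field); absent field -> "unknown".
    """
    if isinstance(stream, str) and "\n" in stream:
        stream = io.StringIO(stream)
    records = []
    for rec in SeqIO.parse(stream, "fasta"):
        parts = rec.id.split("|")
        pid = parts[0]
        species = parts[species_field] if len(parts) > species_field else "unknown"
        records.append((pid, species, str(rec.seq).upper()))
    return SequenceDB(records)


@dataclass
class HomologHit:
    """One local-alignment hit of a template chain against a DB sequence."""

    query_chain: str  # e.g. "1abc_AB:A"
    subject_id: str
    evalue: float
    bitscore: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    alignment: tuple[str, str] | None = None  # gapped (query, subject)

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")
        if self.alignment is not None and len(self.alignment[0]) != len(self.alignment[1]):
            raise ValueError("aligned strings must have equal length")


@dataclass
class HomologFamily:
    """Hits of one template chain passing the E-value threshold."""

    template_id: str
    chain_role: str  # "A" or "B"
    members: list[HomologHit]

    def subject_ids(self) -> list[str]:
        return [h.subject_id for h in self.members]

    def __len__(self) -> int:
        return len(self.members)


def read_blast_tabular(stream: IO[str] | str, query_chain: str | None = None) -> list[HomologHit]:
    """Parse standard 12-column BLAST tabular (outfmt 6) text into hits.

    Alignment strings are not present in tabular output; they are
    reconstructed downstream by aligning against the database on demand.
    Rows with malformed numeric fields are rejected with a warning.
    """
    if isinstance(stream, str) and ("\n" in stream or "\t" in stream or not stream):
        stream = io.StringIO(stream)
    elif isinstance(stream, str):
        stream = open(stream)
    hits: list[HomologHit] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ValueError(f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}")
        q, s = fields[0], fields[1]
        try:
            qstart, qend, sstart, send = (int(x) for x in fields[6:10])
            evalue = float(fields[10])
            bitscore = float(fields[11])
            hit = HomologHit(
                query_chain=query_chain or q,
                subject_id=s,
                evalue=max(evalue, 1e-300),  # tabular rounds tiny E-values to 0
                bitscore=bitscore,
                q_start=qstart,
                q_end=qend,
                s_start=sstart,
                s_end=send,
            )
        except (ValueError, TypeError) as exc:
            if "columns" in str(exc):
                raise
            logger.warning("rejecting malformed tabular row %d: %s", lineno, line)
            continue
        hits.append(hit)
    return hits


def _make_aligner(matrix_name: str, open_gap: int, extend_gap: int, mode: str) -> PairwiseAligner:
    try:
        matrix = substitution_matrices.load(matrix_name)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix_name!r}") from exc
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix
    # BLAST convention: a gap of length g costs open + g*extend
    aligner.open_gap_score = -(open_gap + extend_gap)
    aligner.extend_gap_score = -extend_gap
    return aligner


def _gapped_strings(alignment, query: str, subject: str) -> tuple[str, str, int, int, int, int]:
    blocks_q, blocks_s = alignment.aligned
    qa: list[str] = []
    sa: list[str] = []
    prev_q, prev_s = blocks_q[0][0], blocks_s[0][0]
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        qa.append(query[prev_q:qs])
        sa.append("-" * (qs - prev_q))
        qa.append("-" * (ss - prev_s))
        sa.append(subject[prev_s:ss])
        qa.append(query[qs:qe])
        sa.append(subject[ss:se])
        prev_q, prev_s = qe, se
    return (
        "".join(qa),
        "".join(sa),
        int(blocks_q[0][0]) + 1,
        int(blocks_q[-1][1]),
        int(blocks_s[0][0]) + 1,
        int(blocks_s[-1][1]),
    )


def search_homologs(
    query: str,
    db: SequenceDB,
    open_gap: int = 11,
    extend_gap: int = 1,
    matrix_name: str = "BLOSUM62",
    query_chain: str = "query",
) -> list[HomologHit]:
    """Smith-Waterman search of ``query`` against every DB sequence.

    E = K * m * n * exp(-lambda * S) with ungapped matrix-specific (lambda, K),
    m the query length and n the total residue count of the database. Hits are
    sorted by ascending E-value, ties broken by subject id.
    """
    if not query:
        raise ValueError("query must be non-empty")
    if matrix_name not in KARLIN_ALTSCHUL:
        raise ValueError(f"no Karlin-Altschul parameters for matrix {matrix_name!r}")
    lam, k = KARLIN_ALTSCHUL[matrix_name]
    aligner = _make_aligner(matrix_name, open_gap, extend_gap, "local")
    m, n = len(query), db.total_residues
    hits: list[HomologHit] = []
    for pid, _species, seq in db.records:
        alignments = aligner.align(query, seq)
        if len(alignments) == 0:
            continue
        best = alignments[0]
        score = float(best.score)
        if score <= 0:
            continue
        evalue = k * m * n * math.exp(-lam * score)
        qa, sa, qs, qe, ss, se = _gapped_strings(best, query, seq)
        bitscore = (lam * score - math.log(k)) / math.log(2)
        hits.append(
            HomologHit(
                query_chain=query_chain,
                subject_id=pid,
                evalue=max(evalue, 1e-300),
                bitscore=bitscore,
                q_start=qs,
                q_end=qe,
                s_start=ss,
                s_end=se,
                alignment=(qa, sa),
            )
        )
    hits.sort(key=lambda h: (h.evalue, h.subject_id))
    return hits


def build_family(
    template_id: str,
    chain_role: str,
    hits: Iterable[HomologHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> HomologFamily:
    """Keep hits with E <= ``evalue_max`` (inclusive), best hit per subject."""
    best: dict[str, HomologHit] = {}
    for hit in hits:
        if hit.evalue > evalue_max:
            continue
        prev = best.get(hit.subject_id)
        if prev is None or hit.evalue < prev.evalue:
            best[hit.subject_id] = hit
    members = sorted(best.values(), key=lambda h: (h.evalue, h.subject_id))
    return HomologFamily(template_id=template_id, chain_role=chain_role, members=members)
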