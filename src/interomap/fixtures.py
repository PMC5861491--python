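"""Synthetic inputs with controlled ground truth.

Everything the pipeline consumes — template structures with designed
interface contacts, sequence databases with implanted homologs among
composition-matched decoys, power-law degree samples, GO mini-ontologies,
expression matrices, and mutation sets with a known placement odds ratio —
is generated here deterministically from a seed, so every stage is testable
without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from scipy.special import zeta

from .network import Network

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# designed contact archetypes: (resname_a, atom_a, resname_b, atom_b, distance, kind)
_CONTACT_DESIGNS = {
    "hbond": ("SER", "OG", "GLN", "OE1", 2.9, "S", "Q"),
    "vdw": ("LEU", "CD1", "LEU", "CD1", 3.8, "L", "L"),
}
_RES_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass
class FixtureSpec:
    """Sizes and effect parameters of the template/homolog fixture."""

    seed: int = 1
    chain_len_a: int = 40
    chain_len_b: int = 35
    n_contacts: int = 3
    n_implants: int = 3
    n_decoys: int = 20
    identity: float = 0.9  # implant sequence identity to the template chain

    def __post_init__(self) -> None:
        if min(self.chain_len_a, self.chain_len_b, self.n_contacts,
               self.n_implants, self.n_decoys) <= 0:
            raise ValueError("all sizes must be positive")
        if not 0 < self.identity <= 1:
            raise ValueError("identity must be in (0, 1]")


@dataclass
class TemplateFixture:
    pdb_text: str
    fasta_text: str
    seq_a: str
    seq_b: str
    implants_a: list[str]
    implants_b: list[str]
    decoys_a: list[str]
    decoys_b: list[str]
    true_pairs: set[tuple[str, str]]
    designed_contacts: list[tuple[int, int, str]]
    spec: FixtureSpec = field(repr=False, default=None)


def _atom_line(serial: int, name: str, resname: str, chain: str, resseq: int,
               x: float, y: float, z: float, element: str) -> str:
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {pad_name}{'':1s}{resname:>3s} {chain}{resseq:4d}{'':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _mutate(rng: np.random.Generator, seq: str, keep: set[int], identity: float) -> str:
    n_mut = round(len(seq) * (1 - identity))
    mutable = [i for i in range(len(seq)) if i + 1 not in keep]
    chosen = rng.choice(mutable, size=min(n_mut, len(mutable)), replace=False)
    out = list(seq)
    for i in chosen:
        out[i] = rng.choice([a for a in AA20 if a != seq[i]])
    return "".join(out)


def generate_template_fixture(spec: FixtureSpec) -> TemplateFixture:
    """Build a two-chain template with designed contacts plus a sequence DB.

    The chains run on parallel lines 20 A apart; each designed contact
    places a single sidechain atom pair at its archetype distance (a 2.9 A
    serine-glutamine donor-acceptor pair for hydrogen bonds, a 3.8 A
    leucine-leucine carbon pair for van der Waals), well separated along the
    chain axis so no unintended inter-chain contact arises. The database
    holds, per side, ``n_implants`` point-mutated homologs (contact residues
    preserved) and ``n_decoys`` shuffled (composition-matched) decoys.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = 5  # residues between designed contact positions
    if spec.n_contacts * spacing + 2 > min(spec.chain_len_a, spec.chain_len_b):
        raise ValueError("infeasible geometry: too many contacts for chain length")

    pos_a = [2 + spacing * k for k in range(spec.n_contacts)]
    pos_b = [2 + spacing * k for k in range(spec.n_contacts)]
    kinds = ["hbond" if k % 2 == 0 else "vdw" for k in range(spec.n_contacts)]

    seq_a = list(_random_seq(rng, spec.chain_len_a))
    seq_b = list(_random_seq(rng, spec.chain_len_b))
    for pa, pb, kind in zip(pos_a, pos_b, kinds):
        _, _, _, _, _, one_a, one_b = _CONTACT_DESIGNS[kind]
        seq_a[pa - 1] = one_a
        seq_b[pb - 1] = one_b
    seq_a, seq_b = "".join(seq_a), "".join(seq_b)

    lines: list[str] = []
    serial = 1
    contact_x = {}
    for k, pa in enumerate(pos_a):
        contact_x[("A", pa)] = 30.0 * (k + 1)
        contact_x[("B", pos_b[k])] = 30.0 * (k + 1)
    for chain, seq, y0 in (("A", seq_a, 0.0), ("B", seq_b, 20.0)):
        for i, aa in enumerate(seq, start=1):
            resname = _RES_THREE[aa]
            x = 3.8 * i + (500.0 if chain == "B" else 0.0)
            for name, elem, dx in (("N", "N", -0.5), ("CA", "C", 0.0),
                                   ("C", "C", 0.5), ("O", "O", 1.0)):
                lines.append(_atom_line(serial, name, resname, chain, i, x + dx, y0, 0.0, elem))
                serial += 1
        # designed sidechain atoms sit between the chains
        for k, (pa, pb, kind) in enumerate(zip(pos_a, pos_b, kinds)):
            rn_a, at_a, rn_b, at_b, dist, _, _ = _CONTACT_DESIGNS[kind]
            xk = contact_x[("A", pa)]
            if chain == "A":
                lines.append(_atom_line(serial, at_a, rn_a, "A", pa, xk, 8.0, 0.0, at_a[0]))
            else:
                lines.append(_atom_line(serial, at_b, rn_b, "B", pb, xk, 8.0 + dist, 0.0, at_b[0]))
            serial += 1
    pdb_text = "\n".join(lines) + "\nEND\n"

    keep_a = set(pos_a)
    keep_b = set(pos_b)
    fasta: list[str] = []
    implants_a, implants_b, decoys_a, decoys_b = [], [], [], []
    for side, seq, keep, implants, decoys in (
        ("A", seq_a, keep_a, implants_a, decoys_a),
        ("B", seq_b, keep_b, implants_b, decoys_b),
    ):
        for i in range(spec.n_implants):
            pid = f"imp{side}{i + 1}"
            implants.append(pid)
            fasta.append(f">{pid}|species{i + 1}\n{_mutate(rng, seq, keep, spec.identity)}")
        for i in range(spec.n_decoys):
            pid = f"dec{side}{i + 1}"
            decoys.append(pid)
            shuffled = "".join(rng.permutation(list(seq)))
            fasta.append(f">{pid}|decoysp{i + 1}\n{shuffled}")
    fasta_text = "\n".join(fasta) + "\n"

    return TemplateFixture(
        pdb_text=pdb_text,
        fasta_text=fasta_text,
        seq_a=seq_a,
        seq_b=seq_b,
        implants_a=implants_a,
        implants_b=implants_b,
        decoys_a=decoys_a,
        decoys_b=decoys_b,
        true_pairs={(a, b) for a in implants_a for b in implants_b},
        designed_contacts=[(pa, pb, kind) for pa, pb, kind in zip(pos_a, pos_b, kinds)],
        spec=spec,
    )


def generate_powerlaw_degrees(
    n: int, gamma: float, xmin: int = 1, seed: int = 0, kmax: int = 1_000_000
) -> np.ndarray:
    """Sample n i.i.d. degrees from the discrete power law P(k) ~ k^-gamma.

    Inverse-CDF sampling on the Hurwitz-zeta-normalized pmf tabulated up to
    ``kmax`` (residual tail mass, ~1e-6 at gamma near 2, collapses onto
    kmax). Deterministic under the seed.
    """
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    if n < 100:
        raise ValueError("n must be at least 100")
    ks = np.arange(xmin, kmax + 1, dtype=float)
    pmf = ks ** (-gamma) / zeta(gamma, xmin)
    cdf = np.cumsum(pmf)
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="left")
    return (xmin + np.minimum(idx, kmax - xmin)).astype(int)


def generate_mutation_fixture(
    network: Network,
    sequences: dict[str, str],
    or_target: float,
    n_mut: int,
    seed: int = 0,
) -> tuple[str, dict]:
    """Place mutations with a controlled contact-residue odds ratio.

    Mutations land on contacting residues with probability p1 chosen so that
    the generative odds [p1/(1-p1)] equal ``or_target`` times the background
    residue odds [p2/(1-p2)], p2 being the contacting fraction of all
    residues of the network's proteins. Returns mutation TSV text plus the
    generative truth (p1, p2, counts).
    """
    if n_mut <= 0:
        raise ValueError("n_mut must be positive")
    if or_target <= 0:
        raise ValueError("or_target must be positive")
    contact_sites: list[tuple[str, int]] = []
    other_sites: list[tuple[str, int]] = []
    for pid in network.nodes:
        if pid not in sequences:
            continue
        contacts = set(network.contact_positions(pid))
        for pos in range(1, len(sequences[pid]) + 1):
            (contact_sites if pos in contacts else other_sites).append((pid, pos))
    if not contact_sites:
        raise ValueError("network has no contact annotations")
    p2 = len(contact_sites) / (len(contact_sites) + len(other_sites))
    odds1 = or_target * p2 / (1 - p2)
    p1 = odds1 / (1 + odds1)
    rng = np.random.default_rng(seed)
    rows = []
    n_on_contact = 0
    for _ in range(n_mut):
        if rng.random() < p1:
            pid, pos = contact_sites[int(rng.integers(len(contact_sites)))]
            n_on_contact += 1
        else:
            pid, pos = other_sites[int(rng.integers(len(other_sites)))]
        wt = sequences[pid][pos - 1]
        mut = rng.choice([a for a in AA20 if a != wt])
        rows.append(f"{pid}\t{wt}{pos}{mut}\tfixture_disease\tgermline")
    truth = {
        "or_target": or_target,
        "p1": p1,
        "p2": p2,
        "n_mut": n_mut,
        "n_on_contact": n_on_contact,
        "n_contact_sites": len(contact_sites),
        "n_total_sites": len(contact_sites) + len(other_sites),
    }
    return "\n".join(rows) + "\n", truth


def generate_go_fixture() -> tuple[str, str]:
    """A small fixed GO-style ontology (OBO text) plus annotations TSV.

    One biological_process aspect of seven terms:

        T1 (root) -> T2, T3; T2 -> T4, T5; T3 -> T6; T5 -> T7 (also T7 is_a T6)

    so depths are T1:0, T2/T3:1, T4/T5/T6:2, T7:3.
    """
    terms = {
        "GO:0000001": ("root process", []),
        "GO:0000002": ("branch a", ["GO:0000001"]),
        "GO:0000003": ("branch b", ["GO:0000001"]),
        "GO:0000004": ("leaf a1", ["GO:0000002"]),
        "GO:0000005": ("mid a2", ["GO:0000002"]),
        "GO:0000006": ("leaf b1", ["GO:0000003"]),
        "GO:0000007": ("deep leaf", ["GO:0000005", "GO:0000006"]),
    }
    chunks = ["format-version: 1.2\nontology: fixture"]
    for tid, (name, parents) in terms.items():
        block = [f"[Term]\nid: {tid}\nname: {name}\nnamespace: biological_process"]
        block += [f"is_a: {p} ! parent" for p in parents]
        chunks.append("\n".join(block))
    obo_text = "\n\n".join(chunks) + "\n"
    annotations = "\n".join(
        ["P1\tGO:0000004", "P1\tGO:0000005", "P2\tGO:0000007", "P3\tGO:0000006"]
    ) + "\n"
    return obo_text, annotations


def generate_expression_fixture(
    genes: list[str],
    n_samples: int = 200,
    correlated_pairs: list[tuple[str, str, float]] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Genes x samples expression matrix with designed pairwise correlation.

    Latent values are standard normal per gene; for each (a, b, rho) pair,
    gene b's latent vector is rebuilt as rho*a + sqrt(1-rho^2)*noise. The
    matrix is 2**(latent + 5), so the downstream log2(x+1) transform
    approximately recovers the latent correlations.
    """
    rng = np.random.default_rng(seed)
    latent = {g: rng.standard_normal(n_samples) for g in genes}
    for a, b, rho in correlated_pairs:
        latent[b] = rho * latent[a] + math.sqrt(1 - rho**2) * rng.standard_normal(n_samples)
    mat = pd.DataFrame(
        {f"s{j + 1}": [2.0 ** (latent[g][j] + 5) for g in genes] for j in range(n_samples)},
        index=genes,
    )
    return mat


def expression_to_tsv(expression: pd.DataFrame) -> str:
    buf = StringIO()
    expression.to_csv(buf, sep="\t", index_label="gene")
    return buf.getvalue()
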