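"""End-to-end orchestration: build the network, then the enrichment report.

`run_build` drives templates -> homolog families -> interface scoring ->
network assembly and writes deterministic TSV/JSON artifacts; `run_enrich`
turns mutation classifications plus optional ddG / GO / expression inputs
into one JSON report. All thresholds live in :class:`RunConfig` and are
echoed into the output manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import homology, mutations as mut_mod, network as net_mod, scoring, stats, structures

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds, and the master seed of one pipeline run."""

    templates_dir: str = ""
    db_fasta: str = ""
    blast_tab: str | None = None
    out_dir: str = "interomap_out"
    evalue_max: float = 1e-10
    z_min: float = 3.0
    contact_cutoff: float = 4.5
    hbond_cutoff: float = 3.5
    c_min: float = 0.7
    w_cons: float = 1.0
    gap_penalty: float = -4.0
    ddg_threshold: float = 1.5
    n_bg: int = 200
    matrix_name: str = "BLOSUM62"
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            self.evalue_max, self.z_min, self.contact_cutoff,
            self.hbond_cutoff, self.c_min, self.ddg_threshold, self.n_bg,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("thresholds must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def scoring_config(self) -> scoring.ScoringConfig:
        return scoring.ScoringConfig(
            z_min=self.z_min, n_bg=self.n_bg, seed=self.seed, c_min=self.c_min,
            w_cons=self.w_cons, gap_penalty=self.gap_penalty,
            matrix_name=self.matrix_name,
        )


@dataclass
class BuildResult:
    network: net_mod.Network
    candidates: list[scoring.CandidateInteraction]
    families: dict[str, scoring.PPIFamily]
    template_species: dict[str, str]
    manifest: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _template_index(templates_dir: Path) -> list[tuple[str, str, str, str]]:
    """(template_id, chain_a, chain_b, species) per template PDB file."""
    index_path = templates_dir / "templates.tsv"
    if index_path.exists():
        df = pd.read_csv(
            index_path, sep="\t", header=None,
            names=["template_id", "chain_a", "chain_b", "species"], dtype=str,
        )
        return [tuple(r) for r in df.itertuples(index=False)]
    return [
        (p.stem, "A", "B", "unknown")
        for p in sorted(templates_dir.glob("*.pdb"))
    ]


def run_build(config: RunConfig) -> BuildResult:
    """Run templates -> families -> scoring -> network; write artifacts."""
    t0 = time.monotonic()
    templates_dir = Path(config.templates_dir)
    db_path = Path(config.db_fasta)
    if not db_path.exists():
        raise StageError("read-db", f"FASTA not found: {db_path}")
    if not templates_dir.is_dir():
        raise StageError("read-templates", f"template directory not found: {templates_dir}")
    with open(db_path) as fh:
        db = homology.read_fasta(fh)

    blast_hits: dict[str, list[homology.HomologHit]] = {}
    if config.blast_tab:
        try:
            with open(config.blast_tab) as fh:
                for hit in homology.read_blast_tabular(fh):
                    blast_hits.setdefault(hit.query_chain, []).append(hit)
        except (OSError, ValueError) as exc:
            raise StageError("read-blast", str(exc)) from exc

    candidates: list[scoring.CandidateInteraction] = []
    families: dict[str, scoring.PPIFamily] = {}
    template_species: dict[str, str] = {}
    potentials = scoring.PotentialTable.default(config.matrix_name)
    sconf = config.scoring_config()
    for template_id, chain_a, chain_b, species in _template_index(templates_dir):
        pdb_path = templates_dir / f"{template_id}.pdb"
        try:
            with open(pdb_path) as fh:
                tpl = structures.parse_structure(
                    fh, (chain_a, chain_b), template_id=template_id, species=species
                )
        except (OSError, ValueError) as exc:
            raise StageError("parse-template", f"{template_id}: {exc}") from exc
        tpl.contacts = structures.extract_contacts(
            tpl, config.contact_cutoff, config.hbond_cutoff
        )
        template_species[template_id] = species
        fams = {}
        for role, seq in (("A", tpl.seq_a), ("B", tpl.seq_b)):
            key = f"{template_id}:{role}"
            hits = blast_hits.get(key)
            if hits is None:
                hits = homology.search_homologs(
                    seq, db, matrix_name=config.matrix_name, query_chain=key
                )
            fams[role] = homology.build_family(template_id, role, hits, config.evalue_max)
        cands, fam = scoring.infer_family_ppis(
            tpl, fams["A"], fams["B"], db, sconf, potentials
        )
        candidates.extend(cands)
        if fam is not None:
            families[template_id] = fam
        logger.info(
            "template %s: %d candidates, %d accepted [%.2fs]",
            template_id, len(cands), sum(c.accepted for c in cands),
            time.monotonic() - t0,
        )

    network = net_mod.assemble_network(candidates, template_species)
    manifest = {
        "thresholds": {
            "evalue_max": config.evalue_max,
            "z_min": config.z_min,
            "contact_cutoff": config.contact_cutoff,
            "hbond_cutoff": config.hbond_cutoff,
            "c_min": config.c_min,
            "w_cons": config.w_cons,
            "gap_penalty": config.gap_penalty,
            "ddg_threshold": config.ddg_threshold,
            "n_bg": config.n_bg,
            "matrix_name": config.matrix_name,
        },
        "seed": config.seed,
        "n_templates": len(template_species),
        "n_candidates": len(candidates),
        "n_edges": len(network.edges),
        "n_nodes": len(network.nodes),
    }
    result = BuildResult(network, candidates, families, template_species, manifest)
    if config.out_dir:
        write_build_outputs(result, Path(config.out_dir))
    return result


def write_build_outputs(result: BuildResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    net_mod.write_edge_tsv(result.network, str(out_dir / "edges.tsv"))
    rows = [
        {
            "template_id": c.template_id,
            "protein_a": c.protein_a_id,
            "protein_b": c.protein_b_id,
            "e_vdw": f"{c.breakdown.e_vdw:.6f}",
            "e_sf": f"{c.breakdown.e_sf:.6f}",
            "e_sim": f"{c.breakdown.e_sim:.6f}",
            "e_cons": f"{c.breakdown.e_cons:.6f}",
            "e_tot": f"{c.breakdown.e_tot:.6f}",
            "z": f"{c.z:.6f}",
        }
        for c in result.candidates
        if c.accepted
    ]
    pd.DataFrame(
        rows,
        columns=["template_id", "protein_a", "protein_b", "e_vdw", "e_sf",
                 "e_sim", "e_cons", "e_tot", "z"],
    ).to_csv(out_dir / "interactions.tsv", sep="\t", index=False)
    contact_rows = []
    for pid in result.network.nodes:
        for pos, rc in sorted(result.network.contact_positions(pid).items()):
            contact_rows.append(
                {
                    "protein_id": pid,
                    "position": pos,
                    "kinds": ",".join(sorted(rc.kinds)),
                    "conserved": int(rc.conserved),
                }
            )
    pd.DataFrame(
        contact_rows, columns=["protein_id", "position", "kinds", "conserved"]
    ).to_csv(out_dir / "contacts.tsv", sep="\t", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_network_dir(out_dir: str | Path) -> net_mod.Network:
    """Rebuild a Network skeleton from build artifacts.

    Contact annotations are per-protein unions (the per-edge provenance is
    not round-tripped); classification and enrichment only need the union.
    """
    out_dir = Path(out_dir)
    edges_df = net_mod.read_edge_tsv(str(out_dir / "edges.tsv"))
    contacts_df = pd.read_csv(out_dir / "contacts.tsv", sep="\t")
    per_protein: dict[str, dict[int, net_mod.ResidueContact]] = {}
    for row in contacts_df.itertuples(index=False):
        rc = net_mod.ResidueContact(
            position=int(row.position),
            kinds=set(str(row.kinds).split(",")),
            conserved=bool(row.conserved),
        )
        per_protein.setdefault(str(row.protein_id), {})[rc.position] = rc
    edges = []
    attached: set[str] = set()
    for row in edges_df.itertuples(index=False):
        a, b = str(row.protein_a), str(row.protein_b)
        e = net_mod.InteractionEdge(
            protein_a=a,
            protein_b=b,
            templates=[
                net_mod.SupportingTemplate(
                    "<restored>", float(row.best_z), "unknown",
                    bool(row.human_template_any),
                )
            ],
        )
        if a not in attached:
            e.contacts_a = per_protein.get(a, {})
            attached.add(a)
        if b not in attached:
            e.contacts_b = per_protein.get(b, {})
            attached.add(b)
        edges.append(e)
    return net_mod.Network(edges=edges)


def load_ddg_records(stream) -> list[stats.DdgRecord]:
    """ddG TSV: complex_id, chain, position, ddg, contacting, in_domain."""
    df = pd.read_csv(
        stream, sep="\t", header=None, comment="#",
        names=["complex_id", "chain", "position", "ddg", "contacting", "in_domain"],
    )
    return [
        stats.DdgRecord(
            complex_id=str(r.complex_id),
            chain=str(r.chain),
            position=int(r.position),
            ddg=float(r.ddg),
            contacting=bool(int(r.contacting)),
            in_domain=bool(int(r.in_domain)),
        )
        for r in df.itertuples(index=False)
    ]


def _feature_or(k_obs: int, n_obs: int, k_bg: int, n_bg: int) -> dict:
    if n_obs == 0 or n_bg == 0:
        return {"defined": False}
    res = stats.odds_ratio(stats.EnrichmentInput(k_obs, n_obs, k_bg, n_bg), haldane=True)
    fisher = stats.fisher_exact(k_obs, n_obs - k_obs, k_bg, n_bg - k_bg, "two")
    return {
        "defined": True,
        "k_obs": k_obs, "n_obs": n_obs, "k_bg": k_bg, "n_bg": n_bg,
        "p1": res.p1, "p2": res.p2,
        "odds_ratio": res.odds_ratio,
        "odds_ratio_haldane": res.haldane_odds_ratio,
        "degenerate": res.degenerate,
        "fisher_two_p": fisher,
    }


def run_enrich(
    network: net_mod.Network,
    mutation_list: list[mut_mod.Mutation],
    domain_regions: list[structures.DomainRegion] = (),
    sequences: dict[str, str] | None = None,
    ddg_records: list[stats.DdgRecord] | None = None,
    go_dag: stats.GoDag | None = None,
    go_annotations: dict[str, set[str]] | None = None,
    expression: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Compute the enrichment report (odds ratios, tests, summaries)."""
    config = config or RunConfig()
    sequences = sequences or {}
    classifications = [
        mut_mod.classify_mutation(m, network, domain_regions, sequences, wt_check=False)
        for m in mutation_list
    ]
    table = mut_mod.classification_table(classifications)
    report: dict = {
        "counts": {
            "n_mutations": len(mutation_list),
            "n_in_frame": int((table["category"] == "in_frame").sum()) if len(table) else 0,
            "n_truncating": int((table["category"] == "truncating").sum()) if len(table) else 0,
        },
        "odds_ratios": {},
        "thresholds": {"ddg_threshold": config.ddg_threshold},
    }
    if not mutation_list:
        report["warning"] = "empty mutation list: no odds ratios computed"
        return report

    usable = table[(table["category"] == "in_frame") & (~table["note"].str.startswith("rejected"))]
    mapped = usable[usable["note"] != "unmapped"]

    # residue backgrounds over network proteins with known sequences
    node_set = [p for p in network.nodes if p in sequences]
    total_residues = sum(len(sequences[p]) for p in node_set)
    contact_residues = sum(len(network.contact_positions(p)) for p in node_set)
    hb_residues = cons_residues = 0
    for p in node_set:
        for rc in network.contact_positions(p).values():
            if rc.kinds & {"hbond", "electrostatic"}:
                hb_residues += 1
            if rc.conserved:
                cons_residues += 1

    for db in ("Pfam", "SCOP"):
        regions = [r for r in domain_regions if r.domain_db == db]
        annotated_proteins = {r.protein_id for r in regions} & set(node_set)
        dom_mut = mapped[mapped["protein_id"].isin(annotated_proteins)]
        k_obs = int(dom_mut[f"in_interacting_domain_{db}"].sum())
        k_bg = n_bg = 0
        for p in sorted(annotated_proteins):
            inter, _non = mut_mod.interacting_domains(p, network, regions)
            covered = set()
            for r in inter:
                covered.update(range(r.start, min(r.end, len(sequences[p])) + 1))
            k_bg += len(covered)
            n_bg += len(sequences[p])
        report["odds_ratios"][f"interacting_domain_{db}"] = _feature_or(
            k_obs, len(dom_mut), k_bg, n_bg
        )
        if n_bg:
            report["odds_ratios"][f"noninteracting_domain_{db}"] = _feature_or(
                len(dom_mut) - k_obs, len(dom_mut), n_bg - k_bg, n_bg
            )

    if total_residues:
        n_obs = len(mapped)
        k_contact = int(mapped["contacting"].sum())
        report["odds_ratios"]["contacting"] = _feature_or(
            k_contact, n_obs, contact_residues, total_residues
        )
        report["odds_ratios"]["noncontacting"] = _feature_or(
            n_obs - k_contact, n_obs, total_residues - contact_residues, total_residues
        )
        report["odds_ratios"]["contacting_hbond"] = _feature_or(
            int(mapped["hbond_forming"].sum()), n_obs, hb_residues, total_residues
        )
        report["odds_ratios"]["contacting_conserved"] = _feature_or(
            int(mapped["conserved"].sum()), n_obs, cons_residues, total_residues
        )

    if ddg_records:
        d = stats.ddg_analysis(ddg_records, config.ddg_threshold)
        report["ddg"] = {
            "mean_contacting": d.mean_contacting,
            "mean_noncontacting": d.mean_noncontacting,
            "table": list(d.table),
            "fraction_contacting_high": d.fraction_contacting_high,
            "fraction_contacting_low": d.fraction_contacting_low,
            "odds_ratio": d.enrichment.odds_ratio,
            "fisher_greater_p": d.fisher_greater_p,
            "fisher_two_p": d.fisher_two_p,
            "utest_p": d.utest_p,
            "threshold": d.threshold,
        }

    if go_dag is not None and go_annotations:
        scores = []
        for e in network.edges:
            s = stats.rss_similarity(
                go_annotations.get(e.protein_a, set()),
                go_annotations.get(e.protein_b, set()),
                go_dag,
            )
            if s.defined:
                scores.append(s.value)
        report["rss"] = {
            "aspect": go_dag.aspect,
            "mean": (sum(scores) / len(scores)) if scores else None,
            "n_edges_scored": len(scores),
        }

    if expression is not None:
        co = stats.coexpression(
            [(e.protein_a, e.protein_b) for e in network.edges], expression
        )
        report["coexpression"] = {
            "mean_correlation": co.mean_correlation,
            "n_computed": co.n_computed,
            "n_uncovered": co.n_uncovered,
            "n_skipped_constant": co.n_skipped_constant,
        }
    return report


REPORT_REQUIRED_KEYS = ("counts", "odds_ratios", "thresholds")


def validate_report(report: dict) -> None:
    """Structural validation of an enrichment report."""
    for key in REPORT_REQUIRED_KEYS:
        if key not in report:
            raise ValueError(f"report missing required section {key!r}")
    if not isinstance(report["odds_ratios"], dict):
        raise ValueError("odds_ratios must be a mapping")
    for name, entry in report["odds_ratios"].items():
        if entry.get("defined") and not {"p1", "p2", "odds_ratio"} <= set(entry):
            raise ValueError(f"odds ratio entry {name!r} incomplete")
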