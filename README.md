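# interomap

Template-based **3D–domain interolog mapping** of structurally resolved
protein–protein interaction (PPI) networks, with interface-aware enrichment
statistics for disease mutations.

## The problem

High-throughput PPI screens say *that* two proteins interact, not *how*.
Dimer crystal structures say how, but cover few pairs. Interolog mapping
bridges the two: for a structural template T with chains A and B, every
cross-pair from the homolog families A′ × B′ (BLAST-style hits at
E ≤ 10⁻¹⁰) is a candidate interaction, and the template's interface
contacts — hydrogen-bond/electrostatic and van der Waals residue pairs —
are transferred onto each candidate through sequence alignment. A candidate
is accepted when its interface-similarity score

```
E_tot = E_vdw + E_SF + E_sim + E_cons
```

stands at **Z ≥ 3.0** above a background of randomly paired database
sequences scored through the identical path. `E_vdw` and `E_SF` are
residue-pair contact potentials evaluated on the candidate residues at the
template's vdW and hydrogen-bond/electrostatic contacts, `E_sim` is the
substitution similarity of candidate vs template residues over the aligned
contact positions of both chains, and `E_cons` rewards couple-conserved
contacts (both columns conserved in the template-anchored family alignments
and the candidate conforming).

Accepted pairs merge into a network whose edges carry their supporting
templates and per-residue contact maps. Downstream, the package classifies
point mutations by interface placement (interacting domain, contacting
residue, hydrogen-bond-forming, conserved) and quantifies enrichment with
the odds ratio

```
OR = [p1/(1−p1)] / [p2/(1−p2)]
```

where p1 is the mutation fraction in a feature and p2 the residue fraction
of that feature, plus Fisher exact and Mann–Whitney U tests, ddG hot-spot
contingency analysis, GO relative-specificity similarity (RSS), power-law
degree-exponent fits, and co-expression correlation.

Audience: structural systems biologists who want a reproducible, offline,
desk-scale implementation of the full pipeline — every input (templates,
sequence databases, mutation lists, ontologies, expression) can be
generated synthetically with controlled ground truth.

## Worked example

```python
import io
from interomap import fixtures, structures, homology, scoring, network, stats

# a synthetic dimer template with 3 designed interface contacts, plus a
# sequence DB of 3 implanted homologs and 20 shuffled decoys per chain
fx = fixtures.generate_template_fixture(fixtures.FixtureSpec(seed=1))
tpl = structures.parse_structure(io.StringIO(fx.pdb_text), ("A", "B"), "tpl1", "human")
tpl.contacts = structures.extract_contacts(tpl)          # 4.5 A / 3.5 A cutoffs
print([(c.pos_a, c.pos_b, c.kind) for c in tpl.contacts])
# [(2, 2, 'hbond'), (7, 7, 'vdw'), (12, 12, 'hbond')]

db = homology.read_fasta(fx.fasta_text)
fam_a = homology.build_family("tpl1", "A", homology.search_homologs(tpl.seq_a, db))
fam_b = homology.build_family("tpl1", "B", homology.search_homologs(tpl.seq_b, db))
cands, fam = scoring.infer_family_ppis(tpl, fam_a, fam_b, db,
                                       scoring.ScoringConfig(seed=7))
net = network.assemble_network(cands, {"tpl1": "human"})
print(len(net.nodes), len(net.edges))                    # 6 9
# all 9 implanted homolog pairs accepted at Z >= 3, no decoy pair:
print({(c.protein_a_id, c.protein_b_id) for c in cands if c.accepted} == fx.true_pairs)
# True

# the published interacting-domain worked example, from its printed counts
res = stats.odds_ratio(stats.EnrichmentInput(1653, 2330, 125606, 282517))
print(round(res.p1, 2), round(res.p2, 2), round(res.odds_ratio, 2))
# 0.71 0.44 3.05
```

The numbers mean: 71% of the classified mutations fall in interacting
Pfam domains which hold only 44% of the residues, a 3.05-fold odds
enrichment — disease mutations concentrate at structural interfaces.

The same flow is available from the shell:

```bash
interomap fixtures --out fx --seed 1
interomap build --templates fx/templates --db fx/db.fasta --out out --seed 3
interomap annotate --network out --mutations muts.tsv --sequences fx/db.fasta --out annot.tsv
interomap enrich --network out --mutations muts.tsv --sequences fx/db.fasta --out report.json
```

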