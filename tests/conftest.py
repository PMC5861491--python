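import io

import pytest

from interomap import fixtures as fix_mod
from interomap import homology, network as net_mod, scoring, structures

# default study conditions of the implanted-homolog fixture
FIXTURE_SEED = 1
SCORING_SEED = 7


@pytest.fixture(scope="session")
def template_fixture():
    return fix_mod.generate_template_fixture(fix_mod.FixtureSpec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def template(template_fixture):
    tpl = structures.parse_structure(
        io.StringIO(template_fixture.pdb_text), ("A", "B"), "tpl1", "human"
    )
    tpl.contacts = structures.extract_contacts(tpl)
    return tpl


@pytest.fixture(scope="session")
def seq_db(template_fixture):
    return homology.read_fasta(template_fixture.fasta_text)


@pytest.fixture(scope="session")
def families(template, seq_db):
    fams = {}
    for role, seq in (("A", template.seq_a), ("B", template.seq_b)):
        hits = homology.search_homologs(seq, seq_db, query_chain=f"tpl1:{role}")
        fams[role] = homology.build_family("tpl1", role, hits)
    return fams


@pytest.fixture(scope="session")
def inferred(template, families, seq_db):
    config = scoring.ScoringConfig(seed=SCORING_SEED)
    candidates, family = scoring.infer_family_ppis(
        template, families["A"], families["B"], seq_db, config
    )
    return candidates, family


@pytest.fixture(scope="session")
def network(inferred):
    candidates, _family = inferred
    return net_mod.assemble_network(candidates, {"tpl1": "human"})


@pytest.fixture(scope="session")
def sequences(seq_db):
    return {pid: seq for pid, _species, seq in seq_db.records}
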