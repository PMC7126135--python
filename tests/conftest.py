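import pytest

from protascan import default_background

UNIPROT_FASTA = """\
>sp|P02320|PRM1_BOVIN Sperm protamine P1 OS=Bos taurus OX=9913 GN=PRM1 PE=1 SV=2
MARYRCCRMSRSRCRRRRRRCRRRRRRCCRRRRRRCCRRRRSYTIRCKKY
>tr|A0A000|A0A000_DANRE Protamine OS=Danio rerio OX=7955 GN=prm PE=4 SV=1
MRRRRSSSRPVRRRRRPRVSRRRRRRGGRRRR
"""

UNIPROT_TSV_HEADER = "accession\treviewed\tgene_names\torganism\tlineage\tprotein_name\tsequence"


def tsv_line(accession, reviewed, gene_names, organism, lineage, name, seq):
    return "\t".join([accession, reviewed, gene_names, organism, lineage, name, seq])


@pytest.fixture(scope="session")
def bg():
    return default_background()


@pytest.fixture
def uniprot_fasta(tmp_path):
    path = tmp_path / "records.fasta"
    path.write_text(UNIPROT_FASTA)
    return path


@pytest.fixture
def record_table(tmp_path):
    """A small UniProt-style tabular export spanning all four group rules."""
    rows = [
        UNIPROT_TSV_HEADER,
        tsv_line("P02319", "reviewed", "PRM1", "Mus musculus",
                 "Eukaryota; Metazoa; Chordata; Mammalia; Eutheria; Rodentia",
                 "Sperm protamine P1", "MARYRCCRSQSRSRYYRQRQRSRRRRRRS"),
        tsv_line("P02320", "reviewed", "PRM1", "Bos taurus",
                 "Eukaryota; Metazoa; Chordata; Mammalia; Eutheria",
                 "Sperm protamine P1", "MARYRCCRMSRSRCRRRRRRCRRRRRRCCRRRRSY"),
        tsv_line("Q99999", "unreviewed", "PRM1", "Bos taurus",
                 "Eukaryota; Metazoa; Chordata; Mammalia; Eutheria",
                 "Sperm protamine P1 fragment", "MARYRCCRMSRSRCRRRR"),
        tsv_line("P11101", "reviewed", "PRM2", "Mus musculus",
                 "Eukaryota; Metazoa; Chordata; Mammalia; Eutheria; Rodentia",
                 "Sperm protamine P2", "MVRYRMRSPSEGPHQGPGQDHEREEQGQGQGLSPERVEDYGRTHRGHHHHRHRRCSRKRLHRIHKRRRSCRRRRRHSCRHRRRHRRGCRRSRRRRRCRCRKCRRHHH"),
        tsv_line("P67876", "reviewed", "PRM1", "Macropus eugenii",
                 "Eukaryota; Metazoa; Chordata; Mammalia; Metatheria; Diprotodontia",
                 "Sperm protamine P1", "MARYRRRRSRSRSRSRYGRRRTYRRSRRHSRRRRGYSRRRYSRRGRRRY"),
        tsv_line("P69014", "reviewed", "", "Salmo salar",
                 "Eukaryota; Metazoa; Chordata; Actinopterygii; Salmoniformes",
                 "Protamine (Salmine AI)", "MPRRRRSSSRPVRRRRRPRVSRRRRRRGGRRRR"),
        tsv_line("B00001", "unreviewed", "", "Danio rerio",
                 "Eukaryota; Metazoa; Chordata; Actinopterygii; Cypriniformes",
                 "Protamine-like protein", "MRRRRSSSRPVRRRR"),
        tsv_line("C00001", "unreviewed", "PRM2", "Macropus eugenii",
                 "Eukaryota; Metazoa; Chordata; Mammalia; Metatheria",
                 "Putative protamine P2", "MARYRRRRSRSRSRSRY"),
    ]
    path = tmp_path / "records.tsv"
    path.write_text("\n".join(rows) + "\n")
    return path
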