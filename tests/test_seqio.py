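"""CDS reading, core-gene filtering, and codon counting conventions."""

import numpy as np
import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from mitocub.codes import revcomp
from mitocub.seqio import (CORE_GENES, GeneRecord, canonical_gene,
                           read_fasta_cds, read_genbank, select_core_genes,
                           to_codon_counts)
from mitocub.codes import get_code

from conftest import make_counts


def _write_genbank(path, cds_specs, genome=None):
    """cds_specs: list of (gene_name, start, end, strand). 1-based inclusive in
    spirit; FeatureLocation takes 0-based half-open."""
    genome = genome or "ATGAAATTTGGGCCCTAGATGACT" * 30
    rec = SeqRecord(Seq(genome), id="TEST1", name="TEST1",
                    annotations={"organism": "Synthetic testorganism",
                                 "molecule_type": "DNA"})
    for gene, start, end, strand in cds_specs:
        feat = SeqFeature(FeatureLocation(start, end, strand=strand), type="CDS",
                          qualifiers={"gene": [gene], "transl_table": ["4"]})
        rec.features.append(feat)
    SeqIO.write([rec], str(path), "genbank")


def test_genbank_forward_cds_is_identity_extraction(tmp_path):
    gb = tmp_path / "f.gb"
    _write_genbank(gb, [("nad1", 0, 6, 1)], genome="ATGAAA" + "ACGT" * 20)
    recs = read_genbank(gb)
    assert len(recs) == 1
    assert recs[0].seq == "ATGAAA"
    assert recs[0].gene == "nad1"
    assert recs[0].table_id == 4
    assert recs[0].species == "Synthetic testorganism"


def test_genbank_complement_cds_is_reverse_complemented(tmp_path):
    gb = tmp_path / "r.gb"
    _write_genbank(gb, [("nad1", 0, 6, -1)], genome="TTTCAT" + "ACGT" * 20)
    recs = read_genbank(gb)
    assert recs[0].seq == "ATGAAA"


def test_genbank_eleven_cds_round_trip(tmp_path):
    genes = sorted(CORE_GENES)
    genome = "".join("ATG" + "AAATTT" * 10 + "TAA" for _ in genes)
    gb = tmp_path / "full.gb"
    specs = [(g, i * 66, (i + 1) * 66, 1) for i, g in enumerate(genes)]
    _write_genbank(gb, specs, genome=genome)
    recs = read_genbank(gb)
    assert [r.gene for r in recs] == genes
    assert all(r.seq == genome[:66] for r in recs)


def test_genbank_cds_without_gene_name_is_skipped(tmp_path):
    gb = tmp_path / "anon.gb"
    genome = "ATGAAATAA" + "ACGT" * 20
    rec = SeqRecord(Seq(genome), id="T", name="T",
                    annotations={"organism": "x", "molecule_type": "DNA"})
    rec.features.append(SeqFeature(FeatureLocation(0, 9, strand=1), type="CDS"))
    SeqIO.write([rec], str(gb), "genbank")
    assert read_genbank(gb) == []


def test_genbank_unparseable_file_raises(tmp_path):
    bad = tmp_path / "bad.gb"
    bad.write_text("this is not a genbank file\n")
    with pytest.raises(ValueError):
        read_genbank(bad)


def test_fasta_reader_parses_gene_tokens(tmp_path):
    fa = tmp_path / "sp.fasta"
    fa.write_text(">cox1\nATGGCT\n>nad3 some description\nATGAAA\n")
    recs = read_fasta_cds(fa, species="spX")
    assert [(r.gene, r.seq) for r in recs] == [("cox1", "ATGGCT"), ("nad3", "ATGAAA")]
    assert all(r.species == "spX" for r in recs)


def test_fasta_empty_file_gives_empty_list(tmp_path):
    fa = tmp_path / "empty.fasta"
    fa.write_text("")
    assert read_fasta_cds(fa, species="spX") == []


def test_fasta_duplicate_gene_raises_naming_the_gene(tmp_path):
    fa = tmp_path / "dup.fasta"
    fa.write_text(">cox1\nATGGCT\n>cox1\nATGAAA\n")
    with pytest.raises(ValueError, match="cox1"):
        read_fasta_cds(fa, species="spX")


def test_gene_name_canonicalization():
    assert canonical_gene("CYTB") == "cob"
    assert canonical_gene("ND5") == "nad5"
    assert canonical_gene("ORF_cox1") == "cox1"
    assert canonical_gene("COX1") == "cox1"


@pytest.mark.parametrize("length_nt,retained", [(297, False), (300, True), (303, True)])
def test_core_gene_length_filter_boundary(length_nt, retained):
    rec = GeneRecord(species="s", gene="atp6", seq="ATG" + "A" * (length_nt - 3))
    kept = select_core_genes([rec], min_codons=100)
    assert (rec in kept) == retained


def test_non_core_gene_excluded_regardless_of_length():
    rec = GeneRecord(species="s", gene="rps3", seq="ATG" + "AAA" * 299)
    assert select_core_genes([rec]) == []


def test_codon_counts_drop_terminal_stop(t4_code):
    rec = GeneRecord(species="s", gene="g", seq="ATGAAATAA")
    cc = to_codon_counts(rec, t4_code)
    assert cc.as_dict()["ATG"] == 1 and cc.as_dict()["AAA"] == 1
    assert cc.n_codons == 2
    assert cc.had_terminal_stop


def test_codon_counts_hand_tally(t4_code):
    cc = to_codon_counts(GeneRecord(species="s", gene="g", seq="ATGGCTGCT"), t4_code)
    assert cc.as_dict()["ATG"] == 1 and cc.as_dict()["GCT"] == 2
    assert cc.n_codons == 3


def test_codon_counts_length_error_and_truncate(t4_code):
    rec = GeneRecord(species="s", gene="g", seq="ATGAAAT")
    with pytest.raises(ValueError):
        to_codon_counts(rec, t4_code)
    cc = to_codon_counts(rec, t4_code, on_length_error="truncate")
    assert cc.n_codons == 2


def test_codon_counts_skip_n_and_internal_stops(t4_code):
    # internal TAA excluded by default, counted under the flag; N-codon skipped
    rec = GeneRecord(species="s", gene="g", seq="ATGTAAANNAAATAA")
    cc = to_codon_counts(rec, t4_code)
    assert cc.internal_stops == 1 and cc.skipped == 1
    assert cc.n_codons == 2  # ATG + AAA
    cc2 = to_codon_counts(rec, t4_code, count_internal_stops=True)
    assert cc2.n_codons == 3


def test_length_bookkeeping_invariant(t4_code):
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(2, 60))
        body = "".join(rng.choice(["AAA", "GCT", "TGT", "ANA"], size=n))
        seq = "ATG" + body + ("TAA" if rng.random() < 0.5 else "AAA")
        rec = GeneRecord(species="s", gene="g", seq=seq)
        cc = to_codon_counts(rec, t4_code)
        used = cc.n_codons + cc.skipped + cc.internal_stops + int(cc.had_terminal_stop)
        assert used * 3 == len(seq)


def test_reverse_complement_symmetry(tmp_path):
    """Extracting a minus-strand CDS equals forward extraction of the
    reverse-complemented genome."""
    cds = "ATGGCTAAATTTGGGTAA"
    genome = "ACGTAC" + revcomp(cds) + "GGCCTA"
    start = 6
    gb1 = tmp_path / "minus.gb"
    _write_genbank(gb1, [("cox2", start, start + len(cds), -1)], genome=genome)
    gb2 = tmp_path / "plus.gb"
    rc = revcomp(genome)
    start2 = len(genome) - (start + len(cds))
    _write_genbank(gb2, [("cox2", start2, start2 + len(cds), 1)], genome=rc)
    assert read_genbank(gb1)[0].seq == read_genbank(gb2)[0].seq == cds
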