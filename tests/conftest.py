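import io

import pytest

from circdiv import circ_detect, io_formats
from circdiv.synthetic_data import SimulationConfig, simulate_alignments, simulate_cohort

# fixture annotation with real circRNA host-gene coordinates: HIPK3 exon 2 and
# SMARCA5 exons 15-16 carry the exact boundaries of well-known circles; FGD6
# has deliberately non-matching exons so its circle stays novel.
FIXTURE_GTF = """\
##format: gtf
chr11\ttest\tgene\t33278000\t33290000\t.\t+\t.\tgene_id "ENSG00000110422"; gene_name "HIPK3";
chr11\ttest\texon\t33278100\t33278300\t.\t+\t.\tgene_id "ENSG00000110422"; gene_name "HIPK3"; transcript_id "HIPK3.t1"; exon_number "1";
chr11\ttest\texon\t33286413\t33287512\t.\t+\t.\tgene_id "ENSG00000110422"; gene_name "HIPK3"; transcript_id "HIPK3.t1"; exon_number "2";
chr4\ttest\tgene\t143540000\t143550000\t.\t+\t.\tgene_id "ENSG00000153147"; gene_name "SMARCA5";
chr4\ttest\texon\t143543509\t143543600\t.\t+\t.\tgene_id "ENSG00000153147"; gene_name "SMARCA5"; transcript_id "SMARCA5.t1"; exon_number "15";
chr4\ttest\texon\t143543800\t143543973\t.\t+\t.\tgene_id "ENSG00000153147"; gene_name "SMARCA5"; transcript_id "SMARCA5.t1"; exon_number "16";
chr12\ttest\tgene\t95200000\t95220000\t.\t+\t.\tgene_id "ENSG00000180263"; gene_name "FGD6";
chr12\ttest\texon\t95205000\t95205400\t.\t+\t.\tgene_id "ENSG00000180263"; gene_name "FGD6"; transcript_id "FGD6.t1"; exon_number "1";
chr12\ttest\texon\t95212000\t95212500\t.\t+\t.\tgene_id "ENSG00000180263"; gene_name "FGD6"; transcript_id "FGD6.t1"; exon_number "2";
"""


@pytest.fixture(scope="session")
def fixture_genes():
    return io_formats.read_gtf(io.StringIO(FIXTURE_GTF))


def make_junction_fragment(name, chrom, start, end, strand="+", read_len=100, split=40, mate_offset=10):
    """Alignment records for one back-splice fragment (primary + supp + mate)."""
    up_pos = end - split + 1
    up_cigar = f"{split}M{read_len - split}S"
    down_cigar = f"{split}S{read_len - split}M"
    mate_pos = start + mate_offset
    primary = io_formats.AlignmentRecord(
        read_name=name, chrom=chrom, pos=up_pos, strand=strand, cigar=up_cigar,
        is_first_in_pair=True, mate_chrom=chrom, mate_pos=mate_pos,
        sa_entries=((chrom, start, strand, down_cigar),), mapq=60,
    )
    supp = io_formats.AlignmentRecord(
        read_name=name, chrom=chrom, pos=start, strand=strand, cigar=down_cigar,
        is_first_in_pair=True, mate_chrom=chrom, mate_pos=mate_pos,
        sa_entries=((chrom, up_pos, strand, up_cigar),), mapq=60, is_supplementary=True,
    )
    mate = io_formats.AlignmentRecord(
        read_name=name, chrom=chrom, pos=mate_pos,
        strand="-" if strand == "+" else "+", cigar=f"{read_len}M",
        is_first_in_pair=False, mate_chrom=chrom, mate_pos=up_pos, sa_entries=(), mapq=60,
    )
    return [primary, supp, mate]


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-sample synthetic cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_samples=20, n_genes=50, n_circ=40, n_background_pairs=40, n_decoy_pairs=8
    )
    return simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def small_cohort_sams(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("sams")
    return simulate_alignments(small_cohort.config, small_cohort.truth, small_cohort.genes, out)


@pytest.fixture(scope="session")
def detected(small_cohort, small_cohort_sams):
    """Detector output (catalog, junction-count matrix) on the shared cohort."""
    per_sample = {}
    for sample, path in small_cohort_sams.items():
        ev = circ_detect.extract_split_candidates(io_formats.read_sam(path))
        ev = circ_detect.require_mate_in_circle(ev)
        junctions = circ_detect.call_junctions(ev)
        per_sample[sample] = circ_detect.annotate(junctions, small_cohort.genes)
    return circ_detect.merge_cohort(per_sample)
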