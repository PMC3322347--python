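import pytest

from orflink.io_formats import HitRecord, OrfRecord, Truncation
from orflink.synth_fixtures import FixtureConfig, make_fixture


def mk_orf(
    orf_id,
    genome="g",
    contig=None,
    trunc=Truncation.NONE,
    seq="M" * 50,
    strand=1,
    start=1,
):
    return OrfRecord(
        orf_id=orf_id,
        genome_id=genome,
        contig_id=contig if contig is not None else f"{orf_id}_ctg",
        start=start,
        end=start + 3 * len(seq) - 1,
        strand=strand,
        aa_sequence=seq,
        truncation=trunc,
    )


def mk_hit(query, subject, pident=90.0, q=(1, 50), s=(1, 50), bitscore=100.0, evalue=1e-20):
    return HitRecord(
        query_id=query,
        subject_id=subject,
        pident=pident,
        align_len=q[1] - q[0] + 1,
        mismatches=0,
        gap_opens=0,
        q_start=q[0],
        q_end=q[1],
        s_start=s[0],
        s_end=s[1],
        evalue=evalue,
        bitscore=bitscore,
    )


@pytest.fixture(scope="session")
def small_fixture():
    """A 60-gene fragmented genome with a 5%-diverged reference."""
    config = FixtureConfig(seed=7, n_genes=60)
    bundle, reference = make_fixture(config)
    return bundle, reference
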