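import pytest

from overlapscan import GeneRecord


def make_gene(
    start,
    stop,
    strand="+",
    locus="g",
    replicon="chr1",
    **kwargs,
):
    return GeneRecord(
        replicon_id=replicon,
        start=start,
        stop=stop,
        strand=strand,
        locus_tag=locus,
        **kwargs,
    )


@pytest.fixture
def forward_operon():
    """Three forward genes: a −4 overlap boundary then a +1 gap boundary."""
    return [
        make_gene(1000, 1999, locus="a"),  # stop codon 1997-1999
        make_gene(1996, 2998, locus="b"),  # start codon 1996-1998 -> distance -4
        make_gene(3000, 3899, locus="c"),  # distance 3000-2998-1 = +1
    ]
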