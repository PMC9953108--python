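import pytest

from tcscensus.model import Category, ProteinRecord, TCSProtein


def make_record(
    pid,
    start=1000,
    end=2000,
    strand="+",
    contig="c1",
    genome="G",
    seq=None,
):
    return ProteinRecord(
        protein_id=pid,
        genome_id=genome,
        contig_id=contig,
        start=start,
        end=end,
        strand=strand,
        sequence=seq,
    )


def make_tcs(
    category,
    pid="p1",
    start=1000,
    end=2000,
    strand="+",
    contig="c1",
    genome="G",
    n_rec=0,
    n_transmitter=0,
    roles=None,
    sensing=None,
    rr_family=None,
):
    if isinstance(category, str):
        category = Category(category)
    return TCSProtein(
        protein=make_record(pid, start, end, strand, contig, genome),
        category=category,
        roles=roles or [],
        n_rec=n_rec,
        n_transmitter=n_transmitter,
        sensing=sensing or [],
        rr_family=rr_family,
    )


def count_fixture(n_chk=0, n_hyhk=0, n_rr=0, genome="G"):
    """TCSProtein fixtures with one REC per RR/hyHK and one transmitter per
    cHK/hyHK, spaced as orphans."""
    out = []
    pos = 1000
    i = 0

    def nxt(cat, **kw):
        nonlocal pos, i
        i += 1
        t = make_tcs(cat, pid=f"{genome}_p{i:03d}", start=pos, end=pos + 900,
                     genome=genome, **kw)
        pos += 2000
        return t

    for _ in range(n_chk):
        out.append(nxt(Category.CHK, n_transmitter=1))
    for _ in range(n_hyhk):
        out.append(nxt(Category.HYHK, n_rec=1, n_transmitter=1))
    for _ in range(n_rr):
        out.append(nxt(Category.RR, n_rec=1))
    return out


@pytest.fixture
def rec():
    return make_record
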