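import numpy as np
import pytest

from tcscensus.census import (
    architecture_census,
    architecture_string,
    genome_summary,
    organization_summary,
    pearson,
    rr_family_census,
    rt_ratio,
    sensing_census,
)
from tcscensus.datasets import (
    load_thermophile_organization,
    load_thermophile_summary,
    orf_fractions,
    organization_fractions,
)
from tcscensus.model import (
    HATPASE,
    HISKA,
    REC,
    SENSING,
    Category,
    GeneCluster,
    Role,
)
from tcscensus.utils import round_half_up

from conftest import count_fixture, make_tcs


def _fixture_from_counts(counts):
    """Orphan-spaced TCSProtein list from per-category counts."""
    out = []
    pos = 1000
    for i, (cat, n) in enumerate(counts.items()):
        for j in range(n):
            kw = {}
            if cat in (Category.RR, Category.HYHK):
                kw["n_rec"] = 1
            if cat in (Category.CHK, Category.HYHK):
                kw["n_transmitter"] = 1
            out.append(
                make_tcs(cat, pid=f"{cat.value}_{j}", start=pos, end=pos + 900, **kw)
            )
            pos += 2000
    return out


class TestGenomeSummary:
    def test_totals_and_orf_fraction(self):
        counts = {
            Category.CHK: 42,
            Category.HYHK: 23,
            Category.UNORTHODOX_HK: 1,
            Category.CHEA: 2,
            Category.RR: 61,
            Category.PP_HISKA: 1,
            Category.PP_HPT: 1,
        }
        s = genome_summary(_fixture_from_counts(counts), n_cds=4917, genome_size_mb=5.35)
        assert s.total_tcs == 131
        assert s.orf_fraction == 2.7

    def test_small_genome_fraction(self):
        counts = {
            Category.CHK: 10,
            Category.HYHK: 4,
            Category.CHEA: 3,
            Category.RR: 23,
            Category.PP_HISKA: 1,
            Category.PP_HPT: 1,
        }
        s = genome_summary(_fixture_from_counts(counts), n_cds=2475, genome_size_mb=2.59)
        assert s.total_tcs == 42
        assert s.orf_fraction == 1.7

    def test_empty_counts(self):
        s = genome_summary([], n_cds=1000, genome_size_mb=1.0)
        assert s.total_tcs == 0 and s.orf_fraction == 0.0

    def test_zero_cds_fatal(self):
        with pytest.raises(ValueError):
            genome_summary([], n_cds=0, genome_size_mb=1.0)


class TestRtRatio:
    @pytest.mark.parametrize(
        "chk,hyhk,rr,expected",
        [(8, 3, 32, 3.2), (51, 15, 46, 0.9), (42, 23, 61, 1.3)],
    )
    def test_printed_ratios(self, chk, hyhk, rr, expected):
        assert rt_ratio(count_fixture(n_chk=chk, n_hyhk=hyhk, n_rr=rr)) == expected

    def test_no_receivers(self):
        assert rt_ratio(count_fixture(n_chk=5)) == 0.0

    def test_zero_transmitters_is_na(self):
        assert rt_ratio(count_fixture(n_rr=4)) is None

    def test_multi_rec_proteins_count_domains(self):
        # a hyHK with 2 RECs contributes 2 receivers and 1 transmitter
        t = make_tcs(Category.HYHK, n_rec=2, n_transmitter=1)
        assert rt_ratio([t]) == 2.0

    def test_unorthodox_and_chea_excluded(self):
        genes = count_fixture(n_chk=2, n_rr=2)
        genes.append(make_tcs(Category.UNORTHODOX_HK, pid="u", n_rec=3, n_transmitter=2))
        genes.append(make_tcs(Category.CHEA, pid="c", n_transmitter=1))
        assert rt_ratio(genes) == 1.0


class TestOrganizationSummary:
    def test_printed_aggregation(self):
        clusters = []
        idx = 0

        def add(size, count):
            nonlocal idx
            for _ in range(count):
                members = []
                for k in range(size):
                    members.append(
                        make_tcs(Category.RR, pid=f"p{idx}_{k}", start=1000 + 1100 * k,
                                 end=1900 + 1100 * k)
                    )
                clusters.append(GeneCluster("G", "c1", members))
                idx += 1

        add(1, 137), add(2, 35), add(3, 9), add(5, 1)
        row = organization_summary(clusters)
        assert row["orphan"] == 137 and row["pair"] == 35
        assert row["triad"] == 9 and row["pentad"] == 1
        assert row["total_tcs"] == 239

    def test_single_orphan(self):
        row = organization_summary([GeneCluster("G", "c1", [make_tcs(Category.RR)])])
        assert row["total_tcs"] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_size_weighted_total_identity(self, seed):
        rng = np.random.default_rng(seed)
        clusters = []
        n_genes = 0
        for i in range(int(rng.integers(1, 30))):
            size = int(rng.integers(1, 8))
            members = [
                make_tcs(Category.RR, pid=f"c{i}_{k}", start=1000 + 1100 * k, end=1900 + 1100 * k)
                for k in range(size)
            ]
            clusters.append(GeneCluster("G", "c1", members))
            n_genes += size
        assert organization_summary(clusters)["total_tcs"] == n_genes


class TestDomainCensuses:
    def test_sensing_counts_occurrences(self):
        chk = make_tcs(Category.CHK, pid="a", sensing=["PAS", "PAS", "GAF"])
        hyhk = make_tcs(Category.HYHK, pid="b", sensing=["HAMP"])
        counts = sensing_census([chk, hyhk])
        assert counts["PAS"] == (2, 0)
        assert counts["GAF"] == (1, 0)
        assert counts["HAMP"] == (0, 1)

    @pytest.mark.parametrize(
        "kinds,expected",
        [
            ([(SENSING, "GAF"), (HISKA, None), (HATPASE, None)], "S-T"),
            ([(HISKA, None), (HATPASE, None), (REC, None)], "T-R"),
            ([(HISKA, None)], "T"),  # rescued lone-HisKA kinase
        ],
    )
    def test_architecture_tokens(self, kinds, expected):
        roles = [Role(k, t) for k, t in kinds]
        assert architecture_string(roles) == expected

    def test_thirteen_sensing_domain_architecture(self):
        roles = []
        for _ in range(12):
            roles += [Role(SENSING, "HAMP"), Role(SENSING, "GAF")]
        roles += [Role(HISKA), Role(HATPASE), Role(REC)]
        assert architecture_string(roles) == "-".join(["S"] * 24 + ["T", "R"])

    def test_architecture_census_counts_no_sensing(self):
        a = make_tcs(Category.CHK, pid="a", roles=[Role(HISKA), Role(HATPASE)])
        b = make_tcs(
            Category.CHK,
            pid="b",
            roles=[Role(SENSING, "PAS"), Role(HISKA), Role(HATPASE)],
            sensing=["PAS"],
        )
        archs, no_sensing = architecture_census([a, b])
        assert archs == {"T": 1, "S-T": 1}
        assert no_sensing == 1

    def test_rr_families_partition_rr_total(self):
        genes = [
            make_tcs(Category.RR, pid="a", n_rec=1, rr_family="CheY"),
            make_tcs(Category.RR, pid="b", n_rec=1, rr_family="OmpR"),
            make_tcs(Category.RR, pid="c", n_rec=1, rr_family=None),
            make_tcs(Category.CHK, pid="d", n_transmitter=1),
        ]
        fams = rr_family_census(genes)
        assert sum(fams.values()) == 3  # equals the RR count


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        r, _ = pearson(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_covariance_ratio(self):
        x = [2.1, 3.5, 4.0, 5.5, 6.1, 7.8, 8.2, 9.9, 10.4, 12.0]
        y = [1.0, 2.2, 2.1, 3.9, 4.4, 4.9, 6.5, 6.9, 8.1, 8.8]
        n = len(x)
        mx, my = sum(x) / n, sum(y) / n
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sx = sum((a - mx) ** 2 for a in x) ** 0.5
        sy = sum((b - my) ** 2 for b in y) ** 0.5
        r_hand = cov / (sx * sy)
        r, _ = pearson(x, y)
        assert r == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning):
            r, p = pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r)


class TestReferencePanel:
    """Arithmetic over the packaged 17-genome census counts."""

    def test_row_identities(self):
        summary = load_thermophile_summary()
        org = load_thermophile_organization()
        cats = ["cHK", "hyHK", "uHK", "CheA", "RR", "PP-HisKA", "PP-Hpt"]
        t1_totals = summary[cats].sum(axis=1)
        merged = dict(zip(summary["genome_id"], t1_totals))
        for r in org.itertuples(index=False):
            expected = r.orphan + 2 * r.pair + 3 * r.triad + 4 * r.tetrad + 5 * r.pentad
            assert expected == r.total_tcs == merged[r.genome_id]

    def test_orf_fraction_range(self):
        fr = orf_fractions()
        assert fr.min() == 1.7 and fr.max() == 3.2

    def test_organization_fraction_ranges(self):
        df = organization_fractions()
        assert df["orphan_pct"].min() == 57.3
        assert df["orphan_pct"].max() == 90.2
        assert df["paired_pct"].min() == 3.9
        assert df["paired_pct"].max() == 29.8


def test_round_half_up_ties():
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(0.35, 1) == 0.4
    assert round_half_up(3.18181, 1) == 3.2
    assert round_half_up(0.9242, 1) == 0.9
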