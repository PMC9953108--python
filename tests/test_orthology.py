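import numpy as np
import pytest
from Bio.Align import substitution_matrices

from tcscensus.orthology import (
    align,
    bbh,
    build_families,
    core_percentage,
    find_duplicates,
    make_aligner,
    partition_summary,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
LETTERS = list("ACDEFGHIKLMNPQRSTVWY")


def sw_oracle(a, b, open_cost=11.0, extend_cost=1.0):
    """Independent Gotoh local-alignment DP (first gap residue costs
    ``open_cost``, each further residue ``extend_cost``)."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = s + max(0.0, M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            Ix[i, j] = max(
                M[i - 1, j] - open_cost, Ix[i - 1, j] - extend_cost, Iy[i - 1, j] - open_cost
            )
            Iy[i, j] = max(
                M[i, j - 1] - open_cost, Iy[i, j - 1] - extend_cost, Ix[i, j - 1] - open_cost
            )
            best = max(best, M[i, j])
    return best


class TestAlign:
    def test_identical_sequences(self):
        seq = "".join(np.random.default_rng(1).choice(LETTERS, size=100))
        r = align(seq, seq)
        assert r.identity == 100.0
        assert r.query_coverage == 100.0

    def test_dissimilar_peptides_score_zero(self):
        r = align("WWWW", "DDDD")
        assert r.score == 0.0 and r.identity == 0.0 and r.query_coverage == 0.0

    def test_forty_mer_with_four_mismatches(self):
        rng = np.random.default_rng(7)
        a = "".join(rng.choice(LETTERS, size=40))
        # positive-scoring mismatches keep the full-length alignment optimal
        subs = {"L": "M", "I": "V", "K": "R", "F": "Y", "A": "G", "E": "D",
                "Q": "E", "S": "T", "V": "I", "Y": "F", "D": "E", "R": "K",
                "T": "S", "M": "L", "N": "D", "G": "A", "H": "N", "W": "Y",
                "C": "A", "P": "A"}
        b = list(a)
        for pos in (10, 15, 22, 30):
            b[pos] = subs[a[pos]]
        b = "".join(b)
        assert sum(x != y for x, y in zip(a, b)) == 4
        r = align(a, b)
        assert r.identity == pytest.approx(90.0)
        assert r.query_coverage == pytest.approx(100.0)
        hand_score = sum(BLOSUM62[x, y] for x, y in zip(a, b))
        assert r.score == pytest.approx(hand_score)

    def test_score_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = "".join(rng.choice(LETTERS, size=rng.integers(10, 40)))
            b = "".join(rng.choice(LETTERS, size=rng.integers(10, 40)))
            ra, rb = align(a, b), align(b, a)
            assert ra.score == rb.score
            assert ra.identity == pytest.approx(rb.identity)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align("", "ACDE")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_dp(self, seed):
        rng = np.random.default_rng(seed)
        aligner = make_aligner()
        for _ in range(10):
            a = "".join(rng.choice(LETTERS, size=rng.integers(5, 31)))
            b = "".join(rng.choice(LETTERS, size=rng.integers(5, 31)))
            assert aligner.score(a, b) == sw_oracle(a, b)


def _mutate(seq, n_subs, rng):
    chars = list(seq)
    for i in rng.choice(len(chars), size=n_subs, replace=False):
        chars[i] = rng.choice([c for c in LETTERS if c != chars[i]])
    return "".join(chars)


class TestBBH:
    def test_duplicated_panel_pairs_every_protein(self):
        rng = np.random.default_rng(11)
        a = {
            f"p{i}": "".join(rng.choice(LETTERS, size=120)) for i in range(5)
        }
        b = {f"q{i}": a[f"p{i}"] for i in range(5)}
        pairs = bbh(a, b)
        assert pairs == [(f"p{i}", f"q{i}") for i in range(5)]

    def test_identity_exactly_40_excluded(self):
        # 50-mer with 30 mismatches -> identity 40.0, fails the strict rule
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(LETTERS, size=50))
        b = _mutate(a, 30, rng)
        r = align(a, b)
        if r.identity == pytest.approx(40.0):  # guard: local trimming may shift it
            assert bbh({"a": a}, {"b": b}) == []

    def test_threshold_filtering(self):
        rng = np.random.default_rng(9)
        a = "".join(rng.choice(LETTERS, size=100))
        close = _mutate(a, 10, rng)  # ~90% identity
        assert bbh({"a": a}, {"b": close}) == [("a", "b")]
        assert bbh({"a": a}, {"b": close}, identity_min=95.0) == []

    def test_matches_exhaustive_all_pairs_oracle(self):
        rng = np.random.default_rng(17)
        roots = ["".join(rng.choice(LETTERS, size=150)) for _ in range(3)]
        a = {f"a{i}": _mutate(r, 8, rng) for i, r in enumerate(roots)}
        b = {f"b{i}": _mutate(r, 8, rng) for i, r in enumerate(roots)}
        pairs = bbh(a, b)
        # oracle: brute-force best hits both ways from full align() results
        def best(qs, ss):
            out = {}
            for q, qseq in qs.items():
                cands = []
                for s, sseq in ss.items():
                    r = align(qseq, sseq)
                    if r.identity > 40 and r.query_coverage > 75:
                        cands.append((-r.score, -r.identity, s))
                if cands:
                    out[q] = min(cands)[2]
            return out

        fwd, rev = best(a, b), best(b, a)
        expected = sorted(
            (q, s) for q, s in fwd.items() if rev.get(s) == q
        )
        assert pairs == expected


class TestFamilies:
    def _panel(self, rng, n_genomes=3, n_families=4, subs=6):
        roots = ["".join(rng.choice(LETTERS, size=140)) for _ in range(n_families)]
        return {
            f"G{g}": {
                f"G{g}_F{i}": _mutate(roots[i], subs, rng)
                for i in range(n_families)
            }
            for g in range(n_genomes)
        }

    def test_identical_genomes_all_core(self):
        rng = np.random.default_rng(23)
        panel = self._panel(rng, subs=0)
        fams = build_families(panel)
        assert len(fams) == 4
        assert all(f.partition_class() == "core" for f in fams)
        assert partition_summary(fams)["core_gene_pct"] == 100.0

    def test_unique_protein_is_strain_specific(self):
        rng = np.random.default_rng(29)
        panel = self._panel(rng)
        panel["G0"]["G0_extra"] = "".join(rng.choice(LETTERS, size=130))
        fams = build_families(panel)
        specific = [f for f in fams if f.partition_class() == "strain-specific"]
        assert len(specific) == 1
        assert specific[0].members == {"G0": ["G0_extra"]}

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(31)
        panel = self._panel(rng, n_genomes=3, n_families=3)
        fams = build_families(panel)
        # oracle: union-find over the reciprocal-best-hit edge list
        genomes = sorted(panel)
        parent = {}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for g in genomes:
            for p in panel[g]:
                parent[(g, p)] = (g, p)
        for i, ga in enumerate(genomes):
            for gb in genomes[i + 1:]:
                for pa, pb in bbh(panel[ga], panel[gb]):
                    ra, rb = find((ga, pa)), find((gb, pb))
                    parent[ra] = rb
        groups = {}
        for node in parent:
            groups.setdefault(find(node), set()).add(node)
        expected = sorted(frozenset(g) for g in groups.values())
        got = sorted(
            frozenset((g, p) for g in f.panel for p in f.members.get(g, []))
            for f in fams
        )
        assert got == expected

    def test_presence_vector_tracks_membership(self):
        rng = np.random.default_rng(37)
        panel = self._panel(rng)
        del panel["G2"]["G2_F0"]
        fams = build_families(panel)
        f0 = next(f for f in fams if "G0_F0" in f.members.get("G0", []))
        assert f0.presence == {"G0": 1, "G1": 1, "G2": 0}
        assert f0.partition_class() == "accessory"


class TestDuplicates:
    def _family(self, members):
        from tcscensus.model import OrthologFamily

        return OrthologFamily(family_id="F0", members=members, panel=sorted(members))

    def test_identical_members_flagged(self):
        rng = np.random.default_rng(41)
        seq = "".join(rng.choice(LETTERS, size=120))
        fam = self._family({"G0": ["a", "b"], "G1": ["c"]})
        seqs = {("G0", "a"): seq, ("G0", "b"): seq, ("G1", "c"): seq}
        flags = find_duplicates(fam, seqs, identity_min=100.0)
        assert [(g, p1, p2) for g, p1, p2, _ in flags] == [("G0", "a", "b")]

    def test_threshold_controls_flagging(self):
        rng = np.random.default_rng(43)
        seq = "".join(rng.choice(LETTERS, size=100))
        div = _mutate(seq, 3, rng)  # 97% identity
        fam = self._family({"G0": ["a", "b"], "G1": ["c"]})
        seqs = {("G0", "a"): seq, ("G0", "b"): div, ("G1", "c"): seq}
        assert find_duplicates(fam, seqs, identity_min=95.0)
        assert not find_duplicates(fam, seqs, identity_min=98.0)

    def test_single_member_genome_no_flags(self):
        rng = np.random.default_rng(47)
        seq = "".join(rng.choice(LETTERS, size=100))
        fam = self._family({"G0": ["a"], "G1": ["c"]})
        assert find_duplicates(fam, {("G0", "a"): seq, ("G1", "c"): seq}) == []


def test_core_percentage_arithmetic():
    assert core_percentage(222, 272) == 81.6
    assert core_percentage(174, 242) == 71.9
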