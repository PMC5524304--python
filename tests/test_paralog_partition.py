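import math

import numpy as np
import pandas as pd
import pytest

from ohnocne.cne_pairwise import PairwiseHit
from ohnocne.cne_scan import CNE
from ohnocne.errors import InsufficientDataError
from ohnocne.io_formats import GenomicInterval
from ohnocne.paralog_partition import (
    PartitionTable,
    build_partition,
    count_asymmetry_test,
    partition_from_tsv,
    partition_to_tsv,
    summarize,
)


def make_cne(start, end, tetrapod=False):
    return CNE(
        interval=GenomicInterval("anc", start, end, "+"),
        conserved_column_count=end - start,
        tetrapod_support=tetrapod,
    )


def make_hit(qstart, qend):
    return PairwiseHit(
        query_interval=GenomicInterval("anc", qstart, qend, "+"),
        subject_interval=GenomicInterval("s", 0, qend - qstart, "+"),
        score=qend - qstart,
        identity=0.95,
        aligned_columns=qend - qstart,
        gapped_columns=0,
        matches=qend - qstart,
        strand="+",
    )


def table_from_bool(gene, data, species=("sp1",), tetra=None):
    """data: n_cnes x (2 * n_species) array ordered (sp, a), (sp, b)..."""
    cols = pd.MultiIndex.from_tuples(
        [(sp, p) for sp in species for p in ("a", "b")], names=["species", "paralog"]
    )
    df = pd.DataFrame(np.asarray(data, bool),
                      index=[f"cne_{i}" for i in range(len(data))], columns=cols)
    t = pd.Series(tetra if tetra is not None else [False] * len(data), index=df.index)
    return PartitionTable(gene=gene, table=df, tetrapod_shared=t)


class TestBuildPartition:
    def test_single_environment_hit(self):
        cnes = [make_cne(100, 200)]
        hits = {("medaka", "a"): [], ("medaka", "b"): [make_hit(100, 200)]}
        t = build_partition(cnes, hits)
        assert not t.table.loc["cne_1", ("medaka", "a")]
        assert t.table.loc["cne_1", ("medaka", "b")]

    def test_forty_percent_overlap_is_absent(self):
        cnes = [make_cne(100, 200)]
        hits = {("medaka", "a"): [make_hit(100, 140)]}  # 40% of the CNE
        t = build_partition(cnes, hits)
        assert not t.table.loc["cne_1", ("medaka", "a")]
        half = build_partition(cnes, {("medaka", "a"): [make_hit(100, 150)]})
        assert half.table.loc["cne_1", ("medaka", "a")]

    def test_matches_bruteforce_reclassification(self, rng):
        """Randomised hit sets classified identically by a literal recount."""
        for _ in range(20):
            cnes = [make_cne(int(s), int(s) + 60) for s in rng.integers(0, 3000, 8) * 1]
            keys = [(f"sp{i}", p) for i in range(3) for p in "ab"]
            hits = {}
            for k in keys:
                hits[k] = [make_hit(int(s), int(s) + int(l))
                           for s, l in zip(rng.integers(0, 3000, 5), rng.integers(20, 120, 5))]
            t = build_partition(cnes, hits)
            for ci, cne in enumerate(cnes):
                for k in keys:
                    expected = any(
                        max(0, min(cne.interval.end, h.query_interval.end)
                            - max(cne.interval.start, h.query_interval.start))
                        >= 0.5 * cne.length
                        for h in hits[k]
                    )
                    assert t.table.iloc[ci][k] == expected


class TestSummarize:
    def test_counts_sum_to_total(self, rng):
        data = rng.random((20, 6)) < 0.5
        t = table_from_bool("g", data, species=("sp1", "sp2", "sp3"))
        s = summarize(t)
        assert s.a_only + s.b_only + s.both + s.neither == s.total_cnes == 20

    def test_relabeling_swaps_fractions(self, rng):
        data = rng.random((15, 4)) < 0.4
        t = table_from_bool("g", data, species=("sp1", "sp2"))
        s = summarize(t)
        sw = summarize(t.swap_paralogs())
        assert (s.a_only, s.b_only) == (sw.b_only, sw.a_only)
        assert s.one_paralog_fraction == sw.one_paralog_fraction

    def test_all_both_gives_zero(self):
        t = table_from_bool("g", np.ones((5, 2), bool))
        assert summarize(t).one_paralog_fraction == 0.0

    def test_empty_table_reports_not_available(self):
        t = table_from_bool("g", np.zeros((0, 2), bool))
        s = summarize(t)
        assert s.total_cnes == 0 and s.one_paralog_fraction is None

    def test_per_species_mode(self):
        data = [[True, False, False, True]]  # sp1: a-only; sp2: b-only
        t = table_from_bool("g", data, species=("sp1", "sp2"))
        per = summarize(t, "per_species")
        assert per["sp1"].a_only == 1 and per["sp2"].b_only == 1

    def test_round_trip_tsv(self, tmp_path, rng):
        data = rng.random((6, 4)) < 0.5
        t = table_from_bool("g", data, species=("sp1", "sp2"), tetra=[True] * 6)
        p = tmp_path / "part.tsv"
        partition_to_tsv(t, p)
        back = partition_from_tsv(p, gene="g")
        assert back.table.values.tolist() == t.table.values.tolist()
        assert back.tetrapod_shared.all()


class TestCountAsymmetryTest:
    def test_equal_counts_give_null(self):
        r = count_asymmetry_test([3, 5, 2], [3, 5, 2])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_paired_matches_closed_form(self):
        a = np.array([8.0, 31.0, 5.0, 21.0, 3.0])
        b = np.array([4.0, 5.0, 1.0, 16.0, 0.0])
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        from scipy.stats import t as tdist

        p_expected = 2 * tdist.sf(abs(t_expected), d.size - 1)
        r = count_asymmetry_test(a, b, paired=True)
        assert r.statistic == pytest.approx(t_expected, rel=1e-12)
        assert r.p_value == pytest.approx(p_expected, rel=1e-12)
        assert r.df == 4

    def test_unpaired_matches_closed_form(self):
        a, b = np.array([5.0, 7.0, 9.0]), np.array([1.0, 2.0, 3.0])
        sp = math.sqrt(((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4)
        t_expected = (a.mean() - b.mean()) / (sp * math.sqrt(1 / 3 + 1 / 3))
        r = count_asymmetry_test(a, b, paired=False)
        assert r.statistic == pytest.approx(t_expected, rel=1e-12)
        assert r.df == 4

    def test_unpaired_constant_equal_groups(self):
        r = count_asymmetry_test([1, 1], [1, 1], paired=False)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_zero_variance_nonzero_mean_flagged(self):
        r = count_asymmetry_test([5, 6, 7], [3, 4, 5], paired=True)
        assert r.zero_variance
        assert r.p_value < 1e-300

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            count_asymmetry_test([1], [2])
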