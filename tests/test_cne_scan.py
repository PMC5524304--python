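import numpy as np
import pytest

from conftest import random_block
from ohnocne.cne_scan import (
    CNE,
    ScanParams,
    column_conserved,
    conserved_columns,
    extend_seed,
    find_seeds,
    mask_block,
    scan,
)
from ohnocne.errors import ValidationError
from ohnocne.io_formats import AlignmentBlock, GenomicInterval, MaskTrack
from ohnocne.reference import brute_scan_spans
from ohnocne.synthetic_data import PlantedAlignmentSpec, make_planted_alignment


def block_from_columns(ref: str, others: list[str], classes=None) -> AlignmentBlock:
    rows = {"reference": ref}
    cls = {"reference": "reference"}
    for i, seq in enumerate(others):
        name = f"sp_{i}"
        rows[name] = seq
        cls[name] = (classes or {}).get(name, "fish")
    return AlignmentBlock(reference_species="reference", rows=rows,
                          ref_sequence_id="chrT", ref_start=0, species_class=cls)


class TestColumnConserved:
    def test_all_matching(self):
        b = block_from_columns("A", ["A"] * 10)
        assert column_conserved(b, 0, ScanParams())

    def test_two_of_ten_mismatching(self):
        b = block_from_columns("A", ["A"] * 8 + ["C", "G"])
        assert not column_conserved(b, 0, ScanParams())  # 0.20 >= 0.12

    def test_gaps_excluded_from_denominator(self):
        b = block_from_columns("A", ["A"] * 8 + ["-", "-"])
        assert column_conserved(b, 0, ScanParams())

    def test_too_few_informative_rows(self):
        b = block_from_columns("A", ["A", "A", "-", "-"])
        assert not column_conserved(b, 0, ScanParams(min_species_in_column=3))

    def test_out_of_range(self):
        b = block_from_columns("A", ["A"] * 3)
        with pytest.raises(IndexError):
            column_conserved(b, 5, ScanParams())

    def test_matches_independent_rule_on_enumerated_columns(self, rng):
        """Vectorised predicate equals a literal per-column rule on random columns."""
        params = ScanParams()
        for _ in range(300):
            n_sp = int(rng.integers(1, 8))
            ref = "ACGTN-"[int(rng.integers(0, 5))]  # ref gap handled separately
            col = [str(np.array(list("ACGTN-"))[rng.integers(0, 6)]) for _ in range(n_sp)]
            b = block_from_columns(ref, [c for c in col])
            # literal rule
            informative = [c for c in col if c != "-"]
            mism = [c for c in informative if c != ref or c == "N"]
            expected = (
                ref not in ("-", "N")
                and len(informative) >= params.min_species_in_column
                and len(mism) / len(informative) < params.column_substitution_threshold
            )
            assert column_conserved(b, 0, params) == expected


class TestSeedsAndExtension:
    def _cons_block(self, pattern: str) -> AlignmentBlock:
        """C = conserved column (all match), X = non-conserved (all differ)."""
        ref = "A" * len(pattern)
        other = "".join("A" if ch == "C" else "G" for ch in pattern)
        return block_from_columns(ref, [other] * 5)

    def test_ten_conserved_flanked_exact_identity(self):
        b = self._cons_block("XX" + "C" * 10 + "XX")
        assert find_seeds(b, ScanParams(seed_identity=1.0)) == [(2, 11)]

    def test_ten_conserved_flanked_default_identity(self):
        # at 90% the windows shifted one column into the flanks also qualify
        # (9/10 conserved), so the merged seed region spans them
        b = self._cons_block("XX" + "C" * 10 + "XX")
        assert find_seeds(b, ScanParams()) == [(1, 12)]

    def test_nine_of_ten_qualifies(self):
        b = self._cons_block("X" + "C" * 5 + "X" + "C" * 4 + "X")
        seeds = find_seeds(b, ScanParams())
        assert (1, 10) in seeds

    def test_no_conserved_columns(self):
        b = self._cons_block("X" * 20)
        assert find_seeds(b, ScanParams()) == []

    def test_extension_tolerates_internal_nonconserved(self):
        # seed of 10, then C C X C: all four included, ending on conserved
        b = self._cons_block("C" * 10 + "CCXC" + "XXXX")
        ext = extend_seed(b, (0, 9), ScanParams())
        assert ext == (0, 13)

    def test_trailing_nonconserved_trimmed(self):
        b = self._cons_block("X" + "C" * 10 + "XXXX")
        ext = extend_seed(b, (1, 10), ScanParams())
        assert ext == (1, 10)

    def test_scan_equals_bruteforce_on_random_blocks(self, rng):
        """Fast scanner reproduces exhaustive interval enumeration (small n)."""
        params = ScanParams(fish_presence_min_cover=0.0)
        for _ in range(40):
            n = int(rng.integers(12, 61))
            b = random_block(rng, n_columns=n, p_conserve=float(rng.uniform(0.3, 0.9)),
                             ref_gap_prob=0.05)
            expected = brute_scan_spans(b, params)
            got = scan(b, None, params)
            coords = b.ref_coordinates()
            exp_iv = []
            for s, e in expected:
                cols = coords[s : e + 1]
                cols = cols[cols >= 0]
                exp_iv.append((int(cols[0]), int(cols[-1]) + 1))
            assert [(c.interval.start, c.interval.end) for c in got] == exp_iv


class TestMasking:
    def test_mask_splits_block(self, rng):
        b = random_block(rng, n_columns=50)
        mask = MaskTrack([GenomicInterval("chrT", 20, 31)])
        subs = mask_block(b, mask)
        assert len(subs) == 2
        assert subs[0].n_columns == 20
        assert subs[1].n_columns == 19
        assert subs[1].ref_start == 31

    def test_empty_mask(self, rng):
        b = random_block(rng, n_columns=30)
        assert mask_block(b, MaskTrack([]))[0].rows == b.rows

    def test_mask_covering_everything(self, rng):
        b = random_block(rng, n_columns=30)
        assert mask_block(b, MaskTrack([GenomicInterval("chrT", 0, 30)])) == []

    def test_no_element_overlaps_mask(self, rng):
        spec = PlantedAlignmentSpec(length=2000, cne_lengths=[30, 30], seed=5,
                                    cne_positions=[500, 1400],
                                    mask_intervals=[(900, 1100)])
        block, _ = make_planted_alignment(spec)
        mask = MaskTrack([GenomicInterval("ref_region", 900, 1100)])
        for c in scan(block, mask):
            assert c.interval.overlap(GenomicInterval("ref_region", 900, 1100)) == 0


class TestScanFilters:
    def test_planted_element_recovered(self):
        spec = PlantedAlignmentSpec(length=2000, cne_lengths=[25], cne_positions=[1000],
                                    seed=11)
        block, truth = make_planted_alignment(spec)
        cnes = scan(block, None)
        hits = [c for c in cnes if c.interval.overlap(truth[0]) > 0]
        assert len(hits) == 1

    def test_tetrapod_only_element_dropped(self):
        spec = PlantedAlignmentSpec(length=1500, cne_lengths=[30], cne_positions=[700],
                                    gap_prob=0.0, seed=2)
        block, truth = make_planted_alignment(spec)
        rows = dict(block.rows)
        for sp, cls in block.species_class.items():
            if cls == "fish":  # gap out every fish row across the element
                s = list(rows[sp])
                for k in range(truth[0].start, truth[0].end):
                    s[k] = "-"
                rows[sp] = "".join(s)
        gapped = AlignmentBlock("reference", rows, "ref_region", 0,
                                dict(block.species_class))
        found = scan(gapped, None)
        assert all(c.interval.overlap(truth[0]) == 0 for c in found)
        # ablation: disabling the fish-presence filter restores the element
        found_all = scan(gapped, None, ScanParams(fish_presence_min_cover=0.0))
        assert any(c.interval.overlap(truth[0]) > 0 for c in found_all)

    def test_no_fish_species_is_config_error(self):
        b = block_from_columns("AAAA", ["AAAA"] * 4,
                               classes={f"sp_{i}": "tetrapod" for i in range(4)})
        with pytest.raises(ValidationError):
            scan(b, None)

    def test_threshold_monotonicity(self, rng):
        """Lowering the substitution threshold never increases CNE coverage."""
        b = random_block(rng, n_columns=60, p_conserve=0.7)
        cover = []
        for thr in (0.30, 0.12, 0.05):
            params = ScanParams(column_substitution_threshold=thr,
                                fish_presence_min_cover=0.0)
            cnes = scan(b, None, params)
            cover.append(sum(c.length for c in cnes))
        assert cover[0] >= cover[1] >= cover[2]

    def test_cne_score_and_invariants(self, rng):
        b = random_block(rng, n_columns=60, p_conserve=0.9)
        for c in scan(b, None, ScanParams(fish_presence_min_cover=0.0)):
            assert isinstance(c, CNE)
            assert c.conserved_column_count <= c.length
            assert 0 < c.score_percent <= 100


def test_conserved_columns_vector_matches_scalar(rng):
    b = random_block(rng, n_columns=25)
    params = ScanParams()
    vec = conserved_columns(b, params)
    for j in range(b.n_columns):
        assert vec[j] == column_conserved(b, j, params)
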