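import datetime

import numpy as np
import pytest
from Bio import Align

from conftest import mutate, random_protein
from pvpkit.core_io import NON_PVP, PVP, ProteinRecord
from pvpkit.splits import (
    DatasetSplit,
    compute_pairwise_scores,
    max_cross_split_score,
    pairwise_similarity,
    split_by_imbalance,
    split_by_similarity,
    split_by_time,
    symmetric_score,
)
from pvpkit.synthetic import FamilySpec, gen_protein_families


def strict_aligner() -> Align.PairwiseAligner:
    """match +1 / mismatch -10 / gap -10: optimal local alignments are pure
    exact-match runs, so the best alignment is derivable by enumeration."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -10.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -10.0
    return aligner


def sw_oracle_score(a: str, b: str) -> int:
    """Brute-force Smith-Waterman DP under the strict scoring above."""
    la, lb = len(a), len(b)
    h = np.zeros((la + 1, lb + 1))
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = h[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else -10)
            h[i, j] = max(0, diag, h[i - 1, j] - 10, h[i, j - 1] - 10)
    return int(h.max())


class TestPairwiseSimilarity:
    def test_identical_sequences(self):
        rng = np.random.default_rng(0)
        s = random_protein(rng, 50)
        sc = pairwise_similarity(s, s)
        assert (sc.identity, sc.coverage, sc.score) == (1.0, 1.0, 1.0)

    def test_unalignable_pair_scores_zero(self):
        assert pairwise_similarity("AAAAAAAA", "WWWWWWWW").score == 0.0

    def test_embedded_exact_match_half_coverage(self):
        """A 100-residue query whose middle 50 residues exactly match the
        subject: identity 1, coverage 0.5 under strict scoring."""
        rng = np.random.default_rng(3)
        core = random_protein(rng, 50)
        query = random_protein(rng, 25) + core + random_protein(rng, 25)
        sc = pairwise_similarity(query, core, aligner=strict_aligner())
        assert sc.identity == 1.0
        assert sc.coverage == pytest.approx(0.5)
        assert sc.score == pytest.approx(0.5)

    def test_matches_dp_oracle_on_random_pairs(self):
        """identity x coverage agrees with a quadratic DP oracle: under the
        strict scoring the optimal alignment has score == #matches - penalties,
        and for random short pairs it is a pure match run of length h_max."""
        rng = np.random.default_rng(7)
        aligner = strict_aligner()
        for _ in range(100):
            a = random_protein(rng, int(rng.integers(5, 31)))
            b = random_protein(rng, int(rng.integers(5, 31)))
            best = sw_oracle_score(a, b)
            sc = pairwise_similarity(a, b, aligner=aligner)
            if best == 0:
                assert sc.score == 0.0
            else:
                assert sc.identity == 1.0
                assert sc.score == pytest.approx(best / len(a))

    def test_score_bounded_by_components(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b = random_protein(rng, 40), mutate(random_protein(rng, 40), 0.3, rng)
            sc = pairwise_similarity(a, b)
            assert 0 <= sc.score <= min(sc.identity, sc.coverage) <= 1
            assert sc.score == sc.identity * sc.coverage

    def test_symmetric_score_is_max_over_orderings(self):
        rng = np.random.default_rng(5)
        long = random_protein(rng, 80)
        short = long[20:60]
        s_ab = pairwise_similarity(long, short).score
        s_ba = pairwise_similarity(short, long).score
        assert symmetric_score(long, short) == max(s_ab, s_ba)


def _dated(i, date, label=PVP):
    return ProteinRecord(
        f"r{i}", "MKQNACDEF", f"rec {i}", release_date=date, binary_label=label
    )


class TestSplitByTime:
    CUTOFF = datetime.date(2020, 12, 1)

    def test_strict_cutoff(self):
        records = [
            _dated(0, datetime.date(2019, 5, 1)),
            _dated(1, datetime.date(2021, 3, 1)),
            _dated(2, datetime.date(2020, 12, 1)),  # on the cutoff -> test
        ]
        split = split_by_time(records, self.CUTOFF)
        assert split.train_ids == ("r0",)
        assert set(split.test_ids) == {"r1", "r2"}

    def test_missing_date_names_record(self):
        records = [_dated(0, datetime.date(2019, 1, 1)),
                   ProteinRecord("nodate", "MK", "x")]
        with pytest.raises(ValueError, match="nodate"):
            split_by_time(records, self.CUTOFF)

    def test_all_before_cutoff_warns_empty_test(self, caplog):
        records = [_dated(i, datetime.date(2019, 1, 1)) for i in range(3)]
        with caplog.at_level("WARNING"):
            split = split_by_time(records, self.CUTOFF)
        assert split.test_ids == ()
        assert "empty test set" in caplog.text

    def test_binary_balancing_downsamples_majority(self):
        records = [
            _dated(i, datetime.date(2019, 1, 1), PVP if i < 10 else NON_PVP)
            for i in range(40)
        ] + [_dated(100 + i, datetime.date(2021, 1, 1), PVP if i < 4 else NON_PVP)
             for i in range(12)]
        split = split_by_time(records, self.CUTOFF, balance_binary=True, seed=0)
        by_id = {r.id: r for r in records}
        train_pvp = sum(1 for i in split.train_ids if by_id[i].binary_label == PVP)
        train_non = sum(1 for i in split.train_ids if by_id[i].binary_label == NON_PVP)
        assert train_pvp == train_non == 10
        test_pvp = sum(1 for i in split.test_ids if by_id[i].binary_label == PVP)
        test_non = sum(1 for i in split.test_ids if by_id[i].binary_label == NON_PVP)
        assert test_pvp == test_non == 4

    def test_same_seed_reproducible_and_union_stable(self):
        records = [
            _dated(i, datetime.date(2019, 1, 1) if i % 2 else datetime.date(2021, 1, 1))
            for i in range(10)
        ]
        s1 = split_by_time(records, self.CUTOFF, seed=1)
        s2 = split_by_time(records, self.CUTOFF, seed=1)
        s3 = split_by_time(records, self.CUTOFF, seed=2)
        assert s1.train_ids == s2.train_ids and s1.test_ids == s2.test_ids
        assert set(s1.train_ids + s1.test_ids) == set(s3.train_ids + s3.test_ids)


class TestSplitBySimilarity:
    def test_identical_sequences_co_assigned(self):
        records = [
            ProteinRecord("a", "MKQNACDEFMKQNACDEF" * 3, "x"),
            ProteinRecord("b", "MKQNACDEFMKQNACDEF" * 3, "x"),
        ] + [ProteinRecord(f"z{i}", random_protein(np.random.default_rng(i), 30), "x")
             for i in range(8)]
        split = split_by_similarity(records, threshold=0.9, test_fraction=0.3, seed=0)
        same_side = ({"a", "b"} <= set(split.train_ids)) or (
            {"a", "b"} <= set(split.test_ids)
        )
        assert same_side

    def test_all_zero_scores_hit_per_class_target(self):
        rng = np.random.default_rng(1)
        records = [ProteinRecord(f"p{i}", random_protein(rng, 12), "x") for i in range(10)]
        scores = {frozenset((a.id, b.id)): 0.0
                  for i, a in enumerate(records) for b in records[i + 1:]}
        split = split_by_similarity(records, 0.4, test_fraction=0.2, seed=3, scores=scores)
        assert len(split.test_ids) == 2  # ceil(0.2 * 10)

    def test_whole_family_lands_in_test(self):
        records = gen_protein_families(FamilySpec(3, 5, 100, 0.02, seed=4))
        scores = compute_pairwise_scores(records)
        split = split_by_similarity(records, 0.4, test_fraction=0.33, seed=0, scores=scores)
        assert len(split.test_ids) == 5
        families = {pid.split("_")[0] for pid in split.test_ids}
        assert len(families) == 1  # one intact family
        assert max_cross_split_score(split, records, scores) <= 0.4

    def test_giant_component_raises(self):
        records = gen_protein_families(FamilySpec(1, 6, 80, 0.02, seed=5))
        with pytest.raises(ValueError, match="raise the threshold"):
            split_by_similarity(records, 0.4, test_fraction=0.2, seed=0)

    def test_manifest_round_trip(self, tmp_path):
        records = gen_protein_families(FamilySpec(3, 5, 60, 0.02, seed=6))
        split = split_by_similarity(records, 0.5, test_fraction=0.33, seed=2)
        path = tmp_path / "split.tsv"
        split.save(path)
        back = DatasetSplit.load(path)
        assert back.train_ids == split.train_ids
        assert back.test_ids == split.test_ids
        assert back.protocol == "similarity"


class TestSplitByImbalance:
    def _records(self, n_pvp, n_non):
        return [
            ProteinRecord(f"v{i}", "MKQN", "x", binary_label=PVP) for i in range(n_pvp)
        ] + [
            ProteinRecord(f"n{i}", "MKQN", "x", binary_label=NON_PVP)
            for i in range(n_non)
        ]

    def test_arithmetic_example(self):
        split = split_by_imbalance(self._records(100, 900), 3, train_fraction=0.8, seed=0)
        def counts(ids):
            pvp = sum(1 for i in ids if i.startswith("v"))
            return pvp, len(ids) - pvp
        assert counts(split.train_ids) == (80, 240)
        assert counts(split.test_ids) == (20, 60)

    @pytest.mark.parametrize("r", [1, 3, 5, 9])
    def test_ratio_preserved_within_one(self, r):
        split = split_by_imbalance(self._records(40, 400), r, seed=r)
        for ids in (split.train_ids, split.test_ids):
            pvp = sum(1 for i in ids if i.startswith("v"))
            non = len(ids) - pvp
            assert abs(non - r * pvp) <= r

    def test_insufficient_non_pvp_reports_max_feasible(self):
        with pytest.raises(ValueError, match="maximum feasible is 2"):
            split_by_imbalance(self._records(100, 250), 5)

    def test_reproducible(self):
        records = self._records(30, 200)
        s1 = split_by_imbalance(records, 3, seed=9)
        s2 = split_by_imbalance(records, 3, seed=9)
        assert s1.train_ids == s2.train_ids and s1.test_ids == s2.test_ids
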