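import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from barcodegap.distances import (
    DistanceMatrix,
    barcode_gap,
    distance_matrix,
    k2p,
    partition,
    summarize,
)
from barcodegap.io_metadata import LocusAlignment, SampleRecord, concatenate
from barcodegap.site_stats import classify_sites

DNA = st.text(alphabet="ACGT-N", min_size=60, max_size=120)


class TestK2P:
    def test_identical_sequences_zero(self):
        pc = k2p("ACGT" * 30, "ACGT" * 30)
        assert (pc.P, pc.Q, pc.d) == (0.0, 0.0, 0.0)

    def test_known_counts_closed_form(self):
        # 100 comparable columns, 10 transitions, 5 transversions
        seq_a = "A" * 100
        seq_b = "G" * 10 + "C" * 5 + "A" * 85
        pc = k2p(seq_a, seq_b)
        expected = -0.5 * math.log((1 - 2 * 0.10 - 0.05) * math.sqrt(1 - 2 * 0.05))
        assert pc.n_compared == 100 and pc.P == 0.10 and pc.Q == 0.05
        assert pc.d == pytest.approx(0.1701811651403471, abs=1e-15)
        assert pc.d == pytest.approx(expected, abs=1e-15)

    def test_saturation_is_undefined(self):
        # P = 0.5, Q = 0: log argument hits zero
        pc = k2p("A" * 100, "G" * 50 + "A" * 50)
        assert pc.d is None and pc.reason == "saturated"

    def test_min_overlap_and_empty_overlap(self):
        pc = k2p("A" * 30 + "-" * 70, "-" * 70 + "A" * 30, min_overlap=1)
        assert pc.d is None and "no comparable" in pc.reason
        pc = k2p("A" * 40 + "-" * 60, "A" * 100, min_overlap=50)
        assert pc.d is None and "overlap 40" in pc.reason

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            k2p("ACGT", "ACG")

    def test_ambiguity_codes_excluded_from_comparison(self):
        pc = k2p("AAAANNNNN" + "A" * 91, "AAAATTTTT" + "A" * 91, min_overlap=10)
        assert pc.n_compared == 95 and pc.P == 0.0 and pc.Q == 0.0

    def test_matches_per_column_counting_oracle(self, rng):
        for _ in range(200):
            a = "".join(rng.choice(list("ACGT-N"), 150))
            b = "".join(rng.choice(list("ACGT-N"), 150))
            pc = k2p(a, b, min_overlap=1)
            n, d = oracles.k2p_by_counting(a, b, min_overlap=1)
            assert pc.n_compared == n
            if d is None:
                assert pc.d is None
            else:
                assert pc.d == pytest.approx(d, abs=1e-12)

    @given(DNA, DNA, st.integers(0, 2**31 - 1))
    def test_symmetry_and_column_permutation_invariance(self, a, b, seed):
        L = min(len(a), len(b))
        a, b = a[:L], b[:L]
        fwd = k2p(a, b, min_overlap=1)
        rev = k2p(b, a, min_overlap=1)
        assert (fwd.P, fwd.Q, fwd.d) == (rev.P, rev.Q, rev.d)
        perm = np.random.default_rng(seed).permutation(L)
        pa = "".join(a[i] for i in perm)
        pb = "".join(b[i] for i in perm)
        prm = k2p(pa, pb, min_overlap=1)
        assert (fwd.P, fwd.Q, fwd.d) == (prm.P, prm.Q, prm.d)

    @given(DNA, DNA)
    def test_correction_never_below_observed_divergence(self, a, b):
        L = min(len(a), len(b))
        pc = k2p(a[:L], b[:L], min_overlap=1)
        if pc.d is not None:
            assert pc.d >= pc.P + pc.Q - 1e-12
            if pc.P + pc.Q == 0:
                assert pc.d == 0.0


class TestDistanceMatrix:
    def test_identical_rows_zero_matrix(self):
        aln = LocusAlignment("x", {f"s{i}": "ACGT" * 30 for i in range(3)})
        m = distance_matrix(aln)
        assert np.allclose(m.values, 0.0)

    def test_symmetry_zero_diagonal_on_simulated_data(self):
        from barcodegap.synthetic_data import generate_dataset, preset

        ds = generate_dataset(preset("gapped", 2))
        m = distance_matrix(ds.alignments["locusA"])
        assert np.allclose(m.values, m.values.T, equal_nan=True)
        assert np.all(np.diag(m.values) == 0.0)
        finite = m.values[~np.isnan(m.values)]
        assert (finite >= 0).all()

    def test_concatenated_missing_locus_uses_shared_columns(self, rng):
        base1 = rng.choice(list("ACGT"), 120)
        base2 = rng.choice(list("ACGT"), 80)

        def mutate(base, k):
            seq = base.copy()
            for pos in rng.choice(len(base), k, replace=False):
                seq[pos] = "ACGT"["ACGT".index(seq[pos]) - 1]
            return "".join(seq)

        l1 = {f"s{i}": mutate(base1, 5 * i) for i in range(3)}
        l2 = {f"s{i}": mutate(base2, 4 * i) for i in range(2)}
        samples = [SampleRecord(f"s{i}", f"sp{i}", "sec1") for i in range(3)]
        cat = concatenate(
            [LocusAlignment("l1", l1), LocusAlignment("l2", l2)], samples
        ).as_locus_alignment()
        m = distance_matrix(cat)
        # s2 lacks l2: distance to s0 must equal k2p over l1 alone
        expect = k2p(l1["s0"], l1["s2"]).d
        assert m.get("s0", "s2") == pytest.approx(expect, abs=1e-15)

    def test_imputation_fills_with_max_finite(self):
        vals = np.array([[0, 0.1, np.nan], [0.1, 0, 0.3], [np.nan, 0.3, 0]])
        m = DistanceMatrix(["a", "b", "c"], vals, {(0, 2): "overlap"})
        filled, n = m.imputed()
        assert n == 1 and filled[0, 2] == 0.3


class TestPartition:
    def _demo(self):
        ids = ["a1", "a2", "b1", "b2", "c1"]
        vals = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                if i != j:
                    vals[i, j] = 0.01
        vals[0, 1] = vals[1, 0] = 0.0
        vals[2, 3] = vals[3, 2] = 0.0
        samples = [
            SampleRecord("a1", "spA", "s1"),
            SampleRecord("a2", "spA", "s1"),
            SampleRecord("b1", "spB", "s1"),
            SampleRecord("b2", "spB", "s1"),
            SampleRecord("c1", "spC", "s2"),
        ]
        return DistanceMatrix(ids, vals), samples

    def test_split_and_singleton_exclusion(self):
        m, samples = self._demo()
        part = partition(m, samples)
        assert sorted(d for _, d in part.intra) == [0.0, 0.0]
        assert len(part.inter) == 8
        assert part.excluded_singletons == ["spC"]
        assert all(d == 0.01 for _, _, d in part.inter)

    def test_pair_counts_reconcile_on_simulated_data(self):
        from barcodegap.synthetic_data import OUTGROUP_ID, generate_dataset, preset

        ds = generate_dataset(preset("gapped", 4))
        aln = ds.alignments["locusA"].subset(
            [s for s in ds.alignments["locusA"].sample_ids if s != OUTGROUP_ID]
        )
        m = distance_matrix(aln)
        recs = [r for r in ds.records if r.sample_id in aln.rows]
        part = partition(m, recs)
        n = m.n
        singleton_intra_pairs = 0  # singleton species contribute no intra pairs
        assert (
            len(part.intra) + len(part.inter) + part.n_undefined + singleton_intra_pairs
            == n * (n - 1) // 2
        )

    def test_unlabeled_sample_errors(self):
        m, samples = self._demo()
        with pytest.raises(ValueError, match="without species"):
            partition(m, samples[:-1])


class TestBarcodeGap:
    def test_perfect_gap(self):
        m, samples = self._with_gap(intra=0.001, inter=0.05)
        part = partition(m, samples)
        rep = barcode_gap(part)
        assert rep.overlap_fraction == 0.0
        assert all(g > 0 for g in rep.local_gaps.values())
        assert rep.intra_freq.sum() == pytest.approx(1.0)
        assert rep.inter_freq.sum() == pytest.approx(1.0)

    def test_identical_distributions_overlap_near_one(self):
        m, samples = self._with_gap(intra=0.02, inter=0.02)
        rep = barcode_gap(partition(m, samples))
        assert rep.overlap_fraction == 1.0

    def test_all_singletons_note(self):
        ids = ["a1", "b1"]
        vals = np.array([[0.0, 0.01], [0.01, 0.0]])
        samples = [SampleRecord("a1", "spA", "s"), SampleRecord("b1", "spB", "s")]
        rep = barcode_gap(partition(DistanceMatrix(ids, vals), samples))
        assert rep.overlap_fraction is None and "singleton" in rep.note

    @staticmethod
    def _with_gap(intra, inter):
        ids = ["a1", "a2", "b1", "b2"]
        vals = np.full((4, 4), inter)
        np.fill_diagonal(vals, 0.0)
        vals[0, 1] = vals[1, 0] = intra
        vals[2, 3] = vals[3, 2] = intra
        samples = [
            SampleRecord("a1", "spA", "s"),
            SampleRecord("a2", "spA", "s"),
            SampleRecord("b1", "spB", "s"),
            SampleRecord("b2", "spB", "s"),
        ]
        return DistanceMatrix(ids, vals), samples


class TestSummarize:
    def test_all_identical_alignment(self):
        rows = {f"s{i}": "ACGT" * 40 for i in range(4)}
        aln = LocusAlignment("x", rows)
        samples = [
            SampleRecord("s0", "spA", "s"),
            SampleRecord("s1", "spA", "s"),
            SampleRecord("s2", "spB", "s"),
            SampleRecord("s3", "spB", "s"),
        ]
        m = distance_matrix(aln)
        part = partition(m, samples)
        s = summarize(aln, m, part, classify_sites(aln), samples)
        assert s.n_variable == 0 and s.mean_intra == 0.0 and s.mean_inter == 0.0

    def test_means_match_direct_recomputation(self, two_species_alignment):
        aln, records = two_species_alignment
        m = distance_matrix(aln)
        part = partition(m, records)
        s = summarize(aln, m, part, classify_sites(aln), records)
        assert s.mean_intra == pytest.approx(
            100 * np.mean([d for _, d in part.intra])
        )
        assert s.mean_inter == pytest.approx(
            100 * np.mean([d for _, _, d in part.inter])
        )
        assert s.min_rate <= s.mean_intra <= s.max_rate
        row = s.table_row()
        assert row["n_species"] == 2 and row["n_samples"] == 6
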