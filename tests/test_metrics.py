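import math

import pytest
from hypothesis import given, settings, strategies as st

from kmercomp import (
    DNA,
    KmerSpec,
    SequenceRecord,
    bray_curtis,
    compute_score,
    cosine,
    count_kmers,
    d2_distance,
    d2_raw,
    d2s,
    d2star,
    fit_background,
    get_metric,
    minkowski_family,
    ngd,
    normalised_canberra,
    to_frequencies,
)
from kmercomp.kmer_core import CountVector, FrequencyVector
from conftest import dna_record
from oracles import naive_d2star_d2s


SPEC1 = KmerSpec(DNA, 1)


def counts_of(seq, k=1):
    return count_kmers(SequenceRecord("s", seq, alphabet=DNA), KmerSpec(DNA, k))


# r="AA", q="AAC" at k=1: counts {A:2} and {A:2, C:1}
CR = counts_of("AA")
CQ = counts_of("AAC")


class TestCountMetrics:
    def test_d2_raw_hand_value(self):
        assert d2_raw(CR, CQ) == 4.0

    def test_d2_raw_disjoint_and_self(self):
        ca, cb = counts_of("AAA"), counts_of("CCC")
        assert d2_raw(ca, cb) == 0.0
        assert d2_raw(CQ, CQ) == 2 * 2 + 1 * 1

    def test_cosine_hand_value(self):
        assert cosine(CR, CQ) == pytest.approx(4 / (2 * math.sqrt(5)))

    def test_cosine_identity_and_orthogonal(self):
        assert cosine(CQ, CQ) == pytest.approx(1.0)
        assert cosine(counts_of("AAA"), counts_of("CCC")) == 0.0

    def test_cosine_zero_vector_raises(self):
        empty = CountVector(spec=SPEC1, counts={}, total=0)
        with pytest.raises(ValueError, match="zero count vector"):
            cosine(empty, CQ)

    def test_d2_distance_values(self):
        assert d2_distance(CQ, CQ) == pytest.approx(0.0)
        assert d2_distance(counts_of("AAA"), counts_of("CCC")) == pytest.approx(0.5)
        assert d2_distance(CR, CQ) == pytest.approx(0.5 * (1 - 4 / (2 * math.sqrt(5))))

    def test_bray_curtis_hand_value(self):
        assert bray_curtis(CR, CQ) == pytest.approx(1 - 2 * 2 / (2 + 3))

    def test_bray_curtis_extremes(self):
        assert bray_curtis(CQ, CQ) == 0.0
        assert bray_curtis(counts_of("AAA"), counts_of("CCC")) == 1.0

    def test_ngd_hand_value(self):
        assert ngd(CR, CQ) == pytest.approx((3 - 2) / (5 - 2))

    def test_ngd_identity(self):
        assert ngd(CQ, CQ) == 0.0

    def test_ngd_length_mismatch_bound(self):
        # with very unequal totals, NGD >= (S_long - S_short) / S_long
        short = counts_of("ACGT" * 3, k=2)
        long_ = counts_of("ACGT" * 500, k=2)
        bound = (long_.total - short.total) / long_.total
        assert ngd(short, long_) >= bound
        assert ngd(short, long_) > 0.9

    def test_spec_mismatch_raises(self):
        with pytest.raises(ValueError, match="different KmerSpecs"):
            d2_raw(counts_of("ACGT", k=1), counts_of("ACGT", k=2))


class TestFrequencyMetrics:
    FR = FrequencyVector(spec=SPEC1, freqs={"A": 1.0}, total_kmers=3)
    FQ = FrequencyVector(spec=SPEC1, freqs={"A": 2 / 3, "C": 1 / 3}, total_kmers=3)

    def test_hand_values(self):
        assert minkowski_family(self.FR, self.FQ, "cheby") == pytest.approx(1 / 3)
        assert minkowski_family(self.FR, self.FQ, "manh") == pytest.approx(2 / 3)
        assert minkowski_family(self.FR, self.FQ, "euclid") == pytest.approx(math.sqrt(2) / 3)

    def test_identity(self):
        for which in ("euclid", "manh", "cheby"):
            assert minkowski_family(self.FQ, self.FQ, which) == 0.0

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            minkowski_family(self.FR, self.FQ, "hamming")

    def test_canberra_hand_value(self):
        # word A: |1-2/3|/(1+2/3) = 0.2; word C: 1.0; mean = 0.6
        assert normalised_canberra(self.FR, self.FQ) == pytest.approx(0.6)

    def test_canberra_extremes(self):
        assert normalised_canberra(self.FQ, self.FQ) == 0.0
        fa = FrequencyVector(spec=SPEC1, freqs={"A": 1.0}, total_kmers=2)
        fb = FrequencyVector(spec=SPEC1, freqs={"C": 1.0}, total_kmers=2)
        assert normalised_canberra(fa, fb) == 1.0
        empty = FrequencyVector(spec=SPEC1, freqs={}, total_kmers=0)
        with pytest.raises(ValueError):
            normalised_canberra(empty, empty)


class TestMarkovMetrics:
    def test_identity_is_zero(self):
        r = SequenceRecord("r", "ACGTTGCAACGT", alphabet=DNA)
        cv = count_kmers(r, KmerSpec(DNA, 2))
        bg = fit_background(r)
        assert d2star(cv, bg, cv, bg) == pytest.approx(0.0, abs=1e-12)
        assert d2s(cv, bg, cv, bg) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("r,q,k", [("ACGTACGT", "ACGTACGA", 2), ("ACGTTGCA", "AAACCCGG", 3)])
    def test_oracle_pinned_values(self, r, q, k):
        rr = SequenceRecord("r", r, alphabet=DNA)
        qq = SequenceRecord("q", q, alphabet=DNA)
        spec = KmerSpec(DNA, k)
        cr, cq = count_kmers(rr, spec), count_kmers(qq, spec)
        br, bq = fit_background(rr), fit_background(qq)
        exp_star, exp_s = naive_d2star_d2s(r, q, k)
        assert d2star(cr, br, cq, bq) == pytest.approx(exp_star, rel=1e-12)
        assert d2s(cr, br, cq, bq) == pytest.approx(exp_s, rel=1e-12)

    def test_regression_pinned_values(self):
        # frozen from an independent straight-line evaluation of the formulas
        rr = SequenceRecord("r", "ACGTACGT", alphabet=DNA)
        qq = SequenceRecord("q", "ACGTACGA", alphabet=DNA)
        spec = KmerSpec(DNA, 2)
        cr, cq = count_kmers(rr, spec), count_kmers(qq, spec)
        br, bq = fit_background(rr), fit_background(qq)
        assert d2star(cr, br, cq, bq) == pytest.approx(0.0287333103262758, abs=1e-12)
        assert d2s(cr, br, cq, bq) == pytest.approx(0.0823633989741122, abs=1e-12)

    def test_unrelated_sequences_near_half(self, rng):
        # centred vectors of unrelated iid sequences are uncorrelated
        spec = KmerSpec(DNA, 3)
        for name in ("d2star", "d2s"):
            vals = []
            for _ in range(200):
                a, b = dna_record(rng, 600, "a"), dna_record(rng, 600, "b")
                ca, cb = count_kmers(a, spec), count_kmers(b, spec)
                ba, bb = fit_background(a), fit_background(b)
                fn = d2star if name == "d2star" else d2s
                vals.append(fn(ca, ba, cb, bb))
            mean = sum(vals) / len(vals)
            assert mean == pytest.approx(0.5, abs=0.02), name

    def test_protein_rejected(self):
        from kmercomp import PROTEIN

        rec = SequenceRecord("p", "ACDE", alphabet=PROTEIN)
        spec = KmerSpec(PROTEIN, 1)
        cv = count_kmers(rec, spec)
        with pytest.raises(ValueError, match="DNA only"):
            d2star(cv, None, cv, None)


@st.composite
def dna_pair(draw):
    a = draw(st.text(alphabet="ACGT", min_size=6, max_size=40))
    b = draw(st.text(alphabet="ACGT", min_size=6, max_size=40))
    return a, b


class TestMetricProperties:
    NAMES = ["d2raw", "d2", "euclid", "manh", "cheby", "ncanb", "bc", "ngd", "d2star", "d2s"]

    @staticmethod
    def _score(name, a, b, k=2):
        ra = SequenceRecord("a", a, alphabet=DNA)
        rb = SequenceRecord("b", b, alphabet=DNA)
        spec = KmerSpec(DNA, k)
        ca, cb = count_kmers(ra, spec), count_kmers(rb, spec)
        fa, fb = to_frequencies(ca), to_frequencies(cb)
        ba, bb = fit_background(ra), fit_background(rb)
        return compute_score(name, ca, cb, fa, fb, ba, bb)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pair=dna_pair())
    def test_symmetry(self, pair):
        a, b = pair
        for name in self.NAMES:
            try:
                s_ab = self._score(name, a, b)
                s_ba = self._score(name, b, a)
            except ValueError:
                continue  # degenerate (zero centred vector etc.)
            assert s_ab == pytest.approx(s_ba, rel=1e-9), name

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=st.text(alphabet="ACGT", min_size=6, max_size=40))
    def test_identity_and_range(self, a):
        ranges = {
            "d2": (0, 1), "euclid": (0, math.sqrt(2)), "manh": (0, 2), "cheby": (0, 1),
            "ncanb": (0, 1), "bc": (0, 1), "ngd": (0, 1), "d2star": (0, 1), "d2s": (0, 1),
        }
        for name, (lo, hi) in ranges.items():
            try:
                self_score = self._score(name, a, a)
            except ValueError:
                continue
            assert self_score == pytest.approx(0.0, abs=1e-9), name
            assert lo - 1e-9 <= self_score <= hi + 1e-9

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pair=dna_pair())
    def test_range_on_random_pairs(self, pair):
        a, b = pair
        ranges = {
            "d2": (0, 1), "euclid": (0, math.sqrt(2)), "manh": (0, 2), "cheby": (0, 1),
            "ncanb": (0, 1), "bc": (0, 1), "ngd": (0, 1), "d2star": (0, 1), "d2s": (0, 1),
        }
        for name, (lo, hi) in ranges.items():
            try:
                s = self._score(name, a, b)
            except ValueError:
                continue
            assert lo - 1e-9 <= s <= hi + 1e-9, name

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pair=dna_pair())
    def test_cosine_equals_normalised_d2raw(self, pair):
        a, b = pair
        spec = KmerSpec(DNA, 2)
        ca = count_kmers(SequenceRecord("a", a, alphabet=DNA), spec)
        cb = count_kmers(SequenceRecord("b", b, alphabet=DNA), spec)
        norm = lambda c: math.sqrt(sum(v * v for v in c.counts.values()))
        if norm(ca) == 0 or norm(cb) == 0:
            return
        assert cosine(ca, cb) == pytest.approx(d2_raw(ca, cb) / (norm(ca) * norm(cb)), rel=1e-12)


class TestMetricRegistry:
    def test_alias(self):
        assert get_metric("ncamb").name == "ncanb"

    def test_unknown(self):
        with pytest.raises(ValueError):
            get_metric("blast")

    def test_orientation(self):
        assert not get_metric("d2raw").lower_is_similar
        assert get_metric("ngd").lower_is_similar
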