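"""CUB metric formulas against hand computations and a brute-force oracle."""

import math
import random

import numpy as np
import pandas as pd
import pytest

from codonlm import (
    AMINO_ACIDS,
    STANDARD_CODE,
    BenchmarkTable,
    SequencePair,
    benchmark_rank,
    biased_codon_model,
    compute_usage_table,
    csi,
    gc3_content,
    gc_content,
    generate_corpus,
    jaccard_similarity,
    metric_outcome_correlations,
    minmax_profile,
    rare_codon_stats,
    relative_adaptiveness,
    sequence_identity,
    uniform_codon_model,
)
from codonlm.metrics import UnscoredCodonError, pairwise_matrices, sequence_report
from codonlm.synthetic import SyntheticGenomeSpec


@pytest.fixture(scope="module")
def table():
    spec = SyntheticGenomeSpec(
        n_sequences=300, min_length=20, max_length=60,
        codon_model=biased_codon_model(2.0), seed=31,
    )
    return compute_usage_table(generate_corpus(spec))


# ---------------------------------------------------------------------------
# Independent brute-force oracle: straightforward per-codon loops written
# directly from the defining formulas, sharing no code with the package path.
# ---------------------------------------------------------------------------

def _codons(cds):
    cs = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    return cs[:-1] if cs[-1] in ("TAA", "TAG", "TGA") else cs


def _aa_of(codon):
    return STANDARD_CODE.table[codon]


def oracle_w(table, codon):
    aa = _aa_of(codon)
    fam_x = [table.x[(aa, c)] for c in STANDARD_CODE.families[aa]]
    return table.x[(aa, codon)] / max(fam_x)


def oracle_csi(table, cds):
    ws = [oracle_w(table, c) for c in _codons(cds)]
    return math.exp(sum(math.log(w) for w in ws) / len(ws))


def oracle_gc(cds):
    return sum(1 for b in cds if b in "GC") / len(cds)


def oracle_gc3(cds):
    cs = _codons(cds)
    return sum(1 for c in cs if c[2] in "GC") / len(cs)


def oracle_rare(table, cds):
    count = 0
    for c in _codons(cds):
        aa = _aa_of(c)
        x = table.x[(aa, c)]
        if x < 0.3 and x < 1.0 / len(STANDARD_CODE.families[aa]):
            count += 1
    return count, count / len(_codons(cds))


def oracle_identity(a, b):
    ca, cb = _codons(a), _codons(b)
    return sum(1 for u, v in zip(ca, cb) if u == v) / len(ca)


def oracle_jaccard(a, b):
    sa, sb = set(_codons(a)), set(_codons(b))
    return len(sa & sb) / len(sa | sb)


def oracle_minmax(table, cds, window):
    cs = _codons(cds)
    out = []
    for start in range(len(cs) - window + 1):
        xa = xmx = xmn = xav = 0.0
        for c in cs[start : start + window]:
            aa = _aa_of(c)
            fam = [table.x[(aa, f)] for f in STANDARD_CODE.families[aa]]
            xa += table.x[(aa, c)]
            xmx += max(fam)
            xmn += min(fam)
            xav += sum(fam) / len(fam)
        xa, xmx, xmn, xav = (v / window for v in (xa, xmx, xmn, xav))
        if xa > xav:
            out.append(100 * (xa - xav) / (xmx - xav))
        elif xa < xav:
            out.append(-100 * (xav - xa) / (xav - xmn))
        else:
            out.append(0.0)
    return out


def oracle_rank(values):
    n_rows, n_cols = values.shape
    best = [0] * n_cols
    agg = [0.0] * n_cols
    for i in range(n_rows):
        row_max = max(values[i])
        for j in range(n_cols):
            agg[j] += values[i][j] / row_max
            if values[i][j] == row_max:
                best[j] += 1
    return best, agg


def _random_cds(rng, table, n_codons):
    # only codons actually observed in the table (w > 0), so CSI is defined
    usable = sorted(c for (aa, c), x in table.x.items() if x > 0)
    return "".join(rng.choice(usable) for _ in range(n_codons))


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force_on_random_instances(self, table):
        """100 random (sequence, table) instances agree with the independent
        brute-force formulas to 1e-9."""
        rng = random.Random(17)
        for k in range(100):
            cds = _random_cds(rng, table, rng.randint(20, 60))
            assert csi(cds, table) == pytest.approx(oracle_csi(table, cds), abs=1e-9)
            assert gc_content(cds) == pytest.approx(oracle_gc(cds), abs=1e-9)
            assert gc3_content(cds) == pytest.approx(oracle_gc3(cds), abs=1e-9)
            cnt, frac = rare_codon_stats(cds, table)
            ocnt, ofrac = oracle_rare(table, cds)
            assert cnt == ocnt and frac == pytest.approx(ofrac, abs=1e-9)
            codon = cds[:3]
            assert relative_adaptiveness(table, codon) == pytest.approx(
                oracle_w(table, codon), abs=1e-9
            )
            other = _random_cds(rng, table, len(cds) // 3)
            assert sequence_identity(cds, other) == pytest.approx(
                oracle_identity(cds, other), abs=1e-9
            )
            assert jaccard_similarity(cds, other) == pytest.approx(
                oracle_jaccard(cds, other), abs=1e-9
            )
            prof = minmax_profile(cds, table, window_size=17)
            assert prof.scores == pytest.approx(oracle_minmax(table, cds, 17), abs=1e-9)

    def test_benchmark_rank_matches_brute_force(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(1, 50, size=(6, 5))
        bt = BenchmarkTable(
            titers=pd.DataFrame(values, columns=list("ABCDE"))
        )
        result = benchmark_rank(bt)
        best, agg = oracle_rank(values)
        assert list(result["best_titer_count"]) == best
        assert list(result["aggregated_score"]) == pytest.approx(agg, abs=1e-9)


class TestHandExamples:
    def test_relative_adaptiveness_cases(self, table):
        for aa in table.observed_amino_acids():
            fam = sorted(STANDARD_CODE.families[aa])
            top = max(fam, key=lambda c: table.x[(aa, c)])
            assert relative_adaptiveness(table, top) == pytest.approx(1.0)
        assert relative_adaptiveness(table, "ATG") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            relative_adaptiveness(table, "TAA")

    def test_csi_two_codon_geometric_mean(self):
        # Lys: AAA 4x, AAG 1x -> w(AAA)=1, w(AAG)=0.25
        t = compute_usage_table(
            [SequencePair(id="a", protein="KKKKK", cds="AAA" * 4 + "AAG")]
        )
        assert csi("AAAAAG", t) == pytest.approx(0.5)
        assert csi("AAAAAA", t) == pytest.approx(1.0)

    def test_csi_invariant_under_duplication_and_permutation(self, table):
        s = "ATGGCCAAACTG"
        assert csi(s + s, table) == pytest.approx(csi(s, table), abs=1e-12)
        permuted = "GCCATGCTGAAA"
        assert csi(permuted, table) == pytest.approx(csi(s, table), abs=1e-12)

    def test_csi_unobserved_codon_error_and_pseudocount(self):
        t = compute_usage_table([SequencePair(id="a", protein="KKK", cds="AAAAAAAAA")])
        with pytest.raises(UnscoredCodonError):
            csi("AAG", t)
        assert csi("AAG", t, pseudocount=0.5) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "cds, expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ATGGCC", 4 / 6)]
    )
    def test_gc_content(self, cds, expected):
        assert gc_content(cds) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "cds, expected",
        [("ATGGCCAAA", 2 / 3), ("GGGGGGGGG", 1.0), ("GGAGGAGGA", 0.0)],
    )
    def test_gc3_content(self, cds, expected):
        assert gc3_content(cds) == pytest.approx(expected)

    def test_gc3_excludes_terminal_stop(self):
        # stop codon TAG would count as G at position 3 if not excluded
        assert gc3_content("ATGGCATAG") == pytest.approx(1 / 2)

    def test_rare_codons_uniform_table_boundary(self):
        uniform = compute_usage_table(
            generate_corpus(
                SyntheticGenomeSpec(
                    n_sequences=50, min_length=20, max_length=40,
                    codon_model=uniform_codon_model(), seed=1,
                )
            )
        )
        # force exact uniformity: x == Avg never satisfies the strict rule
        for key in uniform.x:
            uniform.x[key] = uniform.Avg[key[0]]
        cds = _random_cds(random.Random(0), uniform, 30)
        count, frac = rare_codon_stats(cds, uniform)
        assert count == 0 and frac == 0.0

    def test_rare_codons_hand_case(self):
        # Leu (6-fold, Avg=1/6): CTA at x=0.1 is rare; CTG at x=0.5 is not
        cds_pairs = [SequencePair(id="a", protein="L" * 10, cds="CTG" * 5 + "CTT" * 4 + "CTA")]
        t = compute_usage_table(cds_pairs)
        count, frac = rare_codon_stats("CTACTACTGCTGCTG", t)
        assert count == 2
        assert frac == pytest.approx(0.4)

    def test_identity_codon_granularity_convention(self):
        assert sequence_identity("ATGGCC", "ATGGCC") == 1.0
        assert sequence_identity("ATGGCC", "ATGGCG") == 0.5  # 5/6 nt but 1/2 codons
        with pytest.raises(ValueError):
            sequence_identity("ATGGCC", "ATG")

    def test_identity_is_position_sensitive(self):
        assert sequence_identity("ATGGCC", "GCCATG") == 0.0

    def test_jaccard_cases(self):
        assert jaccard_similarity("ATGGCC", "ATGGCC") == 1.0
        assert jaccard_similarity("ATGGCC", "ATGGCG") == pytest.approx(1 / 3)
        assert jaccard_similarity("ATGATG", "CTGCTG") == 0.0


class TestMinMax:
    def test_extreme_sequences_hit_plus_minus_100(self, table):
        aa = "L"
        fam = sorted(STANDARD_CODE.families[aa])
        xs = {c: table.x[(aa, c)] for c in fam}
        best = max(xs, key=xs.get)
        worst = min(xs, key=xs.get)
        prof_hi = minmax_profile(best * 20, table, window_size=5)
        assert all(s == pytest.approx(100.0) for s in prof_hi.scores)
        prof_lo = minmax_profile(worst * 20, table, window_size=5)
        assert all(s == pytest.approx(-100.0) for s in prof_lo.scores)

    def test_window_count_and_bounds(self, table):
        cds = _random_cds(random.Random(5), table, 40)
        prof = minmax_profile(cds, table, window_size=17)
        assert len(prof.scores) == 40 - 17 + 1
        assert all(-100.0 <= s <= 100.0 for s in prof.scores)
        assert prof.positions[0] == 8

    def test_shorter_than_window_raises(self, table):
        with pytest.raises(ValueError):
            minmax_profile("ATG" * 5, table, window_size=17)

    def test_even_window_rejected(self, table):
        with pytest.raises(ValueError):
            minmax_profile("ATG" * 30, table, window_size=16)


class TestBenchmarkRank:
    def test_sweep_winner(self):
        t = pd.DataFrame({"A": [10.0, 8.0], "B": [5.0, 4.0]}, index=["p1", "p2"])
        r = benchmark_rank(BenchmarkTable(titers=t))
        assert r.loc["A", "best_titer_count"] == 2
        assert r.loc["A", "aggregated_score"] == pytest.approx(2.0)

    def test_hand_normalized_table(self):
        # rows p1=[10,5], p2=[4,8]: A -> 10/10 + 4/8 = 1.5; B -> 5/10 + 8/8 = 1.5
        t = pd.DataFrame({"A": [10.0, 4.0], "B": [5.0, 8.0]}, index=["p1", "p2"])
        r = benchmark_rank(BenchmarkTable(titers=t))
        assert r.loc["A", "best_titer_count"] == 1
        assert r.loc["B", "best_titer_count"] == 1
        assert r.loc["A", "aggregated_score"] == pytest.approx(1.5)
        assert r.loc["B", "aggregated_score"] == pytest.approx(1.5)

    def test_aggregated_score_bounded_by_protein_count(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.uniform(0.1, 9, size=(7, 4)))
        r = benchmark_rank(BenchmarkTable(titers=t))
        assert (r["aggregated_score"] <= 7 + 1e-12).all()

    def test_ties_credit_all(self):
        t = pd.DataFrame({"A": [5.0], "B": [5.0]}, index=["p"])
        r = benchmark_rank(BenchmarkTable(titers=t))
        assert list(r["best_titer_count"]) == [1, 1]

    def test_zero_row_rejected(self):
        t = pd.DataFrame({"A": [0.0], "B": [0.0]})
        with pytest.raises(ValueError, match="all-zero"):
            benchmark_rank(BenchmarkTable(titers=t))

    def test_specific_productivity(self):
        t = pd.DataFrame({"A": [10.0], "B": [5.0]})
        od = pd.DataFrame({"A": [2.0], "B": [2.5]})
        r = benchmark_rank(BenchmarkTable(titers=t, optical_density=od))
        sp = r.attrs["specific_productivity"]
        assert sp.loc[0, "A"] == pytest.approx(5.0)
        assert sp.loc[0, "B"] == pytest.approx(2.0)


class TestCorrelations:
    def test_perfect_and_inverted(self):
        m = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [-1.0, -2, -3, -4]})
        r = metric_outcome_correlations(m, [1.0, 2, 3, 4])
        assert r["a"] == pytest.approx(1.0)
        assert r["b"] == pytest.approx(-1.0)

    def test_four_point_toy_against_formula(self):
        x = np.array([0.2, 0.5, 0.9, 0.4])
        y = np.array([3.0, 1.0, 4.0, 1.5])
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        r = metric_outcome_correlations(pd.DataFrame({"m": x}), y)
        assert r["m"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_nan_not_zero(self):
        m = pd.DataFrame({"flat": [1.0, 1.0, 1.0, 1.0]})
        r = metric_outcome_correlations(m, [1.0, 2, 3, 4])
        assert math.isnan(r["flat"])

    def test_spearman_option(self):
        m = pd.DataFrame({"a": [1.0, 10.0, 100.0]})
        r = metric_outcome_correlations(m, [1.0, 2.0, 3.0], method="spearman")
        assert r["a"] == pytest.approx(1.0)


def test_sequence_report_and_pairwise(table):
    records = [("s1", "ATGGCCAAACTGATGGCC"), ("s2", "ATGGCGAAACTGATGGCC")]
    rep = sequence_report(records, table)
    assert list(rep.index) == ["s1", "s2"]
    assert set(rep.columns) >= {"csi", "gc", "gc3", "rare_count", "rare_fraction"}
    ident, jac = pairwise_matrices(records)
    assert ident.loc["s1", "s1"] == 1.0
    assert ident.loc["s1", "s2"] == pytest.approx(5 / 6)
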