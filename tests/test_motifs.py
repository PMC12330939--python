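"""k-mer counting, Fisher/hypergeometric oracles, PWM scoring, enrichment."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circrbp.io import PWMRecord
from circrbp.motifs import (
    count_kmers,
    dual_role_intersection,
    fisher_exact_two_sided,
    hypergeom_upper_tail,
    index_to_kmer,
    kmer_enrichment,
    kmer_to_index,
    motif_enrichment_from_kmers,
    motif_frequency_profile,
    pwm_matching_kmers,
    scan_pwm_hits,
    score_kmer_pwm,
)
from circrbp.regions import RegionSet
from circrbp.synthetic import pwm_from_kmer


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_kmer_count(sequences, k):
    counts = {}
    total = 0
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            counts[w] = counts.get(w, 0) + 1
            total += 1
    return counts, total


def exact_fisher_oracle(a, b, c, d):
    """Two-sided Fisher p with exact rational arithmetic."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, row1)

    def pmf(x):
        return Fraction(math.comb(col1, x) * math.comb(n - col1, row1 - x), denom)

    obs = pmf(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return float(sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= obs))


def exact_hypergeom_upper_oracle(x, M, K, n):
    denom = math.comb(M, n)
    return float(
        sum(Fraction(math.comb(K, j) * math.comb(M - K, n - j), denom)
            for j in range(x, min(K, n) + 1))
    )


# ---------------------------------------------------------------------------
# k-mer counting
# ---------------------------------------------------------------------------

class TestCountKmers:
    def test_single_window(self):
        counts, total = count_kmers(["ACGTAC"], 6)
        assert total == 1 and counts[kmer_to_index("ACGTAC")] == 1

    def test_overlapping_windows(self):
        counts, total = count_kmers(["AAAAAAA"], 6)
        assert total == 2 and counts[kmer_to_index("AAAAAA")] == 2

    def test_n_windows_skipped(self):
        counts, total = count_kmers(["ACGNACGT"], 6)
        oracle, oracle_total = brute_force_kmer_count(["ACGNACGT"], 6)
        assert total == oracle_total
        for w, c in oracle.items():
            assert counts[kmer_to_index(w)] == c
        assert counts.sum() == total

    def test_short_sequence_warns_zero_total(self):
        with pytest.warns(UserWarning):
            counts, total = count_kmers(["ACG"], 6)
        assert total == 0 and counts.sum() == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGTN", min_size=0, max_size=30), min_size=1, max_size=5),
           st.integers(min_value=1, max_value=4))
    def test_matches_brute_force_scan(self, seqs, k):
        counts, total = count_kmers(seqs, k)
        oracle, oracle_total = brute_force_kmer_count(seqs, k)
        assert total == oracle_total == counts.sum()
        for idx in np.flatnonzero(counts):
            assert counts[idx] == oracle[index_to_kmer(idx, k)]


def test_kmer_index_round_trip():
    for km in ("AAAAAA", "TTTTTT", "GATTAC", "CGCGCG"):
        assert index_to_kmer(kmer_to_index(km), 6) == km


# ---------------------------------------------------------------------------
# Fisher / hypergeometric vs exact enumeration
# ---------------------------------------------------------------------------

class TestExactTests:
    def test_fisher_small_table(self):
        assert fisher_exact_two_sided(9, 1, 1, 9) == pytest.approx(
            exact_fisher_oracle(9, 1, 1, 9), abs=1e-12
        )

    def test_fisher_matches_exact_oracle_margins_to_60(self):
        """Exhaustive-enumeration oracle agreement to 1e-10 on a grid of
        2x2 tables with margins up to 60."""
        worst = 0.0
        for a, b, c, d in itertools.product([0, 1, 3, 7, 15, 30], repeat=4):
            if a + b + c + d == 0:
                continue
            p = fisher_exact_two_sided(a, b, c, d)
            oracle = exact_fisher_oracle(a, b, c, d)
            worst = max(worst, abs(p - oracle))
        assert worst < 1e-10

    def test_hypergeom_upper_matches_exact_oracle(self):
        for (x, M, K, n) in [(3, 50, 10, 12), (0, 40, 5, 8), (7, 60, 20, 15), (10, 30, 10, 10)]:
            assert hypergeom_upper_tail(x, M, K, n) == pytest.approx(
                exact_hypergeom_upper_oracle(x, M, K, n), abs=1e-10
            )


# ---------------------------------------------------------------------------
# k-mer enrichment
# ---------------------------------------------------------------------------

class TestKmerEnrichment:
    def test_identical_sets_flat(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(5)]
        table = kmer_enrichment(seqs, list(seqs), k=3)
        assert np.allclose(table["log2_enrichment"], 0.0)
        assert np.allclose(table["pvalue"], 1.0)
        assert not table["enriched"].any()

    def test_totals_conserved(self):
        rng = np.random.default_rng(1)
        fg = ["".join(rng.choice(list("ACGTN"), 100)) for _ in range(4)]
        bg = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(4)]
        table = kmer_enrichment(fg, bg, k=4)
        assert table["count_fg"].sum() == table["total_fg"].iloc[0]
        assert table["count_bg"].sum() == table["total_bg"].iloc[0]

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        fg = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(3)]
        bg = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(3)]
        t1 = kmer_enrichment(fg, bg, k=3)
        t2 = kmer_enrichment(bg, fg, k=3)
        assert np.allclose(t1["log2_enrichment"], -t2["log2_enrichment"], atol=1e-12)
        assert np.allclose(t1["pvalue"], t2["pvalue"], atol=1e-12)

    def test_planted_hexamer_detected(self):
        """TTTTTT at 6/kb in 200 foreground vs 0.5/kb in 800 background
        1 kb sequences lands in the enriched set at FDR < 0.1."""
        rng = np.random.default_rng(3)

        def make(n, rate):
            out = []
            for _ in range(n):
                seq = list("".join(rng.choice(list("ACGT"), 1000)))
                for _ in range(rng.poisson(rate)):
                    pos = rng.integers(0, 995)
                    seq[pos : pos + 6] = "TTTTTT"
                out.append("".join(seq))
            return out

        fg = make(200, 6.0)
        bg = make(800, 0.5)
        table = kmer_enrichment(fg, bg, k=6, motif_fdr=0.1)
        assert bool(table.loc["TTTTTT", "enriched"])
        assert table.loc["TTTTTT", "log2_enrichment"] > 1.0


# ---------------------------------------------------------------------------
# PWM scoring
# ---------------------------------------------------------------------------

class TestScoreKmerPWM:
    def test_perfect_match_scores_one(self):
        pwm = pwm_from_kmer("AAAAAA", "A6", concentration=0.97)
        score, match = score_kmer_pwm("AAAAAA", pwm)
        assert score == pytest.approx(1.0) and match

    def test_uniform_pwm_is_degenerate(self):
        pwm = PWMRecord("uni", np.full((6, 4), 0.25))
        score, match = score_kmer_pwm("ACGTAC", pwm)
        assert score == 0.0 and not match

    def test_matches_exhaustive_offset_oracle(self):
        """Sliding-alignment score equals an explicit all-offsets scan."""
        rng = np.random.default_rng(4)
        m = rng.dirichlet(np.ones(4), size=9)
        pwm = PWMRecord("R", m)
        lo = np.log2(np.maximum(m, 1e-3) / 0.25)
        for kmer in ("ACGTAC", "TTTTTT", "GGGCCC"):
            enc = [("ACGT").index(ch) for ch in kmer]
            best = 0.0
            for off in range(9 - 6 + 1):
                maxs = lo[off : off + 6].max(axis=1).sum()
                if maxs <= 0:
                    continue
                s = sum(lo[off + i, enc[i]] for i in range(6))
                best = max(best, s / maxs)
            score, _ = score_kmer_pwm(kmer, pwm)
            assert score == pytest.approx(best, abs=1e-12)

    def test_short_pwm_slides_inside_kmer(self):
        pwm = pwm_from_kmer("CGCG", "short", concentration=0.97)
        score, match = score_kmer_pwm("AACGCG", pwm)
        assert score == pytest.approx(1.0) and match

    def test_vectorized_universe_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        pwm = PWMRecord("R", rng.dirichlet(np.ones(4) * 0.4, size=7))
        mask = pwm_matching_kmers(pwm, 4)
        for idx in rng.integers(0, 256, 40):
            _, match = score_kmer_pwm(index_to_kmer(int(idx), 4), pwm)
            assert mask[idx] == match


# ---------------------------------------------------------------------------
# motif attribution
# ---------------------------------------------------------------------------

class TestMotifEnrichment:
    def _table(self, k, enriched_kmers):
        n = 4**k
        kmers = [index_to_kmer(i, k) for i in range(n)]
        df = pd.DataFrame({"kmer": kmers, "enriched": [km in enriched_kmers for km in kmers]})
        return df.set_index("kmer", drop=False)

    def test_point_mass_closed_form(self):
        """Enriched set exactly = the PWM's matching set, library of one:
        p equals the closed-form hypergeometric point mass."""
        pwm = pwm_from_kmer("TTTT", "U4", concentration=0.97)
        matching = pwm_matching_kmers(pwm, 4)
        enr = {index_to_kmer(i, 4) for i in np.flatnonzero(matching)}
        res = motif_enrichment_from_kmers(self._table(4, enr), [pwm])
        K = int(matching.sum())
        expected = exact_hypergeom_upper_oracle(K, 256, K, K)
        assert res.loc[0, "pvalue"] == pytest.approx(expected, abs=1e-12)
        assert res.loc[0, "n_enriched_matching"] == K

    def test_empty_enriched_set_all_p_one(self):
        pwms = [pwm_from_kmer("TTTT", "U4"), pwm_from_kmer("ACAC", "AC")]
        res = motif_enrichment_from_kmers(self._table(4, set()), pwms)
        assert np.allclose(res["pvalue"], 1.0)
        assert not res["significant"].any()

    def test_invariant_bound(self):
        pwm = pwm_from_kmer("GGGG", "G4")
        res = motif_enrichment_from_kmers(self._table(4, {"GGGG", "AAAA"}), [pwm])
        row = res.iloc[0]
        assert row["n_enriched_matching"] <= min(row["n_matching_kmers"], 2)


class TestProfileAndDualRole:
    def _regions(self, seqs_by_kind):
        return {
            kind: {f"c{i}": RegionSet(f"c{i}", kind, s) for i, s in enumerate(seqs)}
            for kind, seqs in seqs_by_kind.items()
        }

    def test_absent_motif_all_zero(self):
        pwm = pwm_from_kmer("TTTTTT", "U6", concentration=0.97)
        regions = self._regions({k: ["ACGCGA" * 50] * 3 for k in
                                 ("flank5", "boundary5", "body", "boundary3", "flank3")})
        prof = motif_frequency_profile([pwm], regions)
        assert (prof["normalized_frequency"] == 0).all()

    def test_copy_number_invariance(self):
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list("ACGT"), 400)) for _ in range(3)]
        pwm = pwm_from_kmer("ACGTAC", "R", concentration=0.97)
        hits1, kb1 = scan_pwm_hits(seqs, pwm)
        hits2, kb2 = scan_pwm_hits(seqs * 2, pwm)
        assert hits2 == 2 * hits1 and kb2 == 2 * kb1

    def test_boundary5_planted_motif_peaks_there(self):
        rng = np.random.default_rng(7)

        def rand(n, ln):
            return ["".join(rng.choice(list("ACGT"), ln)) for _ in range(n)]

        def planted(n, ln, motif, copies):
            out = []
            for s in rand(n, ln):
                s = list(s)
                for _ in range(copies):
                    pos = rng.integers(0, ln - 6)
                    s[pos : pos + 6] = motif
                out.append("".join(s))
            return out

        regions = self._regions(
            {
                "flank5": rand(20, 1000),
                "boundary5": planted(20, 100, "TTTTTT", 2),
                "body": rand(20, 1000),
                "boundary3": rand(20, 100),
                "flank3": rand(20, 1000),
            }
        )
        pwm = pwm_from_kmer("TTTTTT", "U6", concentration=0.97)
        prof = motif_frequency_profile([pwm], regions).set_index("region_kind")
        freq = prof["normalized_frequency"]
        assert freq["boundary5"] == freq.max() and freq["boundary5"] > 0

    def test_dual_role_counts(self):
        def res(names, sig):
            return pd.DataFrame({"rbp_name": names, "significant": sig})

        body = res(["A", "B", "C"], [True, True, False])
        flank = res(["A", "B", "C"], [False, True, True])
        venn = dual_role_intersection(body, flank)
        assert venn["both"] == ["B"]
        assert venn["body_only"] == ["A"] and venn["flank_only"] == ["C"]
        assert venn["n_both"] + venn["n_body_only"] + venn["n_flank_only"] == 3

    def test_disjoint_sets_empty_intersection(self):
        body = pd.DataFrame({"rbp_name": ["A"], "significant": [True]})
        flank = pd.DataFrame({"rbp_name": ["B"], "significant": [True]})
        assert dual_role_intersection(body, flank)["both"] == []
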