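"""PWM scanning, dinucleotide shuffling, hypergeometric enrichment and the
TF selection logic."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from chipscape.motifs import (
    MotifEnrichmentTable,
    PWM,
    celltype_specific_tfs,
    condition_differential_motifs,
    dinucleotide_shuffle,
    enrichment_test,
    make_background,
    mut_preservation,
    read_jaspar,
    reverse_complement,
    scan_sequence,
    scan_sequences,
    write_jaspar,
)


def sharp_pwm(consensus, motif_id="m", p=0.85):
    mat = np.full((4, len(consensus)), (1 - p) / 3)
    for j, b in enumerate(consensus):
        mat["ACGT".index(b), j] = p
    return PWM(motif_id=motif_id, matrix=mat)


class TestPWM:
    def test_columns_must_sum_to_one(self):
        bad = np.full((4, 6), 0.3)
        with pytest.raises(ValueError):
            PWM("bad", bad)

    def test_min_length(self):
        with pytest.raises(ValueError):
            PWM("short", np.full((4, 3), 0.25))

    def test_consensus_string(self):
        pwm = sharp_pwm("ACGTAC")
        assert pwm.consensus() == "ACGTAC"

    def test_jaspar_round_trip(self, tmp_path):
        pwms = [sharp_pwm("ACGTACGT", "m1"), sharp_pwm("TTTTCCCC", "m2")]
        p = tmp_path / "panel.jaspar"
        write_jaspar(p, pwms)
        back = read_jaspar(p)
        assert [b.motif_id for b in back] == ["m1", "m2"]
        for a, b in zip(pwms, back):
            assert np.allclose(a.matrix, b.matrix, atol=1e-4)


class TestScanning:
    def test_consensus_is_hit_at_planted_position(self, rng):
        pwm = sharp_pwm("ACGTACGTAC")
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        seq = bg[:90] + "ACGTACGTAC" + bg[90:]
        hit, positions = scan_sequence(seq, pwm)
        assert hit and any(pos == 90 for pos, _s, _sc in positions)

    def test_all_n_sequence_no_hit(self):
        pwm = sharp_pwm("ACGTAC")
        assert scan_sequence("N" * 100, pwm) == (False, [])

    def test_sequence_shorter_than_motif(self):
        pwm = sharp_pwm("ACGTACGT")
        assert scan_sequence("ACG", pwm)[0] is False

    def test_exhaustive_hexamer_oracle(self):
        pwm = sharp_pwm("ACGTTG")
        lo = pwm.log_odds()
        thr = 0.8 * pwm.max_score()

        def brute(seq):
            best = -np.inf
            for s in (seq, reverse_complement(seq)):
                sc = sum(lo["ACGT".index(b), j] for j, b in enumerate(s))
                best = max(best, sc)
            return best >= thr

        for combo in itertools.product("ACGT", repeat=6):
            seq = "".join(combo)
            assert scan_sequence(seq, pwm)[0] == brute(seq)

    def test_strand_symmetry(self, rng):
        pwm = sharp_pwm("ACGGTACGGT")
        seqs = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, 300)) for _ in range(50)
        ]
        seqs[7] = seqs[7][:100] + "ACGGTACGGT" + seqs[7][110:]
        fwd = scan_sequences(seqs, pwm)
        rev = scan_sequences([reverse_complement(s) for s in seqs], pwm)
        assert (fwd == rev).all()


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        shuf = dinucleotide_shuffle(seq, rng)
        assert len(shuf) == len(seq)
        assert Counter(zip(seq, seq[1:])) == Counter(zip(shuf, shuf[1:]))

    def test_actually_shuffles(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        assert any(dinucleotide_shuffle(seq, rng) != seq for _ in range(3))


class TestEnrichment:
    def test_equal_rates_not_significant(self, rng):
        pwm = sharp_pwm("ACGTACGTAC")
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 300)) for _ in range(40)]
        out = enrichment_test(seqs, list(seqs) * 2, pwm)
        assert out["pvalue"] > 0.3

    def test_matches_brute_force_hypergeometric_tail(self):
        # 40/50 fg hits vs 8/100 bg hits
        pwm = sharp_pwm("ACGTACGTAC")
        cons = pwm.consensus()
        fg = [cons + "A" * 20] * 40 + ["A" * 30] * 10
        bg = [cons + "A" * 20] * 8 + ["A" * 30] * 92
        out = enrichment_test(fg, bg, pwm)
        # direct tail summation over the hypergeometric pmf
        from math import comb

        N, K, n = 150, 48, 50
        tail = sum(
            comb(K, k) * comb(N - K, n - k) / comb(N, n) for k in range(40, min(K, n) + 1)
        )
        assert out["pvalue"] == pytest.approx(tail, rel=1e-9)

    def test_monotone_decreasing_in_fg_hits(self):
        pwm = sharp_pwm("ACGTACGTAC")
        cons = pwm.consensus()
        pvals = []
        for k in (10, 20, 30):
            fg = [cons + "A" * 20] * k + ["A" * 30] * (40 - k)
            bg = ["A" * 30] * 80
            pvals.append(enrichment_test(fg, bg, pwm)["pvalue"])
        assert pvals == sorted(pvals, reverse=True)

    def test_empty_foreground_errors(self):
        with pytest.raises(ValueError):
            enrichment_test([], ["ACGT"], sharp_pwm("ACGTAC"))


def table_from_pvalues(pmap):
    """pmap: {(motif, ct, cond): p}"""
    rows = [
        {"motif_id": m, "cell_type": ct, "condition": cond, "fg_hits": 0,
         "n_fg": 1, "bg_hits": 0, "n_bg": 2, "pvalue": p, "qvalue": p}
        for (m, ct, cond), p in pmap.items()
    ]
    return MotifEnrichmentTable(table=pd.DataFrame(rows))


class TestSelectionLogic:
    def test_alpha_one_everything_shared(self):
        t = table_from_pvalues({
            ("m1", "BC", "NC"): 0.5, ("m1", "BC", "MUT"): 0.9,
        })
        out = condition_differential_motifs(t, "BC", alpha=1.0)
        assert out["shared"] == {"m1"}

    def test_nc_only_rule(self):
        t = table_from_pvalues({
            ("m1", "BC", "NC"): 1e-6, ("m1", "BC", "MUT"): 0.3,
        })
        out = condition_differential_motifs(t, "BC", alpha=0.01)
        assert out["NC_only"] == {"m1"} and not out["MUT_only"]

    def test_specific_sets_disjoint_and_match_brute_force(self, rng):
        motifs = [f"m{i}" for i in range(30)]
        cts = ("BC", "LP", "ML")
        pmap = {
            (m, ct, "NC"): float(rng.random() ** 3) for m in motifs for ct in cts
        }
        t = table_from_pvalues(pmap)
        alpha = 0.05
        out = celltype_specific_tfs(t, cell_types=cts, alpha=alpha)
        for a, b in itertools.combinations(cts, 2):
            assert not (out[a] & out[b])
        for m in motifs:
            sig = [ct for ct in cts if pmap[(m, ct, "NC")] < alpha]
            if len(sig) == 1:
                assert m in out[sig[0]]
            else:
                assert all(m not in out[ct] for ct in cts)

    def test_motif_significant_in_two_types_excluded(self):
        pmap = {
            ("m1", "BC", "NC"): 1e-6, ("m1", "LP", "NC"): 1e-6, ("m1", "ML", "NC"): 0.5,
            ("m2", "BC", "NC"): 0.5, ("m2", "LP", "NC"): 1e-6, ("m2", "ML", "NC"): 0.5,
        }
        out = celltype_specific_tfs(table_from_pvalues(pmap), alpha=1e-4)
        assert out == {"BC": set(), "LP": {"m2"}, "ML": set()}

    def test_preservation_identical_tables(self):
        pmap = {}
        for ct in ("BC", "LP", "ML"):
            for cond in ("NC", "MUT"):
                pmap[(f"m_{ct}", ct, cond)] = 1e-8
                for other in ("BC", "LP", "ML"):
                    if other != ct:
                        pmap[(f"m_{ct}", other, cond)] = 0.9
        t = table_from_pvalues(pmap)
        spec = celltype_specific_tfs(t, alpha=1e-4)
        mat = mut_preservation(spec, t, alpha=1e-4)
        assert all(mat.loc[ct, ct] == 1 for ct in ("BC", "LP", "ML"))
        assert mat.to_numpy().sum() == 3  # no cross-gains

    def test_empty_specific_sets_give_zeros(self):
        t = table_from_pvalues({("m1", "BC", "MUT"): 0.5})
        mat = mut_preservation({"BC": set()}, t, alpha=1e-4)
        assert mat.loc["BC", "BC"] == 0

    def test_background_doubles_foreground(self, rng):
        fg = ["ACGTACGTAA" * 10] * 5
        bg = make_background(fg, rng, times=2)
        assert len(bg) == 10
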