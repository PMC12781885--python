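import numpy as np
import pandas as pd
import pytest

from pforge.features import (
    EnergyMatrix,
    FeatureTable,
    chimera_ars,
    composition_and_rbs,
    folding_profile,
    motif_score_features,
    mutation_features,
    promoter_strength,
    reduce_features,
    toy_energy_matrix,
)
from pforge.io import NucSequence
from pforge.pssm import PSSM


def _seq(s, name="x"):
    return NucSequence(name, s, len(s))


class TestFolding:
    def test_window_count(self, rng):
        seq = _seq("".join(rng.choice(list("ACGT"), 400)))
        coords, vals, avg, total = folding_profile(seq, window=40)
        assert len(vals) == 361
        assert avg == pytest.approx(vals.mean())

    def test_unpairable_window_is_zero(self):
        seq = _seq("A" * 40)
        _, vals, avg, total = folding_profile(seq)
        assert vals[0] == 0.0 and total == 0.0

    def test_stem_loop_matches_reference_folder(self):
        stem = "G" * 6 + "C" * 6
        hairpin = stem[:6] + "AAAA" + "".join("C" * 6) + "A" * 24
        seq = _seq(hairpin[:40])
        _, vals, _, total = folding_profile(seq)
        assert total < 0
        # independent oracle: the RNAfold executable on the same sequence
        import subprocess

        out = subprocess.run(
            ["RNAfold", "--noPS"], input=seq.seq, capture_output=True, text=True
        ).stdout
        ref = float(out.splitlines()[1].split("(")[-1].rstrip(")"))
        assert total == pytest.approx(ref, abs=0.1)

    def test_short_sequence_still_gets_total(self, caplog):
        seq = _seq("ACGTACGTAC")
        coords, vals, avg, total = folding_profile(seq, window=40)
        assert len(vals) == 0 and np.isnan(avg)
        assert np.isfinite(total)


class TestMutations:
    def test_self_comparison_all_zero(self):
        s = _seq("ACGTACGT")
        vec, count = mutation_features(s, s)
        assert count == 0 and not vec.any()

    def test_three_substitutions(self):
        control = _seq("AAAAAAAA")
        variant = _seq("ACAAGATA")
        vec, count = mutation_features(variant, control)
        assert count == 3
        assert list(np.nonzero(vec)[0]) == [1, 4, 6]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutation_features(_seq("ACGT"), _seq("ACG"))


class TestChimeraARS:
    def test_identical_to_reference(self):
        s = "ACGTTGCAGT"
        assert chimera_ars(s, [s]) == pytest.approx((len(s) + 1) / 2)

    def test_no_match_means_zero(self):
        assert chimera_ars("TTT", ["ACG", "CGCG"]) == 0.0

    def test_against_quadratic_brute_force(self, rng):
        def brute(seq, refs):
            total = 0
            for p in range(len(seq)):
                best = 0
                for q in range(p + 1, len(seq) + 1):
                    if any(seq[p:q] in r for r in refs):
                        best = q - p
                    else:
                        break
                total += best
            return total / len(seq)

        for _ in range(50):
            n = int(rng.integers(5, 50))
            seq = "".join(rng.choice(list("ACGT"), n))
            refs = ["".join(rng.choice(list("ACGT"), int(rng.integers(5, 50))))
                    for _ in range(int(rng.integers(1, 4)))]
            assert chimera_ars(seq, refs) == pytest.approx(brute(seq, refs))

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            chimera_ars("ACGT", [])


class TestMotifScores:
    def test_uniform_motif_scores_zero(self, uniform_pssm, rng):
        seq = _seq("".join(rng.choice(list("ACGT"), 50)))
        out = motif_score_features(seq, [uniform_pssm])
        assert out["uniform"] == pytest.approx(0.0)

    def test_catalog_size_preserved(self, rng):
        from pforge.synth import gen_motif_catalog

        catalog = gen_motif_catalog(37, rng=rng)
        seq = _seq("".join(rng.choice(list("ACGT"), 100)))
        assert len(motif_score_features(seq, catalog)) == 37

    def test_oversized_motif_omitted(self, rng, caplog):
        import logging

        long_motif = PSSM("long", rng.dirichlet([1] * 4, 30))
        seq = _seq("ACGTACGTAC")
        with caplog.at_level(logging.WARNING, logger="pforge"):
            out = motif_score_features(seq, [long_motif])
        assert out == {}


class TestPromoterStrength:
    def test_zero_matrix(self, rng):
        seq = _seq("".join(rng.choice(list("ACGT"), 60)))
        m = EnergyMatrix(np.zeros((4, 41)))
        contrib, total, avg = promoter_strength(seq, m, tss=0)
        assert total == 0.0 and avg == 0.0

    def test_hand_summed_total(self):
        vals = np.zeros((4, 41))
        vals[0, 0] = -2.0   # A at coordinate -41
        vals[3, 40] = 1.5   # T at coordinate -1
        m = EnergyMatrix(vals)
        seq = _seq("A" * 40 + "T")
        contrib, total, avg = promoter_strength(seq, m, tss=0)
        assert total == pytest.approx(-0.5)
        assert avg == pytest.approx(-0.5 / 41)

    def test_single_substitution_changes_one_contribution(self, rng):
        m = toy_energy_matrix()
        base = "".join(rng.choice(list("ACGT"), 50))
        seq = _seq(base)
        contrib1, total1, _ = promoter_strength(seq, m, tss=0)
        chars = list(base)
        idx = 40  # coordinate -10
        chars[idx] = "A" if chars[idx] != "A" else "C"
        seq2 = _seq("".join(chars))
        contrib2, total2, _ = promoter_strength(seq2, m, tss=0)
        changed = np.nonzero(contrib1 != contrib2)[0]
        assert len(changed) == 1
        assert total2 - total1 == pytest.approx(contrib2[changed[0]] - contrib1[changed[0]])

    def test_window_out_of_range(self):
        with pytest.raises(ValueError):
            promoter_strength(_seq("ACGT"), toy_energy_matrix(), tss=0)

    def test_energy_matrix_tsv_round_trip(self, tmp_path):
        m = toy_energy_matrix()
        m.write_tsv(tmp_path / "em.tsv")
        back = EnergyMatrix.read_tsv(tmp_path / "em.tsv")
        np.testing.assert_allclose(m.values, back.values)


class TestCompositionAndRBS:
    def test_acgt_counts(self):
        comp, _ = composition_and_rbs(_seq("ACGTAC"))
        assert comp["count_A"] == 2 and comp["count_C"] == 2
        assert comp["gc_content"] == pytest.approx(3 / 6)

    def test_dinucleotide_counts_sum(self, rng):
        s = "".join(rng.choice(list("ACGT"), 30))
        comp, _ = composition_and_rbs(_seq(s))
        total = sum(v for k, v in comp.items() if k.startswith("count_") and len(k) == 8)
        assert total == len(s) - 1

    def test_antishine_dalgarno_complement_is_strongest(self):
        # window reverse-complementary to the aSD core's 3' hexamer
        from pforge.features import DEFAULT_ASD

        core = DEFAULT_ASD[:6].replace("U", "T")  # ACCUCC -> ACCTCC
        complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(complement[b] for b in reversed(core))
        filler = "A" * 20
        seq = _seq(filler + rc + filler)
        _, rbs = composition_and_rbs(seq)
        best_coord = min(rbs, key=rbs.get)
        idx = best_coord + seq.anchor
        assert abs(idx - 20) <= 1
        assert rbs[best_coord] == min(rbs.values())


class TestReduceFeatures:
    def _table(self, cols: dict[str, np.ndarray], category="folding"):
        df = pd.DataFrame(cols, index=[f"v{i}" for i in range(len(next(iter(cols.values()))))])
        return FeatureTable(df, {c: category for c in cols})

    def test_duplicate_folding_column_collapsed(self, rng):
        x = rng.normal(size=20)
        t = self._table({"fold_win_-10": x, "fold_win_-50": x.copy()})
        out = reduce_features(t)
        assert list(out.values.columns) == ["fold_win_-10"]

    def test_uncorrelated_folding_columns_survive(self, rng):
        t = self._table({"fold_win_-10": rng.normal(size=30), "fold_win_-50": rng.normal(size=30)})
        out = reduce_features(t)
        assert out.values.shape[1] == 2

    def test_no_remaining_pair_above_cutoff(self, feature_table):
        from scipy.stats import spearmanr

        folds = [f for f in feature_table.values.columns if f.startswith("fold_win_")]
        for i, a in enumerate(folds):
            for b in folds[i + 1:]:
                rho = spearmanr(feature_table.values[a], feature_table.values[b]).statistic
                if np.isfinite(rho):
                    assert abs(rho) <= 0.99

    def test_adjacent_mutation_features_averaged(self, rng):
        cols = {
            "mut_-10": rng.integers(0, 2, 20).astype(float),
            "mut_-9": rng.integers(0, 2, 20).astype(float),
            "mut_-40": rng.integers(0, 2, 20).astype(float),
        }
        t = self._table(cols, category="mutation")
        out = reduce_features(t)
        assert "mut_-10_-9" in out.values.columns
        assert "mut_-40" in out.values.columns
        np.testing.assert_allclose(
            out.values["mut_-10_-9"], (cols["mut_-10"] + cols["mut_-9"]) / 2
        )


def test_extraction_is_pure(variant_panel, control_promoter):
    from pforge.features import extract_features

    kwargs = dict(
        energy_matrix=toy_energy_matrix(),
        chimera_reference=[control_promoter],
        tss=0,
        include=("mutation", "composition", "strength"),
    )
    t1 = extract_features(variant_panel[:5], control_promoter, **kwargs)
    t2 = extract_features(variant_panel[:5], control_promoter, **kwargs)
    pd.testing.assert_frame_equal(t1.values, t2.values)
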