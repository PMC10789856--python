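import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wgdtiming.distances import (CellStatus, DistanceMatrix,
                                 correct_distance, discrete_gamma_rates,
                                 distance_matrix, jtt_model,
                                 ml_distance_empirical, model_spec, p_distance,
                                 pairwise_valid_columns, percent_identity,
                                 transition_transversion_fractions,
                                 uniform_model)
from wgdtiming.errors import SaturationError, UncomparablePairError
from wgdtiming.io_formats import Alignment, Molecule, SequenceRecord


def prot(seq, name="a"):
    return SequenceRecord(name, Molecule.PROTEIN, seq)


def dna(seq, name="a"):
    return SequenceRecord(name, Molecule.DNA, seq)


class TestValidColumns:
    def test_gap_and_ambiguity_removed(self):
        assert pairwise_valid_columns(prot("M-KX"), prot("MLK-", "b")) == [0, 2]

    def test_gap_free(self):
        assert pairwise_valid_columns(prot("MKVL"), prot("MKIL", "b")) == [0, 1, 2, 3]

    def test_uncomparable(self):
        with pytest.raises(UncomparablePairError):
            pairwise_valid_columns(prot("--"), prot("AA", "b"))


class TestPDistance:
    def test_quarter(self):
        assert p_distance(dna("AAAA"), dna("AAAT", "b")) == 0.25

    def test_identical(self):
        assert p_distance(prot("MKVL"), prot("MKVL", "b")) == 0.0

    def test_masked_columns_match(self):
        # valid columns are 0 and 2, and they agree
        assert p_distance(prot("M-KX"), prot("MLK-", "b")) == 0.0


class TestCorrections:
    def test_poisson_quarter(self):
        assert correct_distance(0.25, "poisson") == pytest.approx(
            -math.log(0.75), abs=1e-12)

    def test_kimura_quarter(self):
        assert correct_distance(0.25, "kimura_protein") == pytest.approx(
            -math.log(1 - 0.25 - 0.2 * 0.0625), abs=1e-12)

    @pytest.mark.parametrize("method", ["p", "poisson", "gamma",
                                        "kimura_protein", "jc69"])
    def test_zero_maps_to_zero(self, method):
        assert correct_distance(0.0, method) == 0.0

    def test_k2p_zero(self):
        assert correct_distance((0.0, 0.0), "k2p") == 0.0

    def test_k2p_formula(self):
        ts, tv = 0.1, 0.05
        expect = -0.5 * math.log(1 - 2 * ts - tv) - 0.25 * math.log(1 - 2 * tv)
        assert correct_distance((ts, tv), "k2p") == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("method,bad_p", [
        ("poisson", 1.0), ("gamma", 1.0), ("kimura_protein", 0.9),
        ("jc69", 0.76)])
    def test_saturation(self, method, bad_p):
        with pytest.raises(SaturationError):
            correct_distance(bad_p, method)

    @pytest.mark.parametrize("method,alpha,bound", [
        ("poisson", 1.0, 0.99), ("gamma", 0.5, 0.99), ("gamma", 2.0, 0.99),
        ("kimura_protein", 1.0, 0.85), ("jc69", 1.0, 0.74)])
    def test_strictly_increasing(self, method, alpha, bound):
        grid = np.linspace(0.0, bound, 200)
        values = [correct_distance(p, method, alpha=alpha) for p in grid]
        assert all(b > a for a, b in zip(values, values[1:]))

    @given(st.floats(min_value=0.0, max_value=0.9),
           st.floats(min_value=0.2, max_value=5.0))
    def test_gamma_formula(self, p, alpha):
        expect = alpha * ((1 - p) ** (-1 / alpha) - 1)
        assert correct_distance(p, "gamma", alpha=alpha) == pytest.approx(
            expect, rel=1e-12)


class TestMLDistance:
    def test_identical_floor(self):
        a, b = prot("MKVLSDMKVL"), prot("MKVLSDMKVL", "b")
        d, status = ml_distance_empirical(a, b, uniform_model())
        assert d <= 1e-4 and status is CellStatus.OK

    def test_jc20_closed_form(self):
        rng = np.random.default_rng(0)
        states = list("ARNDCQEGHILKMFPSTWYV")
        seq_a = "".join(rng.choice(states, 1500))
        seq_b = list(seq_a)
        for i in rng.choice(1500, size=300, replace=False):
            seq_b[i] = rng.choice(states)
        a, b = prot(seq_a), prot("".join(seq_b), "b")
        p = p_distance(a, b)
        jc20 = -(19 / 20) * math.log(1 - 20 * p / 19)
        d, _ = ml_distance_empirical(a, b, uniform_model())
        assert d == pytest.approx(jc20, abs=1e-4)

    def test_saturated_pair_flagged(self):
        rng = np.random.default_rng(5)
        states = list("ARNDCQEGHILKMFPSTWYV")
        seq_a = "".join(rng.choice(states, 400))
        # force every column to differ: cycle to the next state
        nxt = {s: states[(k + 1) % 20] for k, s in enumerate(states)}
        seq_b = "".join(nxt[c] for c in seq_a)
        d, status = ml_distance_empirical(prot(seq_a), prot(seq_b, "b"),
                                          uniform_model())
        assert status is CellStatus.SATURATED

    def test_jtt_model_valid(self):
        model = jtt_model()
        q = model.rate_matrix()
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-10)
        assert -(model.frequencies * np.diag(q)).sum() == pytest.approx(1.0)
        # detailed balance: pi_i q_ij = pi_j q_ji
        pi = model.frequencies
        assert np.allclose(pi[:, None] * q, (pi[:, None] * q).T, atol=1e-12)

    def test_gamma_category_rates(self):
        rates = discrete_gamma_rates(0.5, 4)
        assert rates.shape == (4,)
        assert np.all(np.diff(rates) > 0)
        assert rates.mean() == pytest.approx(1.0, abs=1e-10)


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity(prot("MKVL"), prot("MKVL", "b")) == 100.0

    def test_half(self):
        assert percent_identity(prot("M-KX"), prot("MLLK", "b")) == 50.0

    def test_region(self):
        a, b = prot("MKVLSD"), prot("MKVLTT", "b")
        assert percent_identity(a, b, region=(0, 4)) == 100.0
        assert percent_identity(a, b, region=(4, 6)) == 0.0

    def test_empty_region(self):
        with pytest.raises(ValueError):
            percent_identity(prot("MKVL"), prot("MKVL", "b"), region=(2, 2))

    def test_complement_with_p_distance(self):
        a, b = prot("MKVLSDAR"), prot("MKILTDAR", "b")
        assert percent_identity(a, b) + 100 * p_distance(a, b) == pytest.approx(100.0)


class TestDistanceMatrix:
    def test_identical_sequences_zero(self):
        aln = Alignment(tuple(prot("MKVLSD", n) for n in "abc"))
        dm = distance_matrix(aln, model_spec("poisson"))
        assert np.all(dm.values == 0.0) and not dm.has_saturation

    def test_two_sequences_match_pairwise(self):
        aln = Alignment((prot("MKVLSDKK"), prot("MKILTDKK", "b")))
        dm = distance_matrix(aln, model_spec("poisson"))
        expect = correct_distance(p_distance(*aln.records), "poisson")
        assert dm.get("a", "b") == pytest.approx(expect)

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(2)
        states = list("ARNDCQEGHILKMFPSTWYV")
        base = rng.choice(states, 60)
        recs = []
        for i in range(5):
            seq = base.copy()
            for j in rng.choice(60, size=10, replace=False):
                seq[j] = rng.choice(states)
            recs.append(prot("".join(seq), f"s{i}"))
        dm = distance_matrix(Alignment(tuple(recs)), model_spec("kimura_protein"))
        assert np.array_equal(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_uncomparable_pair_listed(self):
        aln = Alignment((prot("MK--"), prot("--VL", "b"), prot("MKVL", "c")))
        with pytest.raises(UncomparablePairError) as err:
            distance_matrix(aln, model_spec("poisson"))
        assert ("a", "b") in err.value.pairs

    def test_k2p_on_dna(self):
        aln = Alignment((dna("ACGTACGTAC"), dna("GCGTACTTAC", "b")))
        dm = distance_matrix(aln, model_spec("k2p", molecule="dna"))
        ts, tv = transition_transversion_fractions(*aln.records)
        assert dm.get("a", "b") == pytest.approx(
            correct_distance((ts, tv), "k2p"))

    def test_protein_method_rejected_for_dna(self):
        aln = Alignment((dna("ACGT"), dna("ACGA", "b")))
        with pytest.raises(ValueError, match="not applicable"):
            distance_matrix(aln, model_spec("kimura_protein"))

    def test_phylip_and_tsv_exports(self):
        aln = Alignment((prot("MKVLSD"), prot("MKILTD", "b")))
        dm = distance_matrix(aln, model_spec("p"))
        assert dm.to_phylip().startswith(" 2\n")
        assert "status" in dm.to_tsv().splitlines()[0]
        assert "\tok" in dm.to_tsv()

    def test_matrix_recovers_simulated_truth(self):
        # 4-taxon family at L=10,000: estimates within 3 SE of true paths
        from wgdtiming.simulate import evolve_alignment
        from wgdtiming.tree import PhyloTree
        tree = PhyloTree.from_newick(
            "((A:0.2,B:0.3):0.1,(C:0.25,D:0.15):0.1);")
        aln = evolve_alignment(tree, uniform_model(), 10000, seed=11)
        dm = distance_matrix(aln, uniform_model())
        for x in "ABCD":
            for y in "ABCD":
                if x >= y:
                    continue
                t = tree.path_length(x, y)
                p = (19 / 20) * (1 - math.exp(-20 * t / 19))
                se_p = math.sqrt(p * (1 - p) / 10000)
                # delta method: SE of d = SE(p) * |dd/dp|
                se_d = se_p / (1 - 20 * p / 19)
                assert abs(dm.get(x, y) - t) < 3 * se_d
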