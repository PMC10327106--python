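import numpy as np
import pandas as pd
import pytest

from memfield.benchmarks import (MutationSpec, SequencePairSet,
                                 UndefinedMetricError, compute_design_metrics,
                                 confusion_matrix, ddg_insertion, ddg_mutation,
                                 divergence, perplexity, sequence_recovery)
from memfield.calibration import F23_WEIGHTS, WeightSet
from memfield.fixtures import make_sequence_set
from memfield.orientation import OrientationState, place
from memfield.params import AA20
from memfield.scoring import MembraneSystem, score
from memfield.structure import build_ideal_helix, sequence_generators


@pytest.fixture(scope="module")
def placed_helix(dlpc_system):
    h = build_ideal_helix("A" * 21)
    return place(h, OrientationState(0.0, 10.0, 0.0), dlpc_system.frame)


class TestDdgMutation:
    def test_identity_mutation_is_zero(self, dlpc_system, placed_helix):
        spec = MutationSpec(10, "A", "A")
        assert ddg_mutation(placed_helix, spec, dlpc_system) == pytest.approx(0.0, abs=1e-9)

    def test_zero_weights_give_zero(self, dlpc_system, placed_helix):
        spec = MutationSpec(10, "A", "W")
        val = ddg_mutation(placed_helix, spec, dlpc_system, WeightSet(0, 0, 0))
        assert val == 0.0

    def test_equals_bilayer_score_difference(self, dlpc_system, placed_helix):
        from memfield.structure import mutate_residue

        spec = MutationSpec(10, "A", "L")
        val = ddg_mutation(placed_helix, spec, dlpc_system)
        mutant = mutate_residue(placed_helix, 10, "L")
        oracle = (score(mutant, dlpc_system, F23_WEIGHTS).total
                  - score(placed_helix, dlpc_system, F23_WEIGHTS).total)
        assert val == pytest.approx(oracle, abs=1e-9)

    def test_antisymmetry(self, dlpc_system, placed_helix):
        from memfield.structure import mutate_residue

        forward = ddg_mutation(placed_helix, MutationSpec(10, "A", "L"), dlpc_system)
        mutant = mutate_residue(placed_helix, 10, "L")
        back = ddg_mutation(mutant, MutationSpec(10, "L", "A"), dlpc_system)
        assert forward == pytest.approx(-back, abs=1e-9)

    def test_native_mismatch_raises(self, dlpc_system, placed_helix):
        with pytest.raises(ValueError):
            ddg_mutation(placed_helix, MutationSpec(10, "W", "L"), dlpc_system)

    def test_charged_mutation_scans_all_19(self, dlpc_system, placed_helix):
        # spot-check the Ala -> X scan including charged/neutral Asp variants
        for mut in ("D-1", "D0", "K", "W"):
            val = ddg_mutation(placed_helix, MutationSpec(10, "A", mut), dlpc_system)
            assert np.isfinite(val)
        d_charged = ddg_mutation(placed_helix, MutationSpec(10, "A", "D-1"), dlpc_system)
        d_neutral = ddg_mutation(placed_helix, MutationSpec(10, "A", "D0"), dlpc_system)
        assert d_charged > d_neutral    # deprotonated Asp is more polar


class TestDdgInsertion:
    kw = dict(z_step=2.0, tilt_step=5.0, spin_step=60.0)

    def test_apolar_probe_reports_zero(self, dlpc_system, apolar_probe):
        val, state = ddg_insertion(apolar_probe, dlpc_system, **self.kw)
        assert val == 0.0 and state is None

    def test_polyleucine_is_strictly_negative(self, dlpc_system):
        gl5 = build_ideal_helix(sequence_generators("glrlg", 5))
        val, state = ddg_insertion(gl5, dlpc_system, **self.kw)
        assert val < 0.0 and state is not None

    def test_never_positive(self, dlpc_system):
        for seq in ("A" * 20, "N" * 12, "GWWLALALWWA"):
            val, _ = ddg_insertion(build_ideal_helix(seq), dlpc_system, **self.kw)
            assert val <= 0.0

    def test_flanking_trp_deepens_insertion(self, dlpc_system):
        plain = build_ideal_helix("G" + "L" * 6 + "R" + "L" * 7 + "G")
        flank = build_ideal_helix("GW" + "L" * 6 + "R" + "L" * 7 + "G")
        v_plain, _ = ddg_insertion(plain, dlpc_system, **self.kw)
        v_flank, st = ddg_insertion(flank, dlpc_system, **self.kw)
        assert v_flank < v_plain
        # the Trp row of the breakdown at the resting state is favorable
        placed = place(flank, st, dlpc_system.frame)
        b = score(placed, dlpc_system, F23_WEIGHTS)
        trp_row = b.table.index[np.array(list(placed.sequence)) == "W"][0]
        assert b.table.loc[trp_row, "weighted_total"] < 0.0


def simple_pairs(native, designed, region="aqueous"):
    return SequencePairSet([native], [designed],
                           [[region] * len(native)])


class TestSequenceRecovery:
    def test_exact_and_zero_recovery(self):
        assert sequence_recovery(simple_pairs("ARNDC", "ARNDC"))[0] == 1.0
        seq = "ARNDCEQGHI"
        shifted = seq[1:] + seq[0]
        assert sequence_recovery(simple_pairs(seq, shifted))[0] == 0.0

    def test_direct_count(self):
        rec, per_type = sequence_recovery(simple_pairs("AAAA", "AALA"))
        assert rec == 0.75
        assert per_type["A"] == 0.75

    def test_empty_subset_raises(self):
        pairs = simple_pairs("AAAA", "AAAA", region="lipid")
        with pytest.raises(UndefinedMetricError):
            sequence_recovery(pairs, region="aqueous")


class TestDivergence:
    def test_identical_distributions_are_zero(self):
        pairs = make_sequence_set(5, 80, recovery_target=1.0, seed=0)
        div = divergence(pairs)
        assert div["D_KL"] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(div["D_s"], 0.0)
        assert div["D"] == pytest.approx(0.0, abs=1e-12)

    def test_two_point_formula(self):
        # p_des = (1, 0, ...), q_nat = (1/2, 1/2, 0, ...) without pseudocount
        pairs = SequencePairSet(["AC", "CA"], ["AA", "AA"],
                                [["aqueous"] * 2] * 2)
        div = divergence(pairs, pseudocount=0.0)
        assert div["D_KL"] == pytest.approx(np.log(2.0), abs=1e-12)
        div2 = divergence(pairs, pseudocount=0.0, base="bits")
        assert div2["D_KL"] == pytest.approx(1.0, abs=1e-12)

    def test_nonnegative_on_random_pairs(self):
        for seed in range(20):
            pairs = make_sequence_set(2, 60, recovery_target=0.2, seed=seed)
            assert divergence(pairs)["D_KL"] >= 0.0

    def test_pseudocount_guards_missing_types(self):
        pairs = simple_pairs("AAAA", "CCCC")
        div = divergence(pairs, pseudocount=0.5)
        assert np.isfinite(div["D_KL"]) and div["D_KL"] > 0


class TestConfusionMatrix:
    def test_identity_for_perfect_design(self):
        cm = confusion_matrix(simple_pairs("ARNDC", "ARNDC"))
        for r in "ARNDC":
            assert cm.loc[r, r] == 1.0
            assert cm.loc[r].sum() == pytest.approx(1.0)

    def test_direct_two_residue_count(self):
        cm = confusion_matrix(simple_pairs("AR", "AK"))
        assert cm.loc["A", "A"] == 1.0
        assert cm.loc["R", "K"] == 1.0
        assert "C" not in cm.index       # absent rows omitted, not zero-filled

    def test_matches_bruteforce_counts(self):
        pairs = make_sequence_set(5, 100, recovery_target=0.3, seed=42)
        cm = confusion_matrix(pairs)
        nat, des = pairs.positions()
        for r in cm.index:
            counts = {s: 0 for s in AA20}
            denom = 0
            for x, y in zip(nat, des):
                if x == r:
                    denom += 1
                    counts[y] += 1
            for s in AA20:
                assert cm.loc[r, s] == pytest.approx(counts[s] / denom, abs=1e-12)

    def test_rows_sum_to_one(self):
        pairs = make_sequence_set(3, 200, recovery_target=0.5, seed=7)
        cm = confusion_matrix(pairs)
        assert np.allclose(cm.sum(axis=1), 1.0, atol=1e-9)


class TestPerplexity:
    @pytest.mark.parametrize("row,expect", [
        (np.full(20, 1 / 20), 20.0),
        ([0.5, 0.5] + [0.0] * 18, 2.0),
        ([1.0] + [0.0] * 19, 1.0),
    ])
    def test_reference_values(self, row, expect):
        assert perplexity(row) == pytest.approx(expect, abs=1e-9)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet(np.ones(20))
            assert 1.0 <= perplexity(p) <= 20.0 + 1e-9

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            perplexity([0.5, 0.6])


class TestStratification:
    def test_region_partition_of_counts(self):
        pairs = make_sequence_set(4, 150, recovery_target=0.3, seed=5)
        total = len(pairs.positions()[0])
        by_region = sum(len(pairs.positions(region=r)[0])
                        for r in ("lipid", "interface", "aqueous"))
        assert by_region == total
        # pooled matches equal the sum of per-region matches
        pooled = sequence_recovery(pairs)[0] * total
        split = sum(sequence_recovery(pairs, region=r)[0]
                    * len(pairs.positions(region=r)[0])
                    for r in ("lipid", "interface", "aqueous"))
        assert pooled == pytest.approx(split, abs=1e-9)

    def test_burial_filter(self):
        pairs = make_sequence_set(4, 150, recovery_target=0.3, seed=6)
        n_b = len(pairs.positions(burial="buried")[0])
        n_s = len(pairs.positions(burial="surface")[0])
        assert n_b + n_s == len(pairs.positions()[0])

    def test_full_metrics_bundle(self):
        pairs = make_sequence_set(4, 100, recovery_target=0.4, seed=8)
        m = compute_design_metrics(pairs, region="aqueous")
        assert 0.0 <= m.recovery <= 1.0
        assert m.D_KL >= 0.0
        assert all(1.0 <= v <= 20.0 + 1e-9 for v in m.perplexity)
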