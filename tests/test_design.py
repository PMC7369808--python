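import numpy as np
import pytest
from oracles import antiparallel_mismatches

from repairguide.design import (
    DesignParams,
    design_from_dict,
    design_spacer,
    design_to_dict,
    emit_oligo_pair,
    enumerate_designs,
    validate_design,
)
from repairguide.errors import DesignError
from repairguide.fixtures import FixtureSpec, design_grids, generate_orf
from repairguide.seq import TranscriptRecord, reverse_complement


def assert_single_mismatch_at_d(design, record):
    """Pairing oracle: aligned antiparallel to its window, the spacer shows a
    C:A mismatch at the target and (unless the 5'-G substitution acted) nowhere
    else."""
    w_start, w_end = design.window
    window_seq = record.slice(w_start, w_end)
    mismatches = antiparallel_mismatches(design.spacer, window_seq, w_start)
    expected = {design.target_a}
    if design.five_prime_base_modified and design.params.five_prime_policy == "substitute":
        five_prime_coord = w_end  # 5' spacer base pairs the highest window coordinate
        expected = expected | {five_prime_coord}
    assert set(mismatches) == expected
    # the mismatch at the target is the C, opposite an A
    L, d = len(design.spacer), design.mismatch_pos_from_3prime
    assert design.spacer[L - d] == "C"
    assert record.base(design.target_a) == "A"


class TestDesignSpacer:
    def test_cftr_50_34_geometry(self, cftr):
        design = design_spacer(cftr, 3846, DesignParams(50, 34))
        assert len(design.spacer) == 50
        assert design.spacer[50 - 34] == "C"
        assert design.window == (3846 - 34 + 1, 3846 + 50 - 34)
        assert_single_mismatch_at_d(design, cftr)

    def test_five_prime_policy_noop_when_already_g(self):
        # window chosen so the spacer 5' base (complement of window end) is G
        rec = TranscriptRecord("x", "ATG" + "GCA" * 20 + "TGA" + "C" * 10 + "TAA")
        target = rec.sequence.index("TGA", 3) + 3  # the opal A
        assert rec.base(target) == "A"
        # pick d so that window end base is C => spacer 5' base G
        L = 30
        for d in range(1, L + 1):
            w_end = target + L - d
            if w_end <= len(rec) and target - d + 1 >= 1 and rec.base(w_end) == "C" and d != L:
                design = design_spacer(rec, target, DesignParams(L, d))
                assert design.spacer[0] == "G"
                assert not design.five_prime_base_modified
                return
        pytest.skip("no suitable window in this construct")

    def test_substitute_policy_overwrites_and_flags(self, h2bgfp):
        design = design_spacer(h2bgfp, 570, DesignParams(50, 34, "substitute"))
        assert design.spacer[0] == "G"

    def test_prepend_policy_extends_length(self, h2bgfp):
        design = design_spacer(h2bgfp, 570, DesignParams(50, 34, "prepend"))
        assert len(design.spacer) == 51
        assert design.spacer[0] == "G"
        assert design.five_prime_base_modified
        assert_single_mismatch_at_d(design, h2bgfp)

    def test_require_policy_errors_on_non_g(self, h2bgfp):
        d50_34 = design_spacer(h2bgfp, 570, DesignParams(50, 34))
        if d50_34.five_prime_base_modified:
            with pytest.raises(DesignError, match="not G"):
                design_spacer(h2bgfp, 570, DesignParams(50, 34, "require"))
        else:
            assert design_spacer(h2bgfp, 570, DesignParams(50, 34, "require")).spacer[0] == "G"

    def test_target_not_adenosine(self, h2bgfp):
        assert h2bgfp.base(569) != "A"
        with pytest.raises(DesignError, match="not an adenosine"):
            design_spacer(h2bgfp, 569, DesignParams(50, 34))

    def test_window_out_of_range(self):
        rec = TranscriptRecord("x", "ATGTGATGGTAA")
        with pytest.raises(DesignError, match="outside record"):
            design_spacer(rec, 6, DesignParams(25, 10))

    @pytest.mark.parametrize(
        "L,d,match",
        [(50, 60, "mismatch distance"), (20, 10, "length 20"), (90, 10, "length 90")],
    )
    def test_parameter_bounds_named(self, h2bgfp, L, d, match):
        with pytest.raises(DesignError, match=match):
            design_spacer(h2bgfp, 570, DesignParams(L, d))

    def test_mismatch_at_5prime_end_conflicts_with_substitute(self, h2bgfp):
        with pytest.raises(DesignError, match="prepend"):
            design_spacer(h2bgfp, 570, DesignParams(30, 30))
        design = design_spacer(h2bgfp, 570, DesignParams(30, 30, "prepend"))
        assert_single_mismatch_at_d(design, h2bgfp)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_designs_have_exactly_one_ca_mismatch(self, seed):
        """Property: random (record, target, L, d) designs always pair with a
        single C:A mismatch at distance d, per the independent pairing oracle."""
        rng = np.random.default_rng(seed)
        rec = generate_orf(FixtureSpec(n_codons=120, seed=seed))
        a_positions = [i + 1 for i, b in enumerate(rec.sequence) if b == "A"]
        for _ in range(50):
            target = int(rng.choice(a_positions))
            L = int(rng.integers(25, 81))
            d = int(rng.integers(1, L))  # d < L so substitute never hits the C
            if target - d + 1 < 1 or target + L - d > len(rec):
                continue
            policy = ("substitute", "prepend")[int(rng.integers(2))]
            design = design_spacer(rec, target, DesignParams(L, d, policy))
            assert_single_mismatch_at_d(design, rec)


class TestEnumerateDesigns:
    def test_gfp_grid_yields_four_designs(self, h2bgfp):
        batch = enumerate_designs(h2bgfp, 570, design_grids()["GFP"])
        assert len(batch) == 4
        assert [(d.params.length, d.params.mismatch_distance) for d in batch] == [
            (50, 32), (50, 34), (50, 35), (30, 25),
        ]
        assert len(batch.designs[3].spacer) == 30

    def test_cftr_grid_yields_three_designs(self, cftr):
        batch = enumerate_designs(cftr, 3846, design_grids()["CFTR"])
        assert len(batch) == 3
        assert all(len(d.spacer) == 50 for d in batch)

    def test_bad_entry_collected_without_aborting(self, h2bgfp):
        grid = [DesignParams(50, 34), DesignParams(50, 60), DesignParams(30, 25)]
        batch = enumerate_designs(h2bgfp, 570, grid)
        assert len(batch) == 2
        assert len(batch.failures) == 1
        assert batch.failures[0][0] == DesignParams(50, 60)
        assert "mismatch distance" in batch.failures[0][1]

    def test_empty_grid_is_an_error(self, h2bgfp):
        with pytest.raises(DesignError, match="empty"):
            enumerate_designs(h2bgfp, 570, [])

    def test_singleton_grid_equals_design_spacer(self, cftr):
        params = DesignParams(50, 32)
        batch = enumerate_designs(cftr, 3846, [params])
        assert batch.designs == [design_spacer(cftr, 3846, params)]


class TestOligoPair:
    def test_default_overhang_lengths(self, cftr):
        design = design_spacer(cftr, 3846, DesignParams(50, 34))
        pair = emit_oligo_pair(design)
        assert len(pair.top_oligo) == 54
        assert len(pair.bottom_oligo) == 54
        assert pair.enzyme == "BbsI"

    def test_empty_overhangs(self, cftr):
        design = design_spacer(cftr, 3846, DesignParams(50, 34))
        pair = emit_oligo_pair(design, overhangs=("", ""))
        assert pair.top_oligo == design.spacer
        assert pair.bottom_oligo == reverse_complement(design.spacer)

    @pytest.mark.parametrize("overhangs", [("CACC", "CAAC"), ("G", "TTTT"), ("", "AATT")])
    def test_annealed_region_reconstructs_spacer(self, h2bgfp, overhangs):
        design = design_spacer(h2bgfp, 570, DesignParams(50, 32))
        pair = emit_oligo_pair(design, overhangs=overhangs)
        top_core = pair.top_oligo[len(pair.top_overhang):]
        bottom_core = pair.bottom_oligo[len(pair.bottom_overhang):]
        assert top_core == design.spacer
        assert reverse_complement(bottom_core) == design.spacer

    def test_non_nucleotide_overhang_rejected(self, h2bgfp):
        design = design_spacer(h2bgfp, 570, DesignParams(50, 32))
        with pytest.raises(Exception, match="overhang"):
            emit_oligo_pair(design, overhangs=("CAXC", "CAAC"))


class TestValidateDesign:
    def test_cftr_50_34_is_clean(self, cftr):
        design = design_spacer(cftr, 3846, DesignParams(50, 34))
        assert validate_design(design, cftr) == []

    def test_short_spacer_flagged(self, h2bgfp):
        design = design_spacer(h2bgfp, 570, DesignParams(26, 10, min_length=20))
        relaxed = design_to_dict(design)
        relaxed["spacer"] = design.spacer[-20:]
        relaxed["params"].update(length=20, min_length=25, mismatch_distance=10)
        issues = validate_design(design_from_dict(relaxed))
        assert any(i.code == "length_below_min" and "25" in i.message for i in issues)

    def test_internal_bbsi_site_flagged(self, h2bgfp):
        design = design_spacer(h2bgfp, 570, DesignParams(50, 34))
        doctored = design_to_dict(design)
        doctored["spacer"] = "GAAGAC" + design.spacer[6:]
        issues = validate_design(design_from_dict(doctored))
        assert any(i.code == "bbsi_site" for i in issues)

    def test_mismatch_not_c_flagged(self, h2bgfp):
        design = design_spacer(h2bgfp, 570, DesignParams(50, 34))
        doctored = design_to_dict(design)
        s = list(design.spacer)
        s[50 - 34] = "T"
        doctored["spacer"] = "".join(s)
        issues = validate_design(design_from_dict(doctored))
        assert any(i.code == "mismatch_not_C" for i in issues)

    def test_round_trip_serialization(self, cftr):
        design = design_spacer(cftr, 3846, DesignParams(50, 35))
        assert design_from_dict(design_to_dict(design)) == design
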