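from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sdscan.duplex_energy import (
    NNParameterTable,
    pair_mask,
    register_delta_g,
    scan_registers,
)
from sdscan.genome_io import reverse_complement, transcribe

from .oracles import load_raw_table, oracle_register_score, oracle_scan


@dataclass(frozen=True)
class FakeTIR:
    seq: str
    start_index: int


def rc_rna(seq: str) -> str:
    return transcribe(reverse_complement(seq))


class TestPairMask:
    def test_canonical_sd_asd_all_paired(self):
        # core ASD 5'-CCUCC-3' against the canonical SD GGAGG, antiparallel
        assert pair_mask("CCUCC", "GGAGG", 4) == [True] * 5

    def test_cc_mismatch_and_gu_wobble(self):
        assert pair_mask("C", "C", 0) == [False]
        assert pair_mask("U", "G", 0) == [True]

    def test_n_never_pairs(self):
        # ASD base 0 sits on window index 1 ('G'), base 1 on index 0 ('N')
        assert pair_mask("CC", "NG", 1) == [True, False]

    def test_zero_overlap_raises(self):
        with pytest.raises(ValueError, match="zero overlap"):
            pair_mask("CCUCC", "GGAGG", -1)


class TestRegisterDeltaG:
    def test_seven_bp_duplex_hand_summed(self, params):
        # ASD segment ACCUCCU over mRNA AGGAGGU: stacks AC/UG + CC/GG +
        # CU/GA + UC/AG + CC/GG + CU/GA = -15.40; init +4.09; two A.U
        # terminal penalties +0.90 => -10.41 kcal/mol
        rs = register_delta_g("ACCUCCU", "AGGAGGU", 6, params)
        assert rs.dG == pytest.approx(-10.41)
        assert rs.helix_len == 7
        assert rs.helix_span == (0, 6)

    def test_no_stable_helix_caps_at_zero(self, params):
        rs = register_delta_g("CCUCC", "AAAAA", 4, params)
        assert rs.dG == 0.0
        assert rs.helix_len < 2

    def test_two_bp_helix_is_not_stabilizing(self, params):
        # init +4.09 dominates a single stack, so dG caps at 0
        rs = register_delta_g("CC", "GG", 1, params)
        assert rs.dG == 0.0

    def test_gc_extension_strictly_decreases(self, params):
        # extend a planted complement by one G.C pair at the helix end
        asd = "ACCUCCUC"
        shorter = rc_rna(asd[:7])  # pairs ASD[0..6]
        longer = rc_rna(asd)  # adds the terminal C.G pair
        dg_short = register_delta_g(asd, shorter, len(shorter) - 1, params).dG
        dg_long = register_delta_g(asd, longer, len(longer) - 1, params).dG
        assert dg_long < dg_short

    def test_monotone_with_complement_length(self, params):
        # 9..13-bp perfect complements of the extended ASD: min dG never
        # increases as the helix is extended
        tail = "GAUCACCUCCUUU"
        dgs = []
        for n in range(9, 14):
            window = rc_rna(tail[:n])
            dgs.append(register_delta_g(tail, window, n - 1, params).dG)
        assert all(b <= a for a, b in zip(dgs, dgs[1:]))
        assert dgs[-1] == pytest.approx(-20.66)


class TestScanRegisters:
    def test_singleton_matches_register_call(self, params):
        tir = FakeTIR(seq="A" * 20 + "AGGAGGU" + "A" * 25, start_index=40)
        (only,) = scan_registers("ACCUCCU", tir, [15], params)
        raw = register_delta_g("ACCUCCU", tir.seq, 40 - 15, params)
        assert only.dG == raw.dG

    def test_planted_register_attains_minimum(self, params):
        tail = "GAUCACCUCCUUU"
        sd = rc_rna(tail)
        # SD 3' end 5 nt upstream of the start codon -> best register 6
        seq = ("A" * (40 - 5 - 13) + sd.replace("U", "T") + "A" * 5 + "ATGAAAAAAAAA")
        tir = FakeTIR(seq=transcribe(seq), start_index=40)
        scores = scan_registers(tail, tir, range(-10, 40), params)
        best = min(scores, key=lambda r: r.dG)
        assert best.offset == 6
        assert best.dG == pytest.approx(-20.66)

    def test_all_a_tir_scores_zero_everywhere(self, params):
        tir = FakeTIR(seq="A" * 52, start_index=40)
        assert all(
            r.dG == 0.0 for r in scan_registers("GAUCACCUCCUUU", tir, range(0, 30), params)
        )

    def test_matches_brute_force_oracle(self, params):
        from .conftest import random_rna

        table = load_raw_table()
        rng = np.random.default_rng(42)
        for _ in range(50):
            asd = random_rna(rng, 13)
            tir = FakeTIR(seq=random_rna(rng, 52), start_index=40)
            offsets = range(-12, 41)
            expected = oracle_scan(asd, tir.seq, 40, offsets, table)
            got = {r.offset: r.dG for r in scan_registers(asd, tir, offsets, params)}
            assert got == pytest.approx(expected)


class TestProperties:
    @given(st.integers(0, 2**31 - 1))
    def test_dg_nonpositive_and_helix_consistency(self, seed):
        params = NNParameterTable.default()
        rng = np.random.default_rng(seed)
        asd = "".join(rng.choice(list("ACGU"), size=13))
        window = "".join(rng.choice(list("ACGUN"), size=30))
        rs = register_delta_g(asd, window, int(rng.integers(0, 30)), params)
        assert rs.dG <= 0.0
        assert (rs.dG == 0.0) == (rs.helix_len < 2)
        if rs.dG < 0.0:
            j0 = rs.offset
            _, best_run = oracle_register_score(
                asd, window, j0, load_raw_table()
            )
            assert best_run is not None

    def test_table_versioned_and_complete(self, params):
        assert params.version == "turner2004-1.0"
        assert len(params.stacks) == 36
        # reversal symmetry of the stack table: 5'xy/3'zw == reversed motif
        for key, dg in params.stacks.items():
            top, bottom = key.split("/")
            flipped = bottom[::-1] + "/" + top[::-1]
            assert params.stacks[flipped] == dg
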