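"""Thermodynamic engine contract: energies, ensembles, pseudoknot scheme.

Independent oracles: the RNAeval command-line executable for fixed-structure
energies, exhaustive secondary-structure enumeration for the suboptimal gap,
and a hand-run two-pass masking procedure for the pseudoknot predictor.
"""

from __future__ import annotations

import itertools
import math
import subprocess

import numpy as np
import pytest

import RNA
from conftest import make_target
from rexfold.structures import parse_dot_bracket
from rexfold.thermo import (
    EngineConfig,
    dimer_quantities,
    evaluate,
    predict_pseudoknotted,
    subopt_gap,
)


def rnaeval_cli(seq: str, structure: str, params: str) -> float:
    """Fixed-structure energy via the RNAeval executable (independent path)."""
    import shutil
    from pathlib import Path

    args = ["RNAeval", "-d2"]
    if params == "Turner1999":
        par = (
            Path(shutil.which("RNAeval")).parent.parent
            / "share" / "ViennaRNA" / "rna_turner1999.par"
        )
        args += ["-P", str(par)]
    out = subprocess.run(
        args,
        input=f"{seq}\n{structure}\n",
        capture_output=True,
        text=True,
        check=True,
    ).stdout
    return float(out.strip().rsplit("(", 1)[1].rstrip(")"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGU"[k] for k in rng.integers(0, 4, n))


class TestEvaluate:
    def test_open_chain_has_zero_energy(self, cfg99):
        t = make_target("N" * 7, ".......")
        rep = evaluate("AAAAAAA", t, cfg99)
        assert rep.e_desired[0] == 0.0

    def test_ensemble_bounds_hold(self, cfg99):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(15, 45))
            seq = random_seq(rng, n)
            t = make_target("N" * n, "." * n)
            rep = evaluate(seq, t, cfg99)
            assert rep.e_pf <= rep.e_mfe + 1e-9
            assert rep.e_pf <= min(rep.e_desired) + 1e-9
            assert 0.0 < rep.mfe_frequency <= 1.0 + 1e-12
            assert 0.0 <= rep.ensemble_defect <= n + 1e-9

    @pytest.mark.parametrize(
        "seq,structure",
        [
            ("GGGAAACCC", "(((...)))"),
            ("GGGGGAAAACCCCC", "((((......))))"),
            ("GCGCUUCGGCGC", "((((....))))"),
        ],
    )
    def test_fixed_structure_energy_matches_rnaeval(self, seq, structure, cfg99):
        t = make_target("N" * len(seq), structure)
        rep = evaluate(seq, t, cfg99)
        assert rep.e_desired[0] == pytest.approx(
            rnaeval_cli(seq, structure, "Turner1999"), abs=1e-6
        )

    def test_turner2004_energies_match_rnaeval(self):
        # the parameter set is fixed per process, so the Turner2004 leg
        # runs in a fresh interpreter
        from conftest import run_py

        cases = [
            ("GGGAAACCC", "(((...)))"),
            ("GCGCUUCGGCGC", "((((....))))"),
        ]
        out = run_py(
            "import json\n"
            "from rexfold.thermo import EngineConfig, evaluate\n"
            "from rexfold.structures import DesignTarget\n"
            f"cases = {cases!r}\n"
            "cfg = EngineConfig(parameter_set='Turner2004')\n"
            "vals = [evaluate(s, DesignTarget.from_strings('N'*len(s), st),"
            " cfg).e_desired[0] for s, st in cases]\n"
            "print(json.dumps(vals))\n"
        )
        import json

        vals = json.loads(out)
        for (seq, structure), got in zip(cases, vals):
            assert got == pytest.approx(
                rnaeval_cli(seq, structure, "Turner2004"), abs=1e-6
            )

    def test_parameter_set_switch_is_refused(self, cfg99):
        # latched at first use; a silent wrong-table computation would be
        # worse than an error
        t = make_target("NNNN", "....")
        evaluate("ACGU", t, cfg99)
        with pytest.raises(RuntimeError, match="fixed"):
            evaluate("ACGU", t, EngineConfig(parameter_set="Turner2004"))

    def test_mfe_frequency_identity_against_engine_probability(self, cfg99):
        # exp((E_pf - E_mfe)/kT) must equal the engine's own Boltzmann
        # probability of the MFE structure
        rng = np.random.default_rng(42)
        for _ in range(30):
            seq = random_seq(rng, int(rng.integers(15, 45)))
            t = make_target("N" * len(seq), "." * len(seq))
            rep = evaluate(seq, t, cfg99)
            fc = RNA.fold_compound(seq, RNA.md())
            ss, mfe = fc.mfe()
            fc.exp_params_rescale(mfe)
            fc.pf()
            assert rep.mfe_frequency == pytest.approx(
                fc.pr_structure(ss), abs=1e-5
            )

    def test_ensemble_defect_zero_and_full_limits(self, cfg99):
        # a rock-stable hairpin against its own MFE structure: tiny defect;
        # against the anti-structure (everything flipped): large defect
        seq = "GGGGGCCCCCGAAAAGGGGGCCCCC"[:14]
        seq = "GCGCGCGAAAGCGCGC"
        t_open = make_target("N" * len(seq), "." * len(seq))
        rep = evaluate(seq, t_open, cfg99)
        mfe_text = rep.mfe_structure.text
        t_mfe = make_target("N" * len(seq), mfe_text)
        rep2 = evaluate(seq, t_mfe, cfg99)
        assert rep2.ensemble_defect < rep.ensemble_defect

    def test_alternative_structures_get_one_energy_each(self, cfg99):
        t = make_target("N" * 32,
                        "((((..((((((....))))))......))))",
                        "((((....))))....((((((....))))))")
        seq = "GCGC" + "AA" + "GGGGGG" + "AAAA" + "CCCCCC" + "AAAAAA" + "GCGC"
        rep = evaluate(seq, t, cfg99)
        assert len(rep.e_desired) == 2

    def test_illegal_nucleotide_raises_with_context(self, cfg99):
        t = make_target("NNNN", "....")
        with pytest.raises(ValueError, match="X"):
            evaluate("AXGU", t, cfg99)


class TestSuboptGap:
    def test_homopolymer_returns_window_sentinel(self, cfg99):
        assert subopt_gap("AAAAAAAA", cfg99, window=5.0) == 5.0

    def test_gap_is_nonnegative(self, cfg99):
        rng = np.random.default_rng(1)
        for _ in range(10):
            seq = random_seq(rng, 20)
            assert subopt_gap(seq, cfg99) >= 0.0

    def test_matches_exhaustive_structure_enumeration(self, cfg99):
        # brute-force oracle: enumerate every secondary structure (hairpin
        # loops >= 3), evaluate each, and find the best non-MFE energy
        seq = "GGGGGAAAACCCCC"
        n = len(seq)

        def enumerate_pairsets(lo, hi):
            if hi - lo < 1:
                yield []
                return
            # position lo unpaired
            for rest in enumerate_pairsets(lo + 1, hi):
                yield rest
            for j in range(lo + 4, hi):
                if (seq[lo], seq[j]) in {
                    ("A", "U"), ("U", "A"), ("G", "C"),
                    ("C", "G"), ("G", "U"), ("U", "G"),
                }:
                    for inner in enumerate_pairsets(lo + 1, j):
                        for outer in enumerate_pairsets(j + 1, hi):
                            yield [(lo, j)] + inner + outer

        md = RNA.md()
        fc = RNA.fold_compound(seq, md)
        mfe_ss, e_mfe = fc.mfe()
        energies = []
        for ps in enumerate_pairsets(0, n):
            chars = ["."] * n
            for i, j in ps:
                chars[i], chars[j] = "(", ")"
            text = "".join(chars)
            if text != mfe_ss:
                energies.append(fc.eval_structure(text))
        oracle_gap = min(energies) - e_mfe
        assert subopt_gap(seq, cfg99, window=10.0) == pytest.approx(
            oracle_gap, abs=1e-6
        )


class TestPseudoknotPrediction:
    def test_depth_one_equals_plain_mfe(self, cfg99):
        rng = np.random.default_rng(9)
        for _ in range(10):
            seq = random_seq(rng, 30)
            pred = predict_pseudoknotted(seq, 1, cfg99)
            fc = RNA.fold_compound(seq, RNA.md())
            ss, _ = fc.mfe()
            assert pred.text == ss

    def test_levels_are_position_disjoint(self, cfg99):
        rng = np.random.default_rng(10)
        for _ in range(10):
            seq = random_seq(rng, 40)
            pred = predict_pseudoknotted(seq, 3, cfg99)
            by_level: dict[int, set[int]] = {}
            for i, j, lvl in pred.pairs:
                by_level.setdefault(lvl, set()).update((i, j))
            levels = sorted(by_level)
            for a, b in itertools.combinations(levels, 2):
                assert not (by_level[a] & by_level[b])

    def test_matches_two_pass_masking_oracle(self, cfg99):
        # run the masking procedure by hand and compare pair sets per level
        rng = np.random.default_rng(11)
        for _ in range(5):
            seq = random_seq(rng, 45)
            md = RNA.md()
            fc1 = RNA.fold_compound(seq, md)
            ss1, _ = fc1.mfe()
            lvl0 = parse_dot_bracket(ss1).pair_set
            fc2 = RNA.fold_compound(seq, md)
            for i in sorted({k for p in lvl0 for k in p}):
                fc2.hc_add_up(i + 1)
            ss2, _ = fc2.mfe()
            lvl1 = parse_dot_bracket(ss2).pair_set
            pred = predict_pseudoknotted(seq, 2, cfg99)
            got0 = {(i, j) for i, j, l in pred.pairs if l == 0}
            got1 = {(i, j) for i, j, l in pred.pairs if l == 1}
            assert got0 == lvl0
            assert got1 == lvl1


class TestDimerQuantities:
    def test_toy_duplex_energy_matches_rnaeval(self, cfg99):
        t = make_target("NNNN&NNNN", "((((&))))")
        rep = evaluate("GGGG&CCCC", t, cfg99)
        assert rep.e_desired[0] == pytest.approx(
            rnaeval_cli("GGGG&CCCC", "((((&))))", "Turner1999"), abs=1e-6
        )

    def test_homodimer_is_symmetric_and_bounded(self, cfg99):
        q = dimer_quantities("GGGGAAAACCCC", "GGGGAAAACCCC", cfg99)
        assert q.e_pf_a == q.e_pf_b
        assert q.e_pf_ab < 0

    def test_structure_fraction_is_mfe_frequency_for_mfe_structure(self, cfg99):
        # when the desired dimer structure is the complex MFE structure the
        # fraction reduces to the complex MFE frequency
        seqA = seqB = "GGGGAAAACCCC"
        fc = RNA.fold_compound(seqA + "&" + seqB, RNA.md())
        ss, e_mfe = fc.mfe_dimer()
        fc.exp_params_rescale(e_mfe)
        q = dimer_quantities(seqA, seqB, cfg99)
        e_des = fc.eval_structure(ss)
        frac = q.structure_fraction(e_des)
        assert frac == pytest.approx(
            math.exp((q.e_pf_ab - e_des) / cfg99.kT), rel=1e-12
        )
        # the homodimer connected-ensemble energy carries the engine's
        # indistinguishable-strand symmetry correction (+kT ln 2) that a
        # fixed-structure evaluation lacks, so the bound is a factor 2
        assert 0 < frac <= 2.001

    def test_empty_strand_rejected(self, cfg99):
        with pytest.raises(ValueError, match="non-empty"):
            dimer_quantities("", "GGG", cfg99)


class TestEngineConfig:
    def test_kt_matches_engine_constant(self, cfg99):
        fc = RNA.fold_compound("GGGAAACCC", RNA.md())
        _, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)  # materializes the Boltzmann parameters
        assert cfg99.kT == pytest.approx(fc.exp_params.kT / 1000.0, rel=1e-12)

    def test_unknown_parameter_set_rejected(self):
        with pytest.raises(ValueError, match="parameter_set"):
            EngineConfig(parameter_set="Turner2021")
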