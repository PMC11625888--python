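"""Relative expression by 2^-ddCt: replicate averaging, calibration, folds."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emmetropy import qpcr, synthgen
from emmetropy.exceptions import InvalidInputError, InvalidSpecError


def ct_rows(sample, group, gene, cts, timepoint="t1"):
    return [
        {
            "sample_id": sample,
            "group": group,
            "timepoint": timepoint,
            "gene": gene,
            "replicate": i,
            "ct": c,
        }
        for i, c in enumerate(cts)
    ]


class TestAverageReplicates:
    def test_hand_arithmetic(self):
        table = pd.DataFrame(
            ct_rows("s1", "wt", "ef1a", [20.0, 20.2, 19.8])
            + ct_rows("s1", "wt", "efemp1", [24.0, 24.0, 24.0])
        )
        out = qpcr.average_replicates(table)
        row = out[out.gene == "ef1a"].iloc[0]
        assert row["mean_ct"] == pytest.approx(20.0)
        assert row["n_replicates"] == 3

    def test_single_replicate_kept_with_count_one(self):
        table = pd.DataFrame(
            ct_rows("s1", "wt", "ef1a", [20.0]) + ct_rows("s1", "wt", "g", [25.0])
        )
        out = qpcr.average_replicates(table)
        assert (out["n_replicates"] == 1).all()

    def test_non_finite_ct_rejected(self):
        table = pd.DataFrame(ct_rows("s1", "wt", "ef1a", [20.0, np.nan]))
        with pytest.raises(InvalidInputError):
            qpcr.average_replicates(table)

    def test_sample_missing_a_gene_rejected(self):
        table = pd.DataFrame(
            ct_rows("s1", "wt", "ef1a", [20.0])
            + ct_rows("s1", "wt", "g", [25.0])
            + ct_rows("s2", "wt", "ef1a", [20.0])
        )
        with pytest.raises(InvalidInputError):
            qpcr.average_replicates(table)


def mean_cts_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "timepoint", "gene", "mean_ct"]
    ).assign(n_replicates=3)


class TestRelativeExpression:
    def test_hand_arithmetic_fold_half(self):
        # case sample: dCt = 25 - 20 = 5; calibrator mean dCt = 4 -> ddCt 1, fold 0.5
        rows = [
            ("cal1", "wt", "t1", "ef1a", 20.0),
            ("cal1", "wt", "t1", "tgt", 24.0),
            ("case1", "mut", "t1", "ef1a", 20.0),
            ("case1", "mut", "t1", "tgt", 25.0),
        ]
        out = qpcr.relative_expression(mean_cts_frame(rows), "tgt", "ef1a", "wt")
        case = out[out.group == "mut"].iloc[0]
        assert case["delta_ct"] == pytest.approx(5.0)
        assert case["delta_delta_ct"] == pytest.approx(1.0)
        assert case["fold_change"] == pytest.approx(0.5)

    def test_calibrator_identity_fold_one(self):
        rows = [
            ("cal1", "wt", "t1", "ef1a", 20.0),
            ("cal1", "wt", "t1", "tgt", 24.0),
        ]
        out = qpcr.relative_expression(mean_cts_frame(rows), "tgt", "ef1a", "wt")
        assert out["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_one_cycle_lower_ct_doubles_expression(self):
        rows = [
            ("cal1", "wt", "t1", "ef1a", 20.0),
            ("cal1", "wt", "t1", "tgt", 24.0),
            ("case1", "mut", "t1", "ef1a", 20.0),
            ("case1", "mut", "t1", "tgt", 23.0),
        ]
        out = qpcr.relative_expression(mean_cts_frame(rows), "tgt", "ef1a", "wt")
        assert out[out.group == "mut"]["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_calibrator_geometric_mean_is_exactly_one(self, rng):
        rows = []
        for i in range(6):
            rows.append((f"cal{i}", "wt", "t1", "ef1a", 20 + rng.normal(0, 0.5)))
            rows.append((f"cal{i}", "wt", "t1", "tgt", 24 + rng.normal(0, 0.5)))
        out = qpcr.relative_expression(mean_cts_frame(rows), "tgt", "ef1a", "wt")
        log_folds = np.log2(out["fold_change"])
        assert log_folds.mean() == pytest.approx(0.0, abs=1e-12)

    def test_constant_ct_shift_leaves_folds_unchanged(self):
        rows = [
            ("cal1", "wt", "t1", "ef1a", 20.0),
            ("cal1", "wt", "t1", "tgt", 24.0),
            ("case1", "mut", "t1", "ef1a", 20.0),
            ("case1", "mut", "t1", "tgt", 25.0),
        ]
        base = qpcr.relative_expression(mean_cts_frame(rows), "tgt", "ef1a", "wt")
        shifted_rows = [(s, g, t, gene, ct + 3.0 if s == "case1" else ct)
                        for s, g, t, gene, ct in rows]
        shifted = qpcr.relative_expression(
            mean_cts_frame(shifted_rows), "tgt", "ef1a", "wt"
        )
        assert np.allclose(base["fold_change"], shifted["fold_change"])

    @settings(derandomize=True, max_examples=40)
    @given(shift=st.floats(-5.0, 5.0))
    def test_shift_invariance_for_any_constant(self, shift):
        """Adding any constant to both genes of a sample leaves its dCt, ddCt
        and fold unchanged (pipetting/input-amount differences cancel)."""
        rows = [
            ("cal1", "wt", "t1", "ef1a", 20.0),
            ("cal1", "wt", "t1", "tgt", 24.0),
            ("case1", "mut", "t1", "ef1a", 20.0 + shift),
            ("case1", "mut", "t1", "tgt", 25.0 + shift),
        ]
        out = qpcr.relative_expression(mean_cts_frame(rows), "tgt", "ef1a", "wt")
        case = out[out.group == "mut"].iloc[0]
        assert case["delta_ct"] == pytest.approx(5.0)
        assert case["fold_change"] == pytest.approx(0.5)

    def test_per_timepoint_calibration(self):
        rows = [
            ("cal1", "wt", "d2", "ef1a", 20.0),
            ("cal1", "wt", "d2", "tgt", 24.0),
            ("case1", "mut", "d2", "ef1a", 20.0),
            ("case1", "mut", "d2", "tgt", 25.0),
            # week-4 stratum has a different calibrator baseline
            ("cal2", "wt", "w4", "ef1a", 20.0),
            ("cal2", "wt", "w4", "tgt", 26.0),
            ("case2", "mut", "w4", "ef1a", 20.0),
            ("case2", "mut", "w4", "tgt", 27.0),
        ]
        out = qpcr.relative_expression(mean_cts_frame(rows), "tgt", "ef1a", "wt")
        mut = out[out.group == "mut"].set_index("timepoint")
        assert mut.loc["d2", "fold_change"] == pytest.approx(0.5)
        assert mut.loc["w4", "fold_change"] == pytest.approx(0.5)

    def test_missing_reference_gene_rejected(self):
        rows = [("cal1", "wt", "t1", "tgt", 24.0)]
        with pytest.raises(InvalidInputError):
            qpcr.relative_expression(mean_cts_frame(rows), "tgt", "ef1a", "wt")

    def test_missing_calibrator_group_rejected(self):
        rows = [
            ("case1", "mut", "t1", "ef1a", 20.0),
            ("case1", "mut", "t1", "tgt", 25.0),
        ]
        with pytest.raises(InvalidInputError):
            qpcr.relative_expression(mean_cts_frame(rows), "tgt", "ef1a", "wt")


class TestSynthRecovery:
    def spec(self, **kw):
        defaults = dict(
            genes=("ef1a", "efemp1", "egr1"),
            fold_changes={
                "wt": {"efemp1": 1.0, "egr1": 1.0},
                "mut": {"efemp1": 0.5, "egr1": 2.0},
            },
        )
        return synthgen.QpcrDesignSpec(**{**defaults, **kw})

    def test_design_row_counts(self):
        table, _ = synthgen.gen_ct_table(self.spec())
        per = table.groupby(["group", "gene"]).size()
        assert (per == 4 * 3).all()  # four samples x three replicates

    def test_zero_noise_recovery_is_exact(self):
        table, truth = synthgen.gen_ct_table(self.spec(ct_noise_sd=0.0))
        expr = qpcr.expression_table(table, "ef1a", "wt")
        for group, folds in truth["fold_changes"].items():
            for gene, fold in folds.items():
                got = expr[(expr.group == group) & (expr.gene == gene)]["fold_change"]
                assert np.allclose(got, fold)

    def test_unit_folds_give_zero_ddct(self):
        spec = self.spec(
            fold_changes={
                "wt": {"efemp1": 1.0, "egr1": 1.0},
                "mut": {"efemp1": 1.0, "egr1": 1.0},
            },
            ct_noise_sd=0.0,
        )
        table, _ = synthgen.gen_ct_table(spec)
        expr = qpcr.expression_table(table, "ef1a", "wt")
        assert np.allclose(expr["delta_delta_ct"], 0.0)

    def test_missing_reference_gene_invalid_spec(self):
        with pytest.raises(InvalidSpecError):
            self.spec(genes=("efemp1", "egr1"))

    def test_non_unit_calibrator_fold_invalid_spec(self):
        with pytest.raises(InvalidSpecError):
            self.spec(
                fold_changes={
                    "wt": {"efemp1": 2.0, "egr1": 1.0},
                    "mut": {"efemp1": 0.5, "egr1": 2.0},
                }
            )
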