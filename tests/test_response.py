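from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from gliosig import (
    SignatureDefinition,
    count_responders,
    delta_delta_ct,
    generate_pdtf_pairs,
    generate_qpcr_plate,
    paired_log2_fold_changes,
    signature_response,
)
from conftest import small_config


def ct_table(rows):
    return pd.DataFrame(rows, columns=["subject_id", "condition", "gene", "ct", "replicate"])


def wilcoxon_sign_enumeration(values):
    """Oracle: exact one-sided (less) p by enumerating all sign assignments."""
    values = np.asarray(values, dtype=float)
    values = values[values != 0]
    ranks = rankdata(np.abs(values))
    w_obs = ranks[values > 0].sum()
    n = len(values)
    total, count = 0, 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if w <= w_obs:
            count += 1
    return count / total


class TestDeltaDeltaCt:
    def test_identical_ct_gives_fold_one(self):
        rows = [
            ("p1", c, g, 20.0 if g == "GAPDH" else 25.0, r)
            for c in ("control", "treated")
            for g in ("GAPDH", "S100A9")
            for r in (1, 2)
        ]
        res = delta_delta_ct(ct_table(rows), "GAPDH")
        assert res.loc[0, "fold"] == pytest.approx(1.0)

    def test_one_cycle_drop_doubles_fold(self):
        rows = [
            ("p1", "control", "GAPDH", 20.0, 1),
            ("p1", "treated", "GAPDH", 20.0, 1),
            ("p1", "control", "S100A9", 25.0, 1),
            ("p1", "treated", "S100A9", 24.0, 1),
        ]
        res = delta_delta_ct(ct_table(rows), "GAPDH")
        row = res.set_index("gene").loc["S100A9"]
        assert row["ddct"] == pytest.approx(-1.0)
        assert row["fold"] == pytest.approx(2.0)

    def test_replicates_averaged_before_dct(self):
        rows = [
            ("p1", "control", "GAPDH", 19.5, 1),
            ("p1", "control", "GAPDH", 20.5, 2),
            ("p1", "treated", "GAPDH", 20.0, 1),
            ("p1", "control", "S100A9", 25.0, 1),
            ("p1", "treated", "S100A9", 24.0, 1),
        ]
        res = delta_delta_ct(ct_table(rows), "GAPDH")
        assert res.loc[0, "fold"] == pytest.approx(2.0)

    def test_plate_shift_invariance(self):
        rows = [
            ("p1", "control", "GAPDH", 20.0, 1),
            ("p1", "treated", "GAPDH", 21.0, 1),
            ("p1", "control", "S100A9", 25.0, 1),
            ("p1", "treated", "S100A9", 24.5, 1),
        ]
        base = delta_delta_ct(ct_table(rows), "GAPDH")
        shifted_rows = [(s, c, g, ct + 3.0, r) for s, c, g, ct, r in rows]
        shifted = delta_delta_ct(ct_table(shifted_rows), "GAPDH")
        assert np.allclose(base["fold"], shifted["fold"])

    def test_missing_reference_or_condition_rejected(self):
        rows = [("p1", "control", "S100A9", 25.0, 1), ("p1", "treated", "S100A9", 24.0, 1)]
        with pytest.raises(ValueError, match="reference gene"):
            delta_delta_ct(ct_table(rows), "GAPDH")
        rows = [("p1", "control", "GAPDH", 20.0, 1), ("p1", "control", "S100A9", 25.0, 1)]
        with pytest.raises(ValueError, match="treated"):
            delta_delta_ct(ct_table(rows), "GAPDH")


class TestSignatureResponse:
    def test_no_change_is_degenerate_non_responder(self):
        call = signature_response(np.zeros(5), "p1")
        assert not call.responder
        assert call.p == 1.0
        assert "no change" in call.rule

    def test_uniform_halving_calls_responder(self):
        call = signature_response(np.full(10, -1.0), "p1")
        assert call.responder
        assert call.delta_score == pytest.approx(-1.0)

    def test_sign_flip_never_responds(self):
        rng = np.random.default_rng(0)
        fc = -np.abs(rng.normal(1, 0.2, size=12))
        assert signature_response(fc, "p1").responder
        assert not signature_response(-fc, "p1").responder

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_exact_p_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        fc = rng.normal(-0.3, 1.0, size=9)
        call = signature_response(fc, "p1")
        assert call.p == pytest.approx(wilcoxon_sign_enumeration(fc), abs=1e-12)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            signature_response([-1.0, -2.0], "p1")

    def test_count_responders(self):
        calls = [signature_response(np.full(10, -1.0 if i < 8 else 0.2), f"p{i}")
                 for i in range(16)]
        n, total, frac = count_responders(calls)
        assert (n, total, frac) == (8, 16, 0.5)
        with pytest.raises(ValueError):
            count_responders([])


class TestPdtfWorkflow:
    def test_saturated_effect_calls_every_responder(self):
        cfg = small_config(seed=3)
        from gliosig import generate_cohort

        _, _, truth = generate_cohort(cfg)
        matrix, meta, ptruth = generate_pdtf_pairs(
            cfg, truth, n_subjects=8, responder_fraction=1.0,
            effect_log2fc=4.0, noise_sd=0.05,
        )
        sig = SignatureDefinition("planted", cfg.anchor_gene, truth.planted_signature)
        fc = paired_log2_fold_changes(matrix, meta, sig)
        calls = [signature_response(fc[s], s) for s in fc.columns]
        assert all(c.responder for c in calls)
        assert all(ptruth.responder_labels[c.subject_id] for c in calls)

    def test_zero_fraction_centers_deltas_at_zero(self):
        cfg = small_config(seed=4)
        from gliosig import generate_cohort

        _, _, truth = generate_cohort(cfg)
        matrix, meta, _ = generate_pdtf_pairs(
            cfg, truth, n_subjects=12, responder_fraction=0.0,
        )
        sig = SignatureDefinition("planted", cfg.anchor_gene, truth.planted_signature)
        fc = paired_log2_fold_changes(matrix, meta, sig)
        deltas = fc.mean(axis=0)
        assert abs(deltas.mean()) < 0.1
        calls = [signature_response(fc[s], s) for s in fc.columns]
        assert sum(c.responder for c in calls) <= 2  # ~5% false positive rate


class TestQpcrPlate:
    def test_zero_noise_reproduces_exact_ct_shift(self):
        ct = generate_qpcr_plate(
            2, ["S100A9"], "GAPDH", {"S100A9": 2.0}, ct_noise_sd=0.0, seed=1
        )
        res = delta_delta_ct(ct, "GAPDH")
        assert np.allclose(res["fold"], 2.0)
        ref = ct[ct.gene == "GAPDH"].pivot_table(index="subject_id", columns="condition",
                                                 values="ct")
        assert np.allclose(ref["control"], ref["treated"])

    def test_unit_folds_give_identical_conditions(self):
        ct = generate_qpcr_plate(
            3, ["A", "B"], "GAPDH", {"A": 1.0, "B": 1.0}, ct_noise_sd=0.0, seed=2
        )
        piv = ct.pivot_table(index=["subject_id", "gene"], columns="condition", values="ct")
        assert np.allclose(piv["control"], piv["treated"])

    def test_noisy_fold_recovery_within_band(self):
        ct = generate_qpcr_plate(
            10, ["S100A9"], "GAPDH", {"S100A9": 2.0}, ct_noise_sd=0.1, seed=5
        )
        res = delta_delta_ct(ct, "GAPDH")
        assert 1.8 <= res["fold"].mean() <= 2.2

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            generate_qpcr_plate(2, ["A"], "GAPDH", {"GAPDH": 2.0})
        with pytest.raises(ValueError, match="> 0"):
            generate_qpcr_plate(2, ["A"], "GAPDH", {"A": -1.0})
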