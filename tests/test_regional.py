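from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from gliosig import (
    ExpressionMatrix,
    mann_whitney_u,
    region_mean_profile,
    region_upregulated_genes,
)

from conftest import case_samples


def exact_mwu_enumeration(a, b):
    """Brute-force oracle: U distribution over all C(n, n_a) group labelings."""
    a, b = list(a), list(b)
    pooled = a + b
    n, na = len(pooled), len(a)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)

    def u_of(idx):
        r = sum(ranks[i] for i in idx)
        return r - na * (na + 1) / 2

    u_obs = u_of(range(na))
    us = [u_of(c) for c in combinations(range(n), na)]
    lo = sum(1 for u in us if u <= u_obs) / len(us)
    hi = sum(1 for u in us if u >= u_obs) / len(us)
    return u_obs, min(1.0, 2 * min(lo, hi))


def region_metadata(sample_regions: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": list(sample_regions),
            "region": list(sample_regions.values()),
            "diagnostic_label": "case",
            "survival_time": np.nan,
            "event": np.nan,
            "subject_id": list(sample_regions),
            "condition": None,
        }
    )


class TestRegionMeanProfile:
    def test_constant_gene_has_constant_profile(self):
        meta = region_metadata({"s1": "LE", "s2": "CT", "s3": "PAN", "s4": "PAN"})
        data = pd.DataFrame(
            {"s1": [5.0, 1.0], "s2": [5.0, 2.0], "s3": [5.0, 3.0], "s4": [5.0, 5.0]},
            index=["flat", "var"],
        )
        prof = region_mean_profile(ExpressionMatrix(data), meta)
        assert (prof.means.loc["flat"] == 5.0).all()
        assert prof.means.loc["var", "PAN"] == pytest.approx(4.0)
        assert prof.n_per_region == {"LE": 1, "CT": 1, "PAN": 2}

    def test_single_sample_regions_reproduce_values(self):
        meta = region_metadata({"s1": "LE", "s2": "MVP"})
        data = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]}, index=["a", "b"])
        prof = region_mean_profile(ExpressionMatrix(data), meta)
        assert prof.means.loc["a", "LE"] == 1.0
        assert prof.means.loc["b", "MVP"] == 4.0

    def test_unlabelled_sample_rejected(self):
        meta = region_metadata({"s1": "LE", "s2": "CT"})
        meta.loc[1, "region"] = None
        data = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="without region"):
            region_mean_profile(ExpressionMatrix(data), meta)

    def test_planted_region_up_genes_peak_in_target_region(self, small_cohort):
        matrix, metadata, truth = small_cohort
        cases = case_samples(metadata)
        prof = region_mean_profile(matrix.subset_samples(cases), metadata)
        targets = truth.config["target_regions"]
        peaked = sum(
            prof.means.loc[g].idxmax() in targets for g in truth.region_up_members
        )
        assert peaked / len(truth.region_up_members) >= 0.95


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        u, _ = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0

    def test_identical_multisets_give_p_one(self):
        u, p = mann_whitney_u([1, 2, 5], [1, 2, 5])
        assert p == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "a, b",
        [
            ([1, 3], [2, 4]),
            ([1, 2, 9], [4, 6, 7]),
            ([10, 20, 30, 40], [15, 25]),
        ],
    )
    def test_exact_p_matches_enumeration_oracle(self, a, b):
        u, p = mann_whitney_u(a, b)
        u_oracle, p_oracle = exact_mwu_enumeration(a, b)
        assert u == pytest.approx(u_oracle)
        assert p == pytest.approx(p_oracle, abs=1e-12)


class TestRegionUpregulated:
    def _separated_case(self):
        rng = np.random.default_rng(0)
        regions = ["PAN"] * 5 + ["CT"] * 5 + ["LE"] * 5
        samples = [f"s{i}" for i in range(15)]
        data = pd.DataFrame(rng.normal(5, 1, size=(3, 15)), index=["up", "null", "flat"],
                            columns=samples)
        data.loc["up", samples[:5]] += 4.0
        data.loc["flat"] = 3.0
        return ExpressionMatrix(data), region_metadata(dict(zip(samples, regions)))

    def test_large_shift_passes_and_constant_does_not(self):
        matrix, meta = self._separated_case()
        gs, results = region_upregulated_genes(matrix, meta, ("PAN",))
        assert "up" in gs.genes
        assert "flat" not in gs.genes
        flat_row = results.set_index("gene").loc["flat"]
        assert flat_row["p"] == 1.0

    def test_swapping_target_and_rest_flips_lfc_sign(self):
        matrix, meta = self._separated_case()
        _, res_pan = region_upregulated_genes(matrix, meta, ("PAN",))
        _, res_rest = region_upregulated_genes(matrix, meta, ("CT", "LE"))
        assert np.allclose(
            res_pan.set_index("gene")["lfc"], -res_rest.set_index("gene")["lfc"]
        )

    def test_bh_q_values_monotone_in_p_and_bounded(self, small_cohort):
        matrix, metadata, truth = small_cohort
        cases = case_samples(metadata)
        _, results = region_upregulated_genes(
            matrix.subset_samples(cases), metadata, tuple(truth.config["target_regions"])
        )
        ordered = results.sort_values("p")
        assert (ordered["q"].to_numpy() >= ordered["p"].to_numpy() - 1e-12).all()
        assert (np.diff(ordered["q"].to_numpy()) >= -1e-12).all()
        assert ordered["q"].max() <= 1.0

    def test_result_independent_of_sample_order(self):
        matrix, meta = self._separated_case()
        shuffled = ExpressionMatrix(matrix.data.iloc[:, ::-1])
        _, a = region_upregulated_genes(matrix, meta, ("PAN",))
        _, b = region_upregulated_genes(shuffled, meta, ("PAN",))
        pd.testing.assert_frame_equal(a, b)

    def test_planted_recovery_on_small_cohort(self, small_cohort):
        matrix, metadata, truth = small_cohort
        cases = case_samples(metadata)
        gs, _ = region_upregulated_genes(
            matrix.subset_samples(cases), metadata, tuple(truth.config["target_regions"])
        )
        tp = len(gs.genes & truth.region_up_members.genes)
        assert tp / len(gs.genes) >= 0.9
        assert tp / len(truth.region_up_members.genes) >= 0.9

    def test_empty_target_region_rejected(self):
        matrix, meta = self._separated_case()
        with pytest.raises(ValueError, match="no samples"):
            region_upregulated_genes(matrix, meta, ("MVP",))
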