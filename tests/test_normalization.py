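"""Two-stage normalization, fold-of-reference scaling, summaries, loading-control QC."""

import numpy as np
import pandas as pd
import pytest

from blotkit import (
    MCConfig,
    default_design,
    generate_table,
    loading_control_qc,
    normalize,
    summarize,
)
from blotkit.synthetic import CONTROL_ANIMAL

QC_MC = MCConfig(pool_size=50_000, reps=5_000, seed=0)


def _normalize_bundle(bundle, reference="normal"):
    return normalize(bundle.table, bundle.blot_set_map, bundle.control_lanes, reference)


def _uniform_table():
    """Two blots, two proteins, all bands equal."""
    rows = []
    for blot in ("B1", "B2"):
        for protein in ("P1", "P2"):
            for i in range(4):
                rows.append((blot, f"L{i + 1:02d}", f"a_{blot}_{i}", "g1" if i < 2 else "g2",
                             protein, 50.0))
            rows.append((blot, "L05", CONTROL_ANIMAL, "control_sample", protein, 50.0))
    return pd.DataFrame(rows, columns=["blot_id", "lane_id", "animal_id", "group",
                                       "protein", "raw_density"])


class TestNormalize:
    def test_all_bands_equal_gives_unity(self):
        table = _uniform_table()
        norm = normalize(table, {"B1": "s", "B2": "s"}, {"B1": "L05", "B2": "L05"}, "g1")
        assert np.allclose(norm.rows.value, 1.0, atol=1e-12)

    def test_pure_batch_effect_cancels_exactly(self, default_bundle):
        base = _normalize_bundle(default_bundle)
        scaled_table = default_bundle.table.copy()
        on_b1 = scaled_table.blot_id == "B1"
        scaled_table.loc[on_b1, "raw_density"] *= 3.0
        scaled = normalize(scaled_table, default_bundle.blot_set_map,
                           default_bundle.control_lanes, "normal")
        merged = base.rows.merge(scaled.rows, on=["animal_id", "group", "protein"])
        assert np.allclose(merged.value_x, merged.value_y, rtol=1e-12)

    def test_reference_group_mean_is_one_per_protein(self, default_bundle):
        norm = _normalize_bundle(default_bundle)
        ref = norm.rows[norm.rows.group == "normal"]
        assert np.allclose(ref.groupby("protein").value.mean(), 1.0, atol=1e-12)

    def test_zero_noise_recovers_truth_exactly(self, zero_noise_bundle):
        norm = _normalize_bundle(zero_noise_bundle)
        truth = norm.rows.apply(
            lambda r: zero_noise_bundle.truth(r.group, r.protein), axis=1
        )
        assert np.allclose(norm.rows.value, truth, rtol=1e-12)

    def test_batch_effects_removed_from_group_means(self):
        """Strong multiplicative blot effects leave recovered means near truth."""
        design = default_design(batch_sd=0.3, loading_sd=0.0)
        errors = []
        for seed in range(5):
            bundle = generate_table(design, seed=seed)
            norm = _normalize_bundle(bundle)
            s = summarize(norm)
            n_ref = design.group_sizes[design.reference_group]
            for row in s.itertuples():
                mu = design.get_effect(row.group, row.measure)
                # own-group mean noise plus fold-of-reference rescaling noise
                se = np.sqrt(
                    design.get_noise_sd(row.group, row.measure) ** 2 / row.n
                    + (mu * design.get_noise_sd(design.reference_group, row.measure)) ** 2
                    / n_ref
                )
                errors.append(abs(row.mean - mu) / max(se, 1e-9))
        assert np.quantile(errors, 0.99) < 4.0

    def test_missing_control_band_error_names_protein_and_blot(self, default_bundle):
        table = default_bundle.table
        broken = table[~((table.blot_id == "B1") & (table.animal_id == CONTROL_ANIMAL)
                         & (table.protein == "VGLUT1"))]
        with pytest.raises(ValueError, match="VGLUT1"):
            normalize(broken, default_bundle.blot_set_map, default_bundle.control_lanes,
                      "normal")

    def test_unassigned_blot_rejected(self, default_bundle):
        with pytest.raises(ValueError, match="B2"):
            normalize(default_bundle.table, {"B1": "s"}, default_bundle.control_lanes,
                      "normal")

    def test_provenance_records_steps(self, default_bundle):
        norm = _normalize_bundle(default_bundle)
        assert norm.provenance["steps"] == [
            "blot_set_average_per_protein",
            "control_sample_ratio_per_blot",
            "fold_of_reference_group",
        ]


class TestSummarize:
    def test_hand_computed_values(self):
        df = pd.DataFrame({
            "group": "g", "protein": "p", "animal_id": list("abcde"),
            "value": [0.6, 0.8, 1.0, 1.2, 1.4],
        })
        s = summarize(df).iloc[0]
        assert s["mean"] == pytest.approx(1.0)
        assert s["sd"] == pytest.approx(np.sqrt(0.1), rel=1e-9)
        assert s["sem"] == pytest.approx(np.sqrt(0.1 / 5), rel=1e-9)

    def test_degenerate_values(self):
        df = pd.DataFrame({"group": "g", "protein": "p", "animal_id": list("abcd"),
                           "value": [1.0] * 4})
        s = summarize(df).iloc[0]
        assert (s["mean"], s["sd"], s["sem"]) == (1.0, 0.0, 0.0)

    def test_small_group_rejected(self):
        df = pd.DataFrame({"group": "g", "protein": "p", "animal_id": ["a"], "value": [1.0]})
        with pytest.raises(ValueError, match="< 2 animals"):
            summarize(df)

    def test_deterministic_given_input(self, default_bundle):
        norm = _normalize_bundle(default_bundle)
        pd.testing.assert_frame_equal(summarize(norm), summarize(norm), check_exact=True)


class TestLoadingControlQC:
    def test_shifted_control_always_fails(self):
        """A 1.5-fold GAPDH shift in one group dwarfs sampling error."""
        for seed in range(8):
            bundle = generate_table(default_design(), seed=seed)
            table = bundle.table.copy()
            shifted = (table.group == "MD") & (table.protein == "GAPDH")
            table.loc[shifted, "raw_density"] *= 1.5
            norm = normalize(table, bundle.blot_set_map, bundle.control_lanes, "normal")
            report = loading_control_qc(norm, "GAPDH", QC_MC.replace(seed=seed))
            assert not report.passed
            flagged = set(report.comparisons.loc[report.comparisons.significant, "comparator"])
            assert "MD" in flagged

    def test_null_control_passes_more_often_than_not_failing_grossly(self):
        """Under a true-null GAPDH the QC passes at a rate far above the shifted case.

        The plug-in Monte-Carlo comparison is anti-conservative at n=6-8
        (reference moments are treated as known), so the null pass rate sits
        near 0.5 for three comparisons rather than (1-alpha)^3.
        """
        passes = 0
        n_seeds = 40
        for seed in range(n_seeds):
            bundle = generate_table(default_design(), seed=100 + seed)
            norm = _normalize_bundle(bundle)
            report = loading_control_qc(norm, "GAPDH", QC_MC.replace(seed=seed))
            passes += report.passed
        assert passes / n_seeds > 0.2

    def test_single_group_trivially_passes(self):
        bundle = generate_table(default_design(), seed=3)
        table = bundle.table
        keep = (table.group == "normal") | (table.animal_id == CONTROL_ANIMAL)
        norm = normalize(table[keep], bundle.blot_set_map, bundle.control_lanes, "normal")
        report = loading_control_qc(norm, "GAPDH", QC_MC)
        assert report.passed
        assert report.comparisons.empty

    def test_missing_control_measurements_listed(self, default_bundle):
        norm = _normalize_bundle(default_bundle)
        rows = norm.rows
        broken = norm.__class__(
            rows=rows[~((rows.protein == "GAPDH") & (rows.animal_id == "MD_01"))],
            reference_group=norm.reference_group,
            provenance=norm.provenance,
        )
        with pytest.raises(ValueError, match="MD_01"):
            loading_control_qc(broken, "GAPDH", QC_MC)
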