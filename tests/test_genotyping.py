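"""Cluster calling, dye-switch code combination, and experiment QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from beadmosaic.genotyping import (
    CODES,
    CountSummary,
    _threshold_model,
    _threshold_codes,
    call_genotypes,
    fit_cluster_model,
    normalize_intensities,
    qc_experiment,
)
from beadmosaic.images import INTENSITY_COLUMNS


def _table(ch1_s1, ch2_s1, ch1_ds, ch2_ds):
    n = len(ch1_s1)
    return pd.DataFrame({
        "bead_id": np.arange(1, n + 1),
        "y": np.zeros(n), "x": np.zeros(n), "area": np.full(n, 50.0),
        "ch1_scan1": ch1_s1, "ch2_scan1": ch2_s1,
        "ch1_dyeswitch": ch1_ds, "ch2_dyeswitch": ch2_ds,
    })


def _synthetic_classes(rng, n=400, p=(0.7, 0.12, 0.12, 0.06), noise=0.02):
    """Intensity table from nominal class profiles: EMPTY/WT/MUT/MIXED."""
    bg, hi = 100.0, 1000.0
    profiles = {  # (ch1_s1, ch2_s1, ch1_ds, ch2_ds)
        "EMPTY": (bg, bg, bg, bg),
        "WT": (hi, bg, bg, hi),
        "MUT": (bg, hi, hi, bg),
        "MIXED": (hi, hi, hi, hi),
    }
    classes = rng.choice(list(profiles), size=n, p=p)
    cols = {c: [] for c in INTENSITY_COLUMNS}
    for cls in classes:
        for col, v in zip(INTENSITY_COLUMNS, profiles[cls]):
            cols[col].append(v * rng.lognormal(0, noise))
    return _table(**dict(zip(
        ["ch1_s1", "ch2_s1", "ch1_ds", "ch2_ds"],
        [np.array(cols[c]) for c in INTENSITY_COLUMNS]))), classes


class TestNormalization:
    def test_gain_scale_invariance(self):
        rng = np.random.default_rng(0)
        table, _ = _synthetic_classes(rng)
        doubled = table.copy()
        doubled["ch1_scan1"] = 2.0 * doubled["ch1_scan1"]
        a = normalize_intensities(table)
        b = normalize_intensities(doubled)
        np.testing.assert_allclose(a["ch1_scan1"], b["ch1_scan1"], atol=1e-12)

    def test_monotone_per_channel(self):
        rng = np.random.default_rng(1)
        table, _ = _synthetic_classes(rng)
        norm = normalize_intensities(table)
        for col in INTENSITY_COLUMNS:
            order_raw = np.argsort(table[col].to_numpy())
            order_norm = np.argsort(norm[col].to_numpy())
            np.testing.assert_array_equal(order_raw, order_norm)

    def test_zero_spread_rejected(self):
        table = _table(*[np.full(10, 100.0)] * 4)
        with pytest.raises(ValueError, match="zero spread"):
            normalize_intensities(table)

    def test_too_few_beads(self):
        table = _table(*[np.array([1.0])] * 4)
        with pytest.raises(ValueError):
            normalize_intensities(table)


class TestClusterModel:
    def test_four_separated_clusters_fully_recovered(self):
        rng = np.random.default_rng(2)
        table, classes = _synthetic_classes(rng, n=600)
        norm = normalize_intensities(table)
        model = fit_cluster_model(norm, "scan1", seed=0)
        expected = {"EMPTY": "00", "WT": "10", "MUT": "01", "MIXED": "11"}
        assert (model.codes.to_numpy()
                == np.array([expected[c] for c in classes])).all()
        assert model.confident.all()

    def test_all_background_is_all_00(self):
        rng = np.random.default_rng(3)
        vals = [100.0 * rng.lognormal(0, 0.02, 200) for _ in range(4)]
        norm = normalize_intensities(_table(*vals))
        model = fit_cluster_model(norm, "scan1", seed=0)
        assert (model.codes == "00").all()

    def test_order_permutation_invariance(self):
        """Shuffling bead order (hence component initialization inputs)
        must not change any bead's code: mapping is by component means."""
        rng = np.random.default_rng(4)
        table, _ = _synthetic_classes(rng, n=500)
        norm = normalize_intensities(table)
        base = fit_cluster_model(norm, "scan1", seed=0)
        perm = rng.permutation(len(norm))
        shuffled = norm.iloc[perm].reset_index(drop=True)
        model = fit_cluster_model(shuffled, "scan1", seed=99)
        merged = base.codes.loc[shuffled["bead_id"]].to_numpy()
        assert (model.codes.to_numpy() == merged).all()

    def test_rare_cluster_not_absorbed(self):
        """Two mutant beads among 400 must still be called 01."""
        rng = np.random.default_rng(5)
        table, classes = _synthetic_classes(rng, n=400,
                                            p=(0.895, 0.1, 0.005, 0.0))
        if (classes == "MUT").sum() == 0:
            pytest.skip("no mutant drawn")
        norm = normalize_intensities(table)
        model = fit_cluster_model(norm, "scan1", seed=0)
        assert (model.codes.to_numpy()[classes == "MUT"] == "01").all()

    def test_threshold_method(self):
        rng = np.random.default_rng(6)
        table, classes = _synthetic_classes(rng, n=300)
        norm = normalize_intensities(table)
        model = fit_cluster_model(norm, "scan1", method="threshold")
        assert model.method == "threshold"
        expected = {"EMPTY": "00", "WT": "10", "MUT": "01", "MIXED": "11"}
        assert (model.codes.to_numpy()
                == np.array([expected[c] for c in classes])).all()

    def test_too_few_beads(self):
        table = _table(*[np.arange(4, dtype=float) + 1] * 4)
        with pytest.raises(ValueError):
            fit_cluster_model(table, "scan1")


class TestCallGenotypes:
    def _model(self, codes):
        quad = np.array([CODES.index(c) for c in codes])
        return _threshold_model(quad, pd.Index(np.arange(len(codes)),
                                               name="bead_id"))

    @pytest.mark.parametrize("c1,c2,expected", [
        ("10", "01", "WT"),       # 1001
        ("01", "10", "MUT"),      # 0110
        ("00", "00", "EMPTY"),
        ("11", "00", "MULTI"),
        ("10", "11", "MULTI"),
        ("10", "10", "INCONSISTENT"),  # no dye switch happened: artefact
        ("10", "00", "INCONSISTENT"),  # signal lost in round 2
        ("01", "01", "INCONSISTENT"),
    ])
    def test_code_classification(self, c1, c2, expected):
        calls = call_genotypes(self._model([c1]), self._model([c2]))
        assert calls.calls["class"].iloc[0] == expected
        assert calls.calls["code"].iloc[0] == c1 + c2

    def test_missing_round_rejected(self):
        m = self._model(["10"])
        with pytest.raises(ValueError, match="both rounds"):
            call_genotypes(m, None)

    def test_mismatched_beads_rejected(self):
        a = self._model(["10", "00"])
        b = _threshold_model(np.array([1]), pd.Index([5], name="bead_id"))
        with pytest.raises(ValueError):
            call_genotypes(a, b)

    @given(st.lists(st.sampled_from(CODES), min_size=1, max_size=40),
           st.lists(st.sampled_from(CODES), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_count_conservation(self, codes1, codes2):
        """Class counts always sum to the number of beads."""
        n = min(len(codes1), len(codes2))
        calls = call_genotypes(self._model(codes1[:n]),
                               self._model(codes2[:n]))
        s = calls.summary
        assert (s.n_wt + s.n_mut + s.n_empty + s.n_multi
                + s.n_inconsistent == s.n_beads == n)

    def test_end_to_end_confusion_matrix_diagonal(self, normalized_table):
        """On a well-separated simulated field every bead class is
        recovered exactly and MIXED beads are eliminated as MULTI."""
        _, norm, true_classes = normalized_table
        r1 = fit_cluster_model(norm, "scan1", seed=0)
        r2 = fit_cluster_model(norm, "dyeswitch", seed=0)
        calls = call_genotypes(r1, r2)
        expected = {"EMPTY": "EMPTY", "WT": "WT", "MUT": "MUT",
                    "MIXED": "MULTI"}
        predicted = calls.calls["class"].to_numpy()
        assert (predicted == np.array([expected[c] for c in true_classes])).all()

    def test_called_fraction_tracks_molecule_fraction(self, normalized_table):
        """The called mutant fraction among WT+MUT beads estimates the
        single-molecule mutant fraction (within binomial scatter)."""
        cfg, norm, true_classes = normalized_table
        r1 = fit_cluster_model(norm, "scan1", seed=0)
        r2 = fit_cluster_model(norm, "dyeswitch", seed=0)
        s = call_genotypes(r1, r2).summary
        p_hat = s.n_mut / (s.n_mut + s.n_wt)
        # among single-allele beads the mutant share is close to true_vaf
        n = s.n_mut + s.n_wt
        sd = np.sqrt(cfg.true_vaf * (1 - cfg.true_vaf) / n)
        assert abs(p_hat - cfg.true_vaf) < 3 * sd


class TestQC:
    def _summary(self, n_wt, n_mut, n_empty, n_multi=0, n_inc=0):
        n = n_wt + n_mut + n_empty + n_multi + n_inc
        return CountSummary(n_beads=n, n_wt=n_wt, n_mut=n_mut,
                            n_empty=n_empty, n_multi=n_multi,
                            n_inconsistent=n_inc)

    def test_ten_percent_positive_passes(self):
        qc = qc_experiment(self._summary(95, 5, 900))
        assert qc.passed and not qc.warnings

    def test_over_thirty_percent_fails(self):
        qc = qc_experiment(self._summary(330, 20, 650))
        assert not qc.passed
        assert "discard" in qc.reasons[0]

    def test_no_signal_fails(self):
        qc = qc_experiment(self._summary(0, 0, 990, n_multi=10))
        assert not qc.passed

    def test_large_deviation_warns(self):
        qc = qc_experiment(self._summary(4, 0, 996))
        assert qc.passed and qc.warnings

    def test_empty_experiment_errors(self):
        with pytest.raises(ValueError):
            qc_experiment(self._summary(0, 0, 0))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            CountSummary(n_beads=10, n_wt=5, n_mut=0, n_empty=0,
                         n_multi=0, n_inconsistent=0)
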