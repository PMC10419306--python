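import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

from scstate.io_formats import CountMatrix
from scstate.qc import QCThresholds, apply_thresholds, compute_metrics, deferred_mito_filter, downsample


def matrix_from_columns(columns, genes):
    return CountMatrix(
        genes=genes,
        barcodes=[f"c{i}" for i in range(len(columns))],
        counts=sparse.csc_matrix(np.array(columns).T),
        sample_id="qc",
    )


def metrics_frame(rows):
    return pd.DataFrame(rows, columns=["n_features", "n_counts", "pct_mito"])


class TestComputeMetrics:
    def test_hand_computed_cell(self):
        m = matrix_from_columns([[3, 2, 5]], genes=["geneA", "geneB", "MT-1"])
        met = compute_metrics(m)
        assert met.loc[0, "n_features"] == 3
        assert met.loc[0, "n_counts"] == 10
        assert met.loc[0, "pct_mito"] == 50.0

    def test_all_zero_cell_is_zeroed(self):
        m = matrix_from_columns([[0, 0, 0]], genes=["geneA", "geneB", "MT-1"])
        met = compute_metrics(m)
        assert tuple(met.loc[0, ["n_features", "n_counts", "pct_mito"]]) == (0, 0, 0.0)

    def test_no_mito_genes_means_zero_pct(self):
        m = matrix_from_columns([[3, 2], [1, 0]], genes=["geneA", "geneB"])
        assert (compute_metrics(m)["pct_mito"] == 0).all()


HEALTHY_BAL = QCThresholds(min_features=1850, max_features=7450, max_counts=85000, max_pct_mito=12.0)


class TestApplyThresholds:
    def test_boundary_cells_kept_strict_violations_discarded(self):
        met = metrics_frame(
            [
                (1850, 10000, 5.0),  # exactly at the lower bound: kept
                (1849, 10000, 5.0),  # below it: discarded
                (7450, 10000, 5.0),  # at the upper bound: kept
                (7451, 10000, 5.0),  # above it: discarded
                (3000, 85000, 12.0),  # both right at the caps: kept
                (3000, 85001, 5.0),  # over the count cap: discarded
                (3000, 10000, 12.1),  # over the mito cap: discarded
            ]
        )
        assert apply_thresholds(met, HEALTHY_BAL).tolist() == [
            True,
            False,
            True,
            False,
            True,
            False,
            False,
        ]

    def test_unset_thresholds_keep_everything(self):
        met = metrics_frame([(0, 0, 100.0), (9999, 10**7, 0.0)])
        assert apply_thresholds(met, QCThresholds()).all()

    def test_ten_cell_fixture_with_three_single_rule_violators(self):
        good = (3000, 10000, 5.0)
        met = metrics_frame(
            [good] * 7
            + [
                (1000, 10000, 5.0),  # too few features
                (3000, 90000, 5.0),  # too many counts
                (3000, 10000, 20.0),  # too much mito
            ]
        )
        assert apply_thresholds(met, HEALTHY_BAL).sum() == 7

    def test_defer_mito_skips_the_mito_rule(self):
        met = metrics_frame([(3000, 10000, 50.0)])
        t = QCThresholds(min_features=1850, max_features=7450, max_counts=85000, max_pct_mito=12.0, defer_mito=True)
        assert apply_thresholds(met, t).all()

    @given(
        nf=st.integers(0, 10000),
        nc=st.integers(0, 100000),
        pm=st.floats(0, 100),
        lo=st.integers(0, 5000),
        hi=st.integers(5000, 10000),
        cap=st.integers(0, 100000),
        mito=st.floats(0, 100),
        relax=st.sampled_from(["min_features", "max_features", "max_counts", "max_pct_mito"]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_relaxing_a_threshold_is_monotone(self, nf, nc, pm, lo, hi, cap, mito, relax):
        met = metrics_frame([(nf, nc, pm)])
        base = dict(min_features=lo, max_features=hi, max_counts=cap, max_pct_mito=mito)
        relaxed = dict(base)
        relaxed[relax] = 0 if relax == "min_features" else relaxed[relax] + 1000
        kept_before = apply_thresholds(met, QCThresholds(**base))[0]
        kept_after = apply_thresholds(met, QCThresholds(**relaxed))[0]
        assert kept_after or not kept_before


class TestDeferredMitoFilter:
    def test_exempt_label_keeps_high_mito_cell(self):
        met = metrics_frame([(3000, 10000, 40.0)])
        t = QCThresholds(max_pct_mito=5.0, mito_exempt_labels=("cardiomyocyte",))
        assert deferred_mito_filter(met, ["cardiomyocyte"], t).all()

    def test_non_exempt_cell_over_cap_discarded(self):
        met = metrics_frame([(3000, 10000, 7.0)])
        t = QCThresholds(max_pct_mito=5.0, mito_exempt_labels=("cardiomyocyte",))
        assert not deferred_mito_filter(met, ["fibroblast"], t).any()

    def test_empty_exempt_list_reduces_to_plain_thresholding(self):
        met = metrics_frame([(1, 1, 4.0), (1, 1, 6.0)])
        t = QCThresholds(max_pct_mito=5.0)
        assert deferred_mito_filter(met, ["x", "y"], t).tolist() == [True, False]

    def test_missing_label_is_an_error(self):
        met = metrics_frame([(1, 1, 4.0)])
        with pytest.raises(ValueError, match="label"):
            deferred_mito_filter(met, [None], QCThresholds(max_pct_mito=5.0))

    def test_two_pass_equals_single_pass_for_non_exempt_cells(self):
        rng = np.random.default_rng(0)
        met = metrics_frame(
            [(int(nf), int(nc), float(pm)) for nf, nc, pm in
             zip(rng.integers(0, 5000, 50), rng.integers(0, 50000, 50), rng.uniform(0, 20, 50))]
        )
        single = QCThresholds(min_features=100, max_counts=40000, max_pct_mito=5.0)
        deferred = QCThresholds(min_features=100, max_counts=40000, max_pct_mito=5.0, defer_mito=True)
        labels = ["other"] * len(met)
        one_pass = apply_thresholds(met, single)
        two_pass = apply_thresholds(met, deferred) & deferred_mito_filter(met, labels, deferred)
        assert (one_pass == two_pass).all()


class TestDownsample:
    def test_oversized_target_is_identity(self, tiny_matrix):
        assert downsample(tiny_matrix, 10, seed=0) is tiny_matrix

    def test_zero_target_keeps_gene_list(self, tiny_matrix):
        out = downsample(tiny_matrix, 0, seed=0)
        assert out.genes == tiny_matrix.genes and out.n_cells == 0

    def test_same_seed_same_subset(self):
        m = matrix_from_columns([[i] for i in range(50)], genes=["g"])
        a = downsample(m, 10, seed=3)
        b = downsample(m, 10, seed=3)
        assert a.barcodes == b.barcodes

    def test_columns_are_untouched(self):
        rng = np.random.default_rng(1)
        cols = rng.poisson(2, size=(30, 5)).tolist()
        m = matrix_from_columns(cols, genes=[f"g{i}" for i in range(5)])
        out = downsample(m, 12, seed=5)
        orig = {b: m.counts[:, i].toarray().ravel().tolist() for i, b in enumerate(m.barcodes)}
        for i, b in enumerate(out.barcodes):
            assert out.counts[:, i].toarray().ravel().tolist() == orig[b]
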