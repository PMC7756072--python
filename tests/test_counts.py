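"""Count hygiene: de-duplication, filtering, TMM, log-CPM, PCA."""

import numpy as np
import pandas as pd
import pytest

from crossregen import (
    CountMatrix,
    cpm,
    dedupe_ids,
    filter_low_expression,
    log_cpm,
    pca_coords,
    tmm_factors,
)
from conftest import make_counts


def tmm_oracle(counts, libs, j, ref, logratio_trim=0.3, sum_trim=0.05):
    """Direct per-definition trimmed weighted mean of M-values."""
    records = []
    for g in range(counts.shape[0]):
        yj, yr = counts[g, j], counts[g, ref]
        if yj == 0 or yr == 0:
            continue
        pj, pr = yj / libs[j], yr / libs[ref]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        w = (libs[j] - yj) / (libs[j] * yj) + (libs[ref] - yr) / (libs[ref] * yr)
        records.append((m, a, w))
    ms = np.array([r[0] for r in records])
    as_ = np.array([r[1] for r in records])
    ws = np.array([r[2] for r in records])
    lo_m, hi_m = np.quantile(ms, [logratio_trim, 1 - logratio_trim])
    lo_a, hi_a = np.quantile(as_, [sum_trim, 1 - sum_trim])
    keep = (ms >= lo_m) & (ms <= hi_m) & (as_ >= lo_a) & (as_ <= hi_a)
    return 2 ** (np.sum(ws[keep] * ms[keep]) / np.sum(ws[keep]))


class TestDedupe:
    def test_largest_iqr_wins(self):
        cm = make_counts([[0, 5, 10, 5], [0, 6, 24, 6], [3, 3, 3, 3]],
                         genes=["e1", "e2", "e3"])
        id_map = pd.DataFrame(
            {"source_id": ["e1", "e2", "e3"], "target_id": ["E", "E", "F"]}
        )
        out = dedupe_ids(cm, id_map)
        # e2 has the larger IQR, survives under target ID E
        assert list(out.counts.loc["E"]) == [0, 6, 24, 6]
        assert list(out.counts.loc["F"]) == [3, 3, 3, 3]

    def test_bijective_map_relabels_only(self):
        cm = make_counts([[1, 2], [3, 4]], genes=["a", "b"])
        id_map = pd.DataFrame({"source_id": ["a", "b"], "target_id": ["A", "B"]})
        out = dedupe_ids(cm, id_map)
        assert sorted(out.counts.index) == ["A", "B"]
        assert list(out.counts.loc["A"]) == [1, 2]

    def test_iqr_tie_breaks_by_total(self):
        # both rows constant (IQR 0); totals 100 vs 80
        cm = make_counts([[25, 25, 25, 25], [20, 20, 20, 20]], genes=["a", "b"])
        id_map = pd.DataFrame({"source_id": ["a", "b"], "target_id": ["X", "X"]})
        out = dedupe_ids(cm, id_map)
        assert list(out.counts.loc["X"]) == [25, 25, 25, 25]

    def test_full_tie_breaks_lexicographically(self):
        cm = make_counts([[5, 5], [5, 5]], genes=["zzz", "aaa"])
        id_map = pd.DataFrame({"source_id": ["zzz", "aaa"], "target_id": ["X", "X"]})
        out = dedupe_ids(cm, id_map)
        # equal IQR and totals: the lexicographically smaller source wins
        assert out.counts.shape == (1, 2)

    def test_empty_map_rejected(self):
        cm = make_counts([[1, 2]])
        with pytest.raises(ValueError):
            dedupe_ids(cm, pd.DataFrame(columns=["source_id", "target_id"]))


class TestFilter:
    def test_all_zero_gene_removed(self):
        cm = make_counts([[0, 0, 0], [10, 10, 10]])
        out = filter_low_expression(cm, min_cpm=1, min_samples=3)
        assert list(out.counts.index) == ["g1"]

    def test_boundary_kept(self):
        # gene passes CPM >= 1 in exactly min_samples samples
        counts = np.full((2, 10), 1000)
        counts[0] = [2, 2, 2, 0, 0, 0, 0, 0, 0, 0]  # CPM ~ 1996 in 3 samples
        cm = make_counts(counts)
        out = filter_low_expression(cm, min_cpm=1, min_samples=3)
        assert "g0" in out.counts.index

    def test_hand_computed_toy(self):
        # 6 genes x 4 samples; library sizes are column sums
        counts = np.array(
            [[100, 100, 100, 100],
             [0, 0, 0, 0],
             [1, 1, 1, 1],
             [50, 0, 0, 0],
             [10, 10, 0, 0],
             [500, 500, 500, 500]]
        )
        cm = make_counts(counts)
        libs = counts.sum(axis=0)
        c = counts / libs * 1e6
        expect = ((c >= 1000).sum(axis=1) >= 2)  # min_cpm=1000, min_samples=2
        out = filter_low_expression(cm, min_cpm=1000, min_samples=2)
        assert set(out.counts.index) == {f"g{i}" for i in np.where(expect)[0]}

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        cm = make_counts(rng.poisson(5, (50, 6)))
        once = filter_low_expression(cm)
        twice = filter_low_expression(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_min_samples_too_large(self):
        with pytest.raises(ValueError):
            filter_low_expression(make_counts([[1, 1]]), min_samples=3)


class TestTMM:
    def test_identical_samples_factor_one(self):
        cm = make_counts(np.tile([[10], [20], [30], [40]], (1, 4)))
        fac = tmm_factors(cm)
        assert np.allclose(fac.factors, 1.0)

    def test_scaled_sample_factor_one(self):
        base = np.array([10, 20, 30, 40, 55])
        cm = make_counts(np.column_stack([base, 3 * base]))
        fac = tmm_factors(cm)
        assert np.allclose(fac.factors, 1.0, atol=1e-12)

    def test_composition_bias_recovered_vs_oracle(self):
        rng = np.random.default_rng(3)
        n = 2000
        base = rng.poisson(np.exp(rng.normal(5, 1, n))) + 1
        biased = base.copy()
        up = rng.choice(n, n // 10, replace=False)
        biased[up] *= 8  # 10% of genes 8-fold up in sample B only
        counts = np.column_stack([base, biased, base])
        cm = make_counts(counts)
        fac = tmm_factors(cm)
        libs = counts.sum(axis=0).astype(float)
        raw = np.array(
            [1.0, tmm_oracle(counts.astype(float), libs, 1, 0), 1.0]
        )
        expected = raw / np.exp(np.mean(np.log(raw)))
        ratio = fac.factors.to_numpy() / expected
        assert np.all(np.abs(ratio - 1) < 0.05)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(50, (300, 5))
        cm = make_counts(counts)
        fac = tmm_factors(cm)
        perm = [3, 0, 4, 1, 2]
        cmp_ = make_counts(counts[:, perm], samples=[f"s{j}" for j in perm])
        facp = tmm_factors(cmp_)
        for j, pj in enumerate(perm):
            assert facp.factors[f"s{pj}"] == pytest.approx(fac.factors[f"s{pj}"], rel=1e-9)

    def test_matches_edger(self, tmp_path):
        """Independent oracle: edgeR's calcNormFactors on the same matrix."""
        import shutil
        import subprocess

        rng = np.random.default_rng(7)
        n = 400
        base = np.exp(rng.normal(5, 1.2, n))
        shift = np.ones((n, 4))
        shift[rng.choice(n, 40, replace=False), 1] = 4.0
        counts = rng.poisson(base[:, None] * np.array([1, 1.5, 0.7, 1.2]) * shift)
        cm = make_counts(counts, samples=list("ABCD"))
        path = tmp_path / "m.tsv"
        cm.counts.to_csv(path, sep="\t")
        out = subprocess.run(
            [shutil.which("Rscript") or "Rscript", "-e",
             f'suppressMessages(library(edgeR)); x <- read.delim("{path}", row.names=1); '
             'cat(calcNormFactors(as.matrix(x), method="TMM"))'],
            capture_output=True, text=True, check=True,
        )
        ref = np.array([float(v) for v in out.stdout.split()])
        ours = tmm_factors(cm).factors.to_numpy()
        assert np.all(np.abs(ours / ref - 1) < 0.05)


class TestLogCpm:
    def test_zero_count_finite_negative(self):
        cm = make_counts([[0, 0], [999998, 999998]])
        fac = tmm_factors(cm)
        out = log_cpm(cm, fac, prior_count=0.5)
        assert np.isfinite(out.to_numpy()).all()
        assert (out.loc["g0"] < 0).all()

    def test_depth_doubling_invariance(self):
        counts = np.array([[10, 20], [30, 5], [100, 200]])
        cm1 = make_counts(counts)
        cm2 = make_counts(2 * counts)
        out1 = log_cpm(cm1, tmm_factors(cm1))
        out2 = log_cpm(cm2, tmm_factors(cm2))
        assert np.allclose(out1.to_numpy(), out2.to_numpy(), atol=1e-9)

    def test_hand_computed_3x3(self):
        counts = np.array([[10, 0, 5], [90, 50, 45], [0, 50, 50]])
        cm = make_counts(counts)
        fac = tmm_factors(cm)
        out = log_cpm(cm, fac, prior_count=0.5)
        eff = (fac.factors * fac.lib_sizes).to_numpy()
        prior = 0.5 * eff / 1e6
        for i in range(3):
            for j in range(3):
                expect = np.log2((counts[i, j] + prior[j]) / (eff[j] + 2 * prior[j]) * 1e6)
                assert out.iloc[i, j] == pytest.approx(expect, abs=1e-9)


class TestPCA:
    def test_identical_samples_zero_coords(self):
        expr = pd.DataFrame(np.tile([[1.0], [2.0], [3.0]], (1, 4)))
        coords, shares = pca_coords(expr, 2)
        assert np.allclose(coords.to_numpy(), 0.0, atol=1e-9)

    def test_planted_shift_separates_on_pc1(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, (50, 5))
        b = rng.normal(0, 0.1, (50, 5)) + 3.0
        expr = pd.DataFrame(np.concatenate([a, b], axis=1))
        coords, shares = pca_coords(expr, 2)
        pc1 = coords["PC1"].to_numpy()
        assert np.sign(pc1[:5]).sum() in (-5, 5)
        assert np.sign(pc1[:5]).sum() == -np.sign(pc1[5:]).sum()
        assert shares.sum() <= 1.0 + 1e-12

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca_coords(pd.DataFrame(np.eye(3)), 5)
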