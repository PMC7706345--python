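import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from trenchroot import (PhenotypeTable, broad_sense_heritability, cluster_accessions,
                        oneway_anova, pearson, steel_dwass)


def _table(accessions, reps, values, width=None):
    n = len(values)
    return PhenotypeTable(pd.DataFrame({
        "accession": accessions,
        "depth50_cm": values,
        "width50_cm": width if width is not None else np.zeros(n),
    }))


class TestPearson:
    def test_perfect_positive_linearity(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([1.0, 2, 3])
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # product-moment formula by hand: cov = 0.5, sd_x = sd_y = 1
        assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_sign_of_affine_map(self, rng):
        x = rng.random(10)
        assert pearson(x, -3 * x + 7) == pytest.approx(-1.0)
        assert pearson(x, 0.1 * x) == pytest.approx(1.0)

    def test_contract_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            pearson([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="3 points"):
            pearson([1, 2], [3, 4])
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [1, 2, 3])


class TestHeritability:
    def test_no_within_accession_variance_gives_one(self):
        t = _table(["a"] * 3 + ["b"] * 3 + ["c"] * 3,
                   3, [5, 5, 5, 8, 8, 8, 11, 11, 11])
        assert broad_sense_heritability(t, "depth50_cm").H2 == pytest.approx(1.0)

    def test_pure_noise_limit_is_near_zero(self, rng):
        acc = np.repeat([f"a{i}" for i in range(40)], 10)
        vals = 10 + rng.normal(0, 1, 400)
        res = broad_sense_heritability(_table(acc, 10, vals), "depth50_cm")
        assert res.H2 < 0.15

    def test_recovers_analytic_three_quarters(self, rng):
        # V_G = 3, V_E = 1 over 60 accessions x 3 reps -> H2 = 0.75
        ests = []
        for _ in range(25):
            g = rng.normal(0, np.sqrt(3.0), 60)
            y = g[:, None] + rng.normal(0, 1.0, (60, 3)) + 20.0
            acc = np.repeat([f"a{i}" for i in range(60)], 3)
            ests.append(broad_sense_heritability(_table(acc, 3, y.ravel()), "depth50_cm").H2)
        assert np.mean(ests) == pytest.approx(0.75, abs=0.1)

    def test_affine_rescaling_invariance(self, rng):
        acc = np.repeat([f"a{i}" for i in range(10)], 3)
        vals = rng.random(30) * 10 + 5
        h_cm = broad_sense_heritability(_table(acc, 3, vals), "depth50_cm").H2
        h_mm = broad_sense_heritability(_table(acc, 3, vals * 10), "depth50_cm").H2
        assert h_cm == pytest.approx(h_mm)

    def test_single_accession_rejected(self):
        with pytest.raises(ValueError, match="accessions"):
            broad_sense_heritability(_table(["a"] * 3, 3, [1.0, 2.0, 3.0]), "depth50_cm")


class TestAnova:
    def test_identical_groups(self):
        f, p = oneway_anova([[1.0, 2, 3], [1.0, 2, 3]])
        assert f == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_extreme_separation(self):
        _, p = oneway_anova([[1.0, 2, 3], [101.0, 102, 103]])
        assert p < 1e-3

    def test_shift_invariance(self, rng):
        groups = [rng.random(5) for _ in range(3)]
        f1, _ = oneway_anova(groups)
        f2, _ = oneway_anova([g + 100 for g in groups])
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            oneway_anova([[1.0, 2.0], [3.0]])


class TestSteelDwass:
    def test_two_groups_reduce_to_ranksum(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        res = steel_dwass({"a": a, "b": b})
        ref = sps.ranksums(a, b).pvalue  # two-sided normal approximation
        assert res.loc[0, "p"] == pytest.approx(ref, abs=0.01)

    def test_identical_groups_give_p_near_one(self):
        g = np.arange(10.0)
        res = steel_dwass({"a": g, "b": g, "c": g})
        assert (res["p"] > 0.95).all()

    def test_all_pairs_reported(self, rng):
        groups = {lab: rng.random(5) for lab in "abcd"}
        res = steel_dwass(groups)
        assert len(res) == 6  # C(4,2)

    def test_familywise_error_under_null(self):
        # seeded null with k=4 groups of 15: reject any pair at alpha=0.05
        rng = np.random.default_rng(2024)
        fwe = 0
        n_reps = 300
        for _ in range(n_reps):
            groups = {lab: rng.normal(0, 1, 15) for lab in "abcd"}
            res = steel_dwass(groups)
            fwe += (res["p"] < 0.05).any()
        assert fwe / n_reps <= 0.07


class TestClustering:
    def _panel(self, rng, centers, n_each=10, sd=0.05):
        rows = []
        for ci, (d, w) in enumerate(centers):
            for j in range(n_each):
                rows.append({"accession": f"c{ci}_a{j}",
                             "depth50_cm": d + rng.normal(0, sd),
                             "width50_cm": w + rng.normal(0, sd)})
        return PhenotypeTable(pd.DataFrame(rows))

    def test_two_separated_clouds(self, rng):
        t = self._panel(rng, [(5.0, 5.0), (20.0, 12.0)])
        labels, _ = cluster_accessions(t, k=2)
        first = {a for a in labels.index if a.startswith("c0")}
        assert len({labels[a] for a in first}) == 1
        assert len(set(labels)) == 2

    def test_k_equals_n_gives_singletons(self, rng):
        t = self._panel(rng, [(5.0, 5.0)], n_each=6, sd=1.0)
        labels, _ = cluster_accessions(t, k=6)
        assert len(set(labels)) == 6

    def test_three_gaussian_clusters_perfectly_recovered(self, rng):
        t = self._panel(rng, [(5.0, 3.0), (15.0, 8.0), (22.0, 14.0)])
        labels, _ = cluster_accessions(t, k=3)
        truth = [a.split("_")[0] for a in labels.index]
        # adjusted agreement = 1 <=> partition identical up to relabeling
        mapping = {}
        for t_lab, c_lab in zip(truth, labels):
            mapping.setdefault(t_lab, c_lab)
            assert mapping[t_lab] == c_lab

    def test_order_invariance(self, rng):
        t = self._panel(rng, [(5.0, 5.0), (20.0, 12.0)], n_each=5)
        shuffled = PhenotypeTable(t.data.sample(frac=1, random_state=1).reset_index(drop=True))
        a, _ = cluster_accessions(t, k=2)
        b, _ = cluster_accessions(shuffled, k=2)
        agree = all(
            (a[i] == a[j]) == (b[i] == b[j])
            for i in a.index for j in a.index
        )
        assert agree

    def test_k_too_large_rejected(self, rng):
        t = self._panel(rng, [(5.0, 5.0)], n_each=3, sd=1.0)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_accessions(t, k=10)
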