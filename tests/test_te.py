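"""TE coverage fractions and Pearson correlation tests."""

import numpy as np
import pytest
from scipy import stats

from intronarch import pearson_correlation, te_profile
from intronarch.datasets import _gene_with_intron_sites
from intronarch.models import TEAnnotation
from intronarch.simulate import SimConfig, simulate_family
from intronarch.te import correlation_report, te_profile_table
from intronarch.metrics import length_summary


def _model_with_gene_length(n_introns=12):
    return _gene_with_intron_sites("tx", "g1", [("GT", "AG")] * n_introns)


def _anno(start, end, te_class="retrotransposon", superfamily="Gypsy"):
    return TEAnnotation("g1", start, end, te_class, superfamily)


class TestTEProfile:
    def test_single_element_fractions(self):
        m = _model_with_gene_length()
        L = len(m.gene_seq)
        prof = te_profile(m, [_anno(5, 5 + L // 5)])
        assert prof.te_fraction == pytest.approx(100 * (L // 5) / L)
        assert prof.class_fractions["retrotransposon"] == pytest.approx(100.0)
        assert prof.ltr_split["Gypsy"] == pytest.approx(100.0)

    def test_overlap_idempotence(self):
        m = _model_with_gene_length()
        one = te_profile(m, [_anno(10, 60)])
        two = te_profile(m, [_anno(10, 60), _anno(10, 60)])
        assert one.te_fraction == two.te_fraction

    def test_split_invariance(self):
        m = _model_with_gene_length()
        whole = te_profile(m, [_anno(10, 90)])
        split = te_profile(m, [_anno(10, 47), _anno(47, 90)])
        assert whole.te_fraction == pytest.approx(split.te_fraction)
        assert whole.class_fractions == pytest.approx(split.class_fractions)

    def test_zero_annotations(self):
        prof = te_profile(_model_with_gene_length(), [])
        assert prof.te_fraction == 0.0
        assert all(v == 0.0 for v in prof.class_fractions.values())

    def test_monotone_in_added_te(self):
        m = _model_with_gene_length()
        fractions = [
            te_profile(m, [_anno(5, 5 + w)]).te_fraction for w in (10, 40, 80, 120)
        ]
        assert fractions == sorted(fractions)

    def test_interclass_overlap_priority(self):
        m = _model_with_gene_length()
        prof = te_profile(
            m,
            [_anno(10, 60, "retrotransposon", "Copia"), _anno(40, 90, "helitron", "Helitron")],
        )
        # union is 80 bp; retrotransposon claims its 50, helitron the free 30
        assert prof.class_fractions["retrotransposon"] == pytest.approx(100 * 50 / 80)
        assert prof.class_fractions["helitron"] == pytest.approx(100 * 30 / 80)

    def test_clipping_outside_gene_span(self, caplog):
        m = _model_with_gene_length()
        L = len(m.gene_seq)
        with caplog.at_level("WARNING", logger="intronarch"):
            prof = te_profile(m, [_anno(L - 10, L + 100)])
        assert prof.te_fraction == pytest.approx(100 * 10 / L)
        assert "clipped" in caplog.text

    def test_intron_denominator(self):
        m = _model_with_gene_length()
        s, e = m.introns[0]
        prof = te_profile(m, [_anno(s, e)], denominator="intron")
        intron_len = sum(e2 - s2 for s2, e2 in m.introns)
        assert prof.te_fraction == pytest.approx(100 * (e - s) / intron_len)


class TestPearson:
    def test_perfect_positive(self):
        r, p = pearson_correlation([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_perfect_negative(self):
        r, _ = pearson_correlation([1, 2, 3], [-1, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_hand_example_n5(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        r, p = pearson_correlation(x, y)
        assert r == pytest.approx(0.8)
        # p from the closed form t = r sqrt((n-2)/(1-r^2)), 3 df
        t = 0.8 * np.sqrt(3 / (1 - 0.64))
        assert p == pytest.approx(2 * stats.t.sf(t, 3))

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r, p = pearson_correlation(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestCorrelationReport:
    def _run(self, te_rate_max=3.0, seed=1, n=12):
        cfg = SimConfig(
            seed=seed, n_leaves=n, gain_rate=0, loss_rate=0, subst_rate=0,
            te_rate_max=te_rate_max,
        )
        models, truth = simulate_family(cfg)
        profiles = []
        for m in models:
            annos = [
                TEAnnotation(m.gene_id, r["start"], r["end"], r["te_class"], r["superfamily"])
                for r in truth.te_registry[m.taxon]
            ]
            profiles.append(te_profile(m, annos))
        return models, profiles

    def test_te_driven_growth_gives_strong_correlation(self):
        models, profiles = self._run()
        report = correlation_report(profiles, length_summary(models))
        row = report[report["pair"] == "gene_length~te_fraction"].iloc[0]
        assert row["r"] > 0.8
        assert row["p"] < 0.01

    def test_shuffled_pairing_kills_correlation(self):
        models, profiles = self._run()
        rng = np.random.default_rng(42)
        shuffled = list(profiles)
        rng.shuffle(shuffled)
        relabeled = []
        for m, p in zip(models, shuffled):
            p2 = type(p)(m.taxon, m.gene_id, p.te_fraction, p.class_fractions, p.ltr_split)
            relabeled.append(p2)
        report = correlation_report(relabeled, length_summary(models))
        row = report[report["pair"] == "gene_length~te_fraction"].iloc[0]
        assert abs(row["r"]) < 0.5

    def test_too_few_pairs_skipped(self, caplog):
        models, profiles = self._run(n=4)
        with caplog.at_level("WARNING", logger="intronarch"):
            report = correlation_report(profiles[:2], length_summary(models[:2]))
        assert report.empty
        assert "skipped" in caplog.text

    def test_profile_table_columns(self):
        _, profiles = self._run(n=4)
        df = te_profile_table(profiles)
        assert {"taxon", "te_fraction", "pct_retrotransposon"} <= set(df.columns)
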