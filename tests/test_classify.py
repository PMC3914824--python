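"""Four-step probability-classification: correlation, standard set,
attribution, actualization, final labelling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spstates import (ClassifierConfig, SpectralPatternClassifier,
                      attribute_to_classes, actualize, build_pool,
                      final_classify, generate_standard_set, shifted_cc)
from spstates.classify import DegenerateInputError, Pool, _cc_matrix

from conftest import single_peak_spectrum


def pearson_oracle(x, y):
    """Independent Pearson by the textbook formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    den = np.sqrt((dx**2).sum() * (dy**2).sum())
    return (dx * dy).sum() / den if den > 0 else 0.0


def shifted_cc_oracle(a, b):
    """Max of Pearson at shifts -1, 0, +1 with 58-bin overlap."""
    return max(pearson_oracle(a, b),
               pearson_oracle(a[1:], b[:-1]),
               pearson_oracle(a[:-1], b[1:]))


class TestShiftedCC:
    def test_identical_spectra(self):
        a = single_peak_spectrum(20)
        assert shifted_cc(a, a) == pytest.approx(1.0)

    def test_one_bin_translation_recovered(self):
        a = single_peak_spectrum(20)
        b = np.roll(a, 1)
        assert shifted_cc(a, b) == pytest.approx(1.0)

    def test_distant_peaks_below_acceptance(self):
        a = single_peak_spectrum(15)
        b = single_peak_spectrum(25)
        val = shifted_cc(a, b)
        assert val == pytest.approx(shifted_cc_oracle(a, b), abs=1e-12)
        assert val < 0.71

    def test_matches_oracle_on_random_spectra(self, rng):
        for _ in range(50):
            a = rng.random(59) * 10
            b = rng.random(59) * 10
            assert shifted_cc(a, b) == pytest.approx(shifted_cc_oracle(a, b),
                                                     abs=1e-12)

    def test_zero_variance_defined_as_zero(self):
        assert shifted_cc(np.full(59, 4.0), single_peak_spectrum(10)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            shifted_cc(np.zeros(59), np.zeros(58))


class TestBuildPool:
    def test_pool_size_is_product(self, rng):
        entries = [dict(subject="S1", condition="CE", channel=f"ch{c}",
                        epoch=0, spectra=rng.random((149, 59)))
                   for c in range(8)]
        pool = build_pool(entries)
        assert len(pool) == 149 * 8

    def test_duplicates_kept(self, rng):
        X = rng.random((10, 59))
        pool = build_pool([
            dict(subject="S1", condition="CE", channel="O1", epoch=0, spectra=X),
            dict(subject="S1", condition="CE", channel="O1", epoch=1, spectra=X),
        ])
        assert len(pool) == 20

    def test_provenance_query(self, rng):
        pool = build_pool([dict(subject="S2", condition="OE", channel="F3",
                                epoch=3, spectra=rng.random((5, 59)))])
        row = pool.meta.iloc[4]
        assert (row.subject, row.condition, row.channel, row.epoch,
                row.window) == ("S2", "OE", "F3", 3, 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_pool([])


def three_class_pool(counts=(10, 7, 5), bins=(5, 25, 45), rng=None):
    """Pool of noisy copies of three mutually low-correlation spectra."""
    rng = rng or np.random.default_rng(0)
    rows, truth = [], []
    for c, b in zip(counts, bins):
        base = single_peak_spectrum(b)
        for _ in range(c):
            rows.append(base + rng.random(59) * 1e-6)
            truth.append(b)
    return np.array(rows), np.array(truth)


class TestStandardSet:
    def test_three_well_separated_classes(self):
        X, _ = three_class_pool()
        # oracle: the three candidates are pairwise below the admission cut
        for i, j in [(5, 25), (5, 45), (25, 45)]:
            assert shifted_cc_oracle(single_peak_spectrum(i),
                                     single_peak_spectrum(j)) < 0.71
        std = generate_standard_set(X)
        assert std.class_ids == [1, 2, 3]
        # ids ordered by count: bin 5 (10 copies), bin 25 (7), bin 45 (5)
        assert [t.peaks.tolist() for t in std.templates] == [[5], [25], [45]]
        assert [t.count for t in std.templates] == [10, 7, 5]

    def test_correlated_candidate_not_admitted(self):
        """Two signatures whose templates correlate above the admission
        threshold: only the higher-count one enters the standard set."""
        a = single_peak_spectrum(20)
        b = np.roll(a, 1)  # shift-corrected cc = 1.0 > 0.71
        X = np.vstack([a] * 6 + [b] * 4)
        std = generate_standard_set(X)
        assert len(std.templates) == 1
        assert std.templates[0].peaks.tolist() == [20]

    def test_min_count_excludes_singletons(self):
        X, _ = three_class_pool(counts=(5, 5, 1))
        std = generate_standard_set(X)
        assert len(std.templates) == 2

    def test_degenerate_pool_raises(self):
        flat = np.ones((20, 59))  # no SP passes the 60% peak rule
        with pytest.raises(DegenerateInputError):
            generate_standard_set(flat)


class TestAttribution:
    @pytest.fixture
    def standards(self):
        X, _ = three_class_pool()
        return generate_standard_set(X)

    def test_template_belongs_to_its_class(self, standards):
        m = attribute_to_classes(standards.templates[1].template, standards)
        assert m[0, 1]

    def test_membership_matches_thresholded_correlation(self, standards, rng):
        X = rng.random((30, 59)) * 5
        m = attribute_to_classes(X, standards)
        for i in range(30):
            for j, tpl in enumerate(standards.templates):
                assert m[i, j] == (
                    shifted_cc_oracle(X[i], tpl.template) >= 0.71)

    def test_multi_membership_possible(self):
        """An SP blending two mildly correlated templates joins both
        classes at this stage (membership is many-to-many)."""
        bins = np.arange(59)
        g1 = np.exp(-((bins - 20.0) ** 2) / (2 * 3.0**2))
        g2 = np.exp(-((bins - 27.0) ** 2) / (2 * 3.0**2))
        X = np.vstack([g1] * 5 + [g2] * 4)
        std = generate_standard_set(X)
        assert len(std.templates) == 2
        blend = g1 + g2
        cc = [shifted_cc(blend, t.template) for t in std.templates]
        m = attribute_to_classes(blend, std)[0]
        assert m.tolist() == [c >= 0.71 for c in cc]
        assert m.sum() == 2

    def test_orphan_sp_belongs_nowhere(self, standards):
        m = attribute_to_classes(single_peak_spectrum(55), standards)
        assert not m.any()


class TestActualize:
    @pytest.fixture
    def standards(self):
        X, _ = three_class_pool()
        return generate_standard_set(X)

    def test_single_member_becomes_template(self, standards):
        sp = standards.templates[0].template + 0.01
        m = attribute_to_classes(sp, standards)
        act = actualize(sp[None, :], m, standards, "O1")
        assert np.allclose(act.templates[0].template, sp)

    def test_members_identical_to_standard(self, standards):
        X = np.vstack([standards.templates[1].template] * 4)
        m = attribute_to_classes(X, standards)
        act = actualize(X, m, standards, "O1")
        assert np.allclose(act.templates[1].template,
                           standards.templates[1].template)

    def test_symmetric_noise_leaves_peak_bin(self, standards, rng):
        base = standards.templates[0].template
        X = np.abs(base + rng.normal(0, 0.02, size=(50, 59)))
        m = attribute_to_classes(X, standards)
        act = actualize(X, m, standards, "O1")
        assert act.templates[0].template.argmax() == base.argmax()

    def test_empty_class_keeps_standard_flagged(self, standards):
        sp = standards.templates[0].template
        m = attribute_to_classes(sp, standards)
        act = actualize(sp[None, :], m, standards, "O1")
        assert act.templates[2].fallback
        assert np.allclose(act.templates[2].template,
                           standards.templates[2].template)


class TestFinalClassify:
    @pytest.fixture
    def actuals(self):
        X, _ = three_class_pool()
        std = generate_standard_set(X)
        m = attribute_to_classes(X, std)
        return actualize(X, m, std, "O1")

    def test_template_gets_its_own_label(self, actuals):
        seq = final_classify(actuals.templates[2].template, actuals)
        assert seq.labels[0] == 3
        assert seq.confidence[0] == pytest.approx(1.0)
        assert not seq.low_confidence[0]

    def test_maximum_correlation_wins(self, actuals):
        """Among classes passing 0.71, the maximum-correlation class is
        chosen even when several are acceptable."""
        blend = 0.25 * actuals.templates[0].template \
            + 0.75 * actuals.templates[1].template
        cc = [shifted_cc(blend, t.template) for t in actuals.templates]
        seq = final_classify(blend, actuals)
        accepted = [c for c in cc if c >= 0.71]
        assert len(accepted) >= 1
        assert seq.labels[0] == int(np.argmax(cc)) + 1

    def test_no_undecided_category(self, actuals):
        """Below-threshold SPs still get the argmax label, flagged."""
        orphan = single_peak_spectrum(55)
        cc = [shifted_cc(orphan, t.template) for t in actuals.templates]
        assert max(cc) < 0.71
        seq = final_classify(orphan, actuals)
        assert seq.labels[0] == int(np.argmax(cc)) + 1
        assert seq.low_confidence[0]

    def test_every_window_labelled(self, actuals, rng):
        X = rng.random((200, 59))
        seq = final_classify(X, actuals)
        assert len(seq) == 200
        assert np.all(np.isin(seq.labels, [1, 2, 3]))


from functools import lru_cache


@lru_cache(maxsize=4)
def make_study(freq_offset=0.0, seed=42) -> Pool:
    """Pooled spectra of a small three-state study (cached)."""
    from spstates import (ClusterSpec, StateDef, StudyDesign, gen_study,
                          sliding_spectra)

    states = {
        s: StateDef(s, (f + freq_offset,), (20.0,), 1.0, 1.0)
        for s, f in [("A", 3.0), ("B", 10.0), ("C", 21.0)]
    }
    matrix = {s: ClusterSpec(("c1",), 1.0) for s in states}
    design = StudyDesign(states, matrix, ["c1"], n_subjects=2,
                         n_channels=2, seed=seed)
    dataset, _, _ = gen_study(design, epoch_len=10.0)
    entries = []
    for rec, _ in dataset:
        n_ep = rec.n_samples // 1280
        for e in range(n_ep):
            block = rec.samples[:, e * 1280:(e + 1) * 1280]
            for ci, ch in enumerate(rec.channel_labels):
                entries.append(dict(subject=rec.subject_id, condition="c1",
                                    channel=ch, epoch=e,
                                    spectra=sliding_spectra(block[ci])))
    return build_pool(entries)


class TestEstimatorProperties:
    def test_fit_predict_totality(self):
        pool = make_study()
        clf = SpectralPatternClassifier().fit(
            pool.spectra, channels=pool.meta["channel"].to_numpy())
        labels = clf.predict(pool.spectra,
                             channels=pool.meta["channel"].to_numpy())
        assert labels.shape == (len(pool),)
        assert np.all(np.isin(labels, clf.classes_))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        """Multiplying all SPs by a positive constant changes nothing."""
        pool = make_study()
        ch = pool.meta["channel"].to_numpy()
        a = SpectralPatternClassifier().fit(pool.spectra, channels=ch)
        b = SpectralPatternClassifier().fit(pool.spectra * scale, channels=ch)
        assert a.n_classes_ == b.n_classes_
        assert np.array_equal(a.predict(pool.spectra, channels=ch),
                              b.predict(pool.spectra * scale, channels=ch))

    def test_shift_robustness(self):
        """Translating every tone by +0.5 Hz leaves the label sequence
        unchanged (the +-0.5 Hz shift correction at work)."""
        pool_a = make_study(0.0)
        pool_b = make_study(0.5)
        ch = pool_a.meta["channel"].to_numpy()
        ca = SpectralPatternClassifier().fit(pool_a.spectra, channels=ch)
        cb = SpectralPatternClassifier().fit(pool_b.spectra, channels=ch)
        assert ca.n_classes_ == cb.n_classes_
        assert np.array_equal(ca.predict(pool_a.spectra, channels=ch),
                              cb.predict(pool_b.spectra, channels=ch))

    def test_threshold_shares_majority_of_variance(self):
        cfg = ClassifierConfig()
        assert cfg.cc_accept**2 > 0.5

    def test_sklearn_params_roundtrip(self):
        clf = SpectralPatternClassifier(cc_accept=0.8)
        assert clf.get_params()["cc_accept"] == 0.8
        clf.set_params(min_count=3)
        assert clf._config().min_count == 3
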