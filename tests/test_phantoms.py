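"""Phantom generator: determinism, implanted effect sizes, cohort contracts."""


import numpy as np
import pytest
from scipy import stats

from neurophantom.images import load_nifti
from neurophantom.phantoms import (PhantomConfig, make_template, render_three_tissue,
                                   roi_core, synth_minimal_t1w, synth_subject,
                                   make_bias_field, soft_roi)

from conftest import record


class TestTemplate:
    def test_deterministic_given_seed(self):
        t1, m1, r1 = make_template((32, 32, 32), seed=3)
        t2, m2, r2 = make_template((32, 32, 32), seed=3)
        assert np.array_equal(t1.data, t2.data)
        assert np.array_equal(m1.data, m2.data)
        assert np.array_equal(r1.data, r2.data)

    def test_range_and_mask_nonempty(self):
        t, m, _ = make_template((32, 32, 32), seed=11)
        assert t.data.min() >= 0.0 and t.data.max() <= 1.0
        assert m.data.any()

    def test_roi_contained_in_brain(self, template24):
        _, mask, roi = template24
        assert not (roi.data & ~mask.data).any()

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError):
            make_template((8, 8, 8), seed=0)


class TestSubject:
    def test_identity_when_no_effect_no_noise(self, template24):
        tpl, mask, roi = template24
        cfg = PhantomConfig(shape=(24, 24, 24), noise_sd=0.0)
        rec = record(group="CN", icv=1.0, site="nosite")
        img = synth_subject(tpl, roi, rec, cfg, brain_mask=mask)
        np.testing.assert_allclose(img.data, tpl.data, atol=1e-12)

    def test_roi_core_contrast_equals_effect(self, template24):
        # delta=0.3, no noise: ROI-core mean ratio = 0.7 within soft-edge tolerance
        tpl, mask, roi = template24
        cfg = PhantomConfig(shape=(24, 24, 24), noise_sd=0.0)
        rec = record(group="AD", icv=1.0, site="nosite")
        img = synth_subject(tpl, roi, rec, cfg, brain_mask=mask)
        core = roi_core(roi, cfg.roi_soft_sigma)
        ratio = img.data[core].mean() / tpl.data[core].mean()
        assert ratio == pytest.approx(0.70, abs=0.01)

    def test_effect_size_recovery_between_groups(self, template24):
        # noise-free contrast between groups is (1-da)/(1-db) in the ROI core
        tpl, mask, roi = template24
        cfg = PhantomConfig(shape=(24, 24, 24), noise_sd=0.0)
        core = roi_core(roi, cfg.roi_soft_sigma)
        means = {}
        for g in ("AD", "MCIc", "MCInc"):
            img = synth_subject(tpl, roi, record(group=g, site="nosite"), cfg,
                                brain_mask=mask)
            means[g] = img.data[core].mean()
        base = tpl.data[core].mean()
        for a, b in (("AD", "MCIc"), ("MCIc", "MCInc")):
            da = cfg.atrophy_effect[a]
            db = cfg.atrophy_effect[b]
            # soft (Gaussian) ROI edge: core contrast matches to ~1%
            assert means[a] / means[b] == pytest.approx((1 - da) / (1 - db), abs=0.01)
        assert means["AD"] / base == pytest.approx(0.70, abs=0.01)

    def test_noise_model_monte_carlo(self, template24):
        # mean ROI-core intensity over 200 AD subjects ~ 0.7 * template core mean
        tpl, mask, roi = template24
        cfg = PhantomConfig(shape=(24, 24, 24), noise_sd=0.05)
        core = roi_core(roi, cfg.roi_soft_sigma)
        vals = []
        for s in range(200):
            img = synth_subject(tpl, roi, record(group="AD", site="nosite", seed=s),
                                cfg, brain_mask=mask)
            vals.append(img.data[core].mean())
        vals = np.asarray(vals)
        target = 0.7 * tpl.data[core].mean()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - target) <= 2 * se + 0.01 * target

    def test_deterministic_given_record_seed(self, template24):
        tpl, mask, roi = template24
        cfg = PhantomConfig(shape=(24, 24, 24))
        rec = record(group="AD", seed=77)
        a = synth_subject(tpl, roi, rec, cfg, brain_mask=mask)
        b = synth_subject(tpl, roi, rec, cfg, brain_mask=mask)
        assert np.array_equal(a.data, b.data)

    def test_unknown_group_rejected(self, template24):
        tpl, _, roi = template24
        cfg = PhantomConfig(shape=(24, 24, 24))
        cfg.atrophy_effect.pop("MCInc")
        with pytest.raises(ValueError, match="atrophy"):
            synth_subject(tpl, roi, record(group="MCInc"), cfg)


class TestMinimalT1w:
    def _gm(self, template24):
        tpl, mask, roi = template24
        cfg = PhantomConfig(shape=(24, 24, 24), noise_sd=0.0)
        return synth_subject(tpl, roi, record(group="AD", site="nosite"), cfg,
                             brain_mask=mask)

    def test_identity_with_zero_amplitudes(self, template24):
        gm = self._gm(template24)
        cfg = PhantomConfig(shape=(24, 24, 24), max_rotation_deg=0.0,
                            max_scale_jitter=0.0, deformation_amplitude=0.0,
                            bias_field_amplitude=0.0)
        out = synth_minimal_t1w(gm, record(group="AD"), cfg)
        ref = render_three_tissue(gm)
        assert np.abs(out.data - ref.data).max() < 1e-6

    def test_deterministic_given_seed(self, template24):
        gm = self._gm(template24)
        cfg = PhantomConfig(shape=(24, 24, 24))
        rec = record(group="AD", seed=5)
        a = synth_minimal_t1w(gm, rec, cfg)
        b = synth_minimal_t1w(gm, rec, cfg)
        assert np.array_equal(a.data, b.data)

    def test_bias_field_is_smooth(self, rng):
        # finite-difference gradient of the generated field is bounded by its
        # amplitude over its correlation length
        amp, sigma = 0.2, 8.0
        field = make_bias_field((32, 32, 32), rng, amplitude=amp, sigma=sigma)
        grads = np.gradient(field)
        gmax = max(np.abs(g).max() for g in grads)
        assert gmax <= 3.0 * amp / sigma
        assert abs(field.mean() - 1.0) < amp

    def test_folding_deformation_rejected(self, template24):
        gm = self._gm(template24)
        cfg = PhantomConfig(shape=(24, 24, 24), deformation_amplitude=30.0,
                            deformation_sigma=2.0)
        with pytest.raises(ValueError, match="folding"):
            synth_minimal_t1w(gm, record(group="AD", seed=3), cfg)


class TestCohort:
    def test_counts_match_config(self, small_cohort, small_config):
        for g, n in small_config.n_internal.items():
            assert len(small_cohort.ids("internal", (g,))) == n
        for g, n in small_config.n_external.items():
            assert len(small_cohort.ids("external", (g,))) == n

    def test_round_trip_readable_and_shaped(self, small_cohort, small_config):
        for rep, paths in small_cohort.image_paths.items():
            for pid, p in paths.items():
                img = load_nifti(p)
                assert img.shape == small_config.shape

    def test_participants_tsv_schema(self, small_cohort):
        header = (small_cohort.out_dir / "participants.tsv").read_text().splitlines()[0]
        assert header.split("\t") == ["id", "group", "cohort", "icv", "site", "seed"]

    def test_cohort_is_pure_function_of_config(self, small_config, tmp_path):
        from neurophantom.phantoms import synth_cohort, cohort_hash

        c1 = synth_cohort(small_config, tmp_path / "a",
                          representations=("modulated_gm",))
        c2 = synth_cohort(small_config, tmp_path / "b",
                          representations=("modulated_gm",))
        assert cohort_hash(c1) == cohort_hash(c2)
        a = load_nifti(c1.image_paths["modulated_gm"][c1.records[0].id])
        b = load_nifti(c2.image_paths["modulated_gm"][c2.records[0].id])
        assert np.array_equal(a.data, b.data)

    def test_external_gain_shifts_whole_brain_mean(self, template24):
        # external site gain 1.1: mean whole-brain intensity ratio ~ 1.1
        tpl, mask, roi = template24
        cfg = PhantomConfig(shape=(24, 24, 24))
        rng = np.random.default_rng(99)
        means = {"site_int": [], "site_ext": []}
        for site in ("site_int", "site_ext"):
            for s in range(100):
                icv = float(rng.uniform(*cfg.icv_range))
                rec = record(group="CN" if site == "site_int" else "SCD", icv=icv,
                             site=site, seed=1000 + s + (0 if site == "site_int" else 5000))
                img = synth_subject(tpl, roi, rec, cfg, brain_mask=mask)
                means[site].append(img.data[mask.data].mean())
        a = np.asarray(means["site_int"])
        p = np.asarray(means["site_ext"])
        se = np.sqrt(1.1**2 * a.var(ddof=1) / a.size + p.var(ddof=1) / p.size)
        assert abs(p.mean() - 1.1 * a.mean()) <= 2 * se + 0.005

    def test_distribution_shift_detectable(self, template24):
        # power check: two-sample test separates internal vs external controls
        tpl, mask, roi = template24
        cfg = PhantomConfig(shape=(24, 24, 24))
        rng = np.random.default_rng(17)
        groups = []
        for site, grp in (("site_int", "CN"), ("site_ext", "SCD")):
            vals = []
            for s in range(100):
                icv = float(rng.uniform(*cfg.icv_range))
                rec = record(group=grp, icv=icv, site=site, seed=s * 13 + 7)
                img = synth_subject(tpl, roi, rec, cfg, brain_mask=mask)
                vals.append(img.data[mask.data].mean())
            groups.append(vals)
        t, p = stats.ttest_ind(groups[0], groups[1])
        assert p < 1e-6


def test_soft_roi_core_is_one(template24):
    _, _, roi = template24
    r = soft_roi(roi, sigma=1.0)
    core = roi_core(roi, sigma=1.0)
    assert r.max() == pytest.approx(1.0)
    assert r[core].min() > 0.9
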