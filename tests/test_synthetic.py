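"""Generator contracts: determinism, configured distributions, geometry phantoms."""

import numpy as np
import pytest
from scipy import stats

from opgpred.errors import ConfigurationError, GeometryError
from opgpred.cohort import label_progression
from opgpred.geometry import RegionMask, filter_streamlines
from opgpred.synthetic import (
    CohortConfig,
    generate_cohort,
    generate_streamlines,
    generate_tube_mask,
    make_feature_table,
    subject_or_fa_mean,
)


def test_invalid_config_names_offending_field():
    with pytest.raises(ConfigurationError, match="n_cases"):
        CohortConfig(n_cases=0)
    with pytest.raises(ConfigurationError, match="fa_sd_case"):
        CohortConfig(fa_sd_case=-1.0)
    with pytest.raises(ConfigurationError, match="grid_shape"):
        CohortConfig(grid_shape=(8, 32, 32))
    with pytest.raises(ConfigurationError, match="scans_per_subject"):
        CohortConfig(scans_per_subject=5)


def test_cohort_count_and_label_conservation():
    subs = generate_cohort(CohortConfig(n_cases=2, n_controls=2, seed=7, grid_shape=(16, 16, 16)))
    assert len(subs) == 4
    assert sum(s.group == "case" for s in subs) == 2


def test_cohort_is_bit_identical_for_fixed_seed():
    cfg = dict(n_cases=1, n_controls=1, seed=42, grid_shape=(16, 16, 16), scans_per_subject=2)
    a = generate_cohort(CohortConfig(**cfg))
    b = generate_cohort(CohortConfig(**cfg))
    for sa, sb in zip(a, b):
        for ka, kb in zip(sa.scans, sb.scans):
            for mod in ka.volumes:
                assert np.array_equal(ka.volumes[mod], kb.volumes[mod])
        for la, lb in zip(sa.streamlines[0].lines, sb.streamlines[0].lines):
            assert np.array_equal(la, lb)


def test_subjects_share_grid_and_time_windows():
    subs = generate_cohort(CohortConfig(n_cases=2, n_controls=2, seed=3, grid_shape=(16, 16, 16)))
    for s in subs:
        shapes = {scan.grid_shape for scan in s.scans}
        spacings = {scan.spacing_mm for scan in s.scans}
        assert len(shapes) == 1 and len(spacings) == 1
        times = [scan.time_years for scan in s.scans]
        assert all(t1 > t0 for t0, t1 in zip(times, times[1:]))
        assert times[-1] == 0.0  # index scan anchors the clock
        assert times[-1] - times[0] <= 2.0  # surveillance window


def test_case_subjects_trigger_progression_and_controls_do_not():
    subs = generate_cohort(CohortConfig(n_cases=3, n_controls=3, seed=5, grid_shape=(16, 16, 16)))
    from opgpred.cohort import ClinicalRecord

    for s in subs:
        rec = ClinicalRecord(
            subject_id=s.subject_id,
            va_series=s.va_series,
            radiographic_flags=s.radiographic_flags,
        )
        label, _ = label_progression(rec)
        expected = "progression" if s.group == "case" else "no_progression"
        assert label == expected


def test_group_effect_size_matches_printed_summaries():
    """Subject-level OR-FA separation reproduces the reported group contrast.

    With group summaries 2.38 +/- 1.79 vs 6.23 +/- 3.56 the pooled
    standardized difference is (6.23-2.38)/sqrt((3.56^2+1.79^2)/2) ~ 1.37;
    the empirical subject-level effect should land within 10%.
    """
    cfg = CohortConfig(
        n_cases=200, n_controls=200, seed=7, grid_shape=(16, 16, 16), scans_per_subject=1
    )
    subs = generate_cohort(cfg)
    fa = {"case": [], "control": []}
    for s in subs:
        fa[s.group].append(subject_or_fa_mean(s))
    case, ctrl = np.asarray(fa["case"]), np.asarray(fa["control"])
    d = abs(ctrl.mean() - case.mean()) / np.sqrt((case.std(ddof=1) ** 2 + ctrl.std(ddof=1) ** 2) / 2)
    expected = (6.23 - 2.38) / np.sqrt((3.56**2 + 1.79**2) / 2)
    assert d == pytest.approx(expected, rel=0.10)
    welch = stats.ttest_ind(ctrl, case, equal_var=False)
    assert welch.pvalue < 1e-6


def test_or_voxel_fa_follows_configured_distributions():
    """KS checks of the two levels the generator draws from.

    The FA signal is hierarchical (subject mean from the group
    distribution, voxels scattered around it), so the pooled voxel
    sample of a handful of subjects is a finite normal mixture, not an
    i.i.d. normal draw. The distributional contract is therefore tested
    where it holds exactly: (a) within-subject voxel residuals against
    N(0, noise_sd) at >= 1e4 voxels per group, and (b) subject means
    across many subjects against the group normal. Group means sit far
    from zero so censoring is inactive.
    """
    cfg = CohortConfig(
        n_cases=12,
        n_controls=12,
        seed=7,
        grid_shape=(32, 32, 32),
        scans_per_subject=1,
        fa_mean_case=8.0,
        fa_sd_case=1.0,
        fa_mean_control=12.0,
        fa_sd_control=1.5,
    )
    subs = generate_cohort(cfg)
    resid = {"case": [], "control": []}
    for s in subs:
        sel = s.masks[-1]["OR-L"].mask | s.masks[-1]["OR-R"].mask
        resid[s.group].extend(s.scans[-1].volumes["FA"][sel].astype(float) - s.fa_subject_mean)
    for group in ("case", "control"):
        x = np.asarray(resid[group])
        assert len(x) >= 10_000
        res = stats.kstest(x, stats.norm(0.0, cfg.noise_sd).cdf)
        assert res.pvalue > 0.01

    # subject-mean level, many light subjects
    cfg2 = CohortConfig(
        n_cases=150,
        n_controls=150,
        seed=7,
        grid_shape=(16, 16, 16),
        scans_per_subject=1,
        fa_mean_case=8.0,
        fa_sd_case=1.0,
        fa_mean_control=12.0,
        fa_sd_control=1.5,
    )
    means = {"case": [], "control": []}
    for s in generate_cohort(cfg2):
        means[s.group].append(s.fa_subject_mean)
    for group, mu, sd in (("case", 8.0, 1.0), ("control", 12.0, 1.5)):
        sb = np.sqrt(sd**2 - cfg2.noise_sd**2)
        res = stats.kstest(np.asarray(means[group]), stats.norm(mu, sb).cdf)
        assert res.pvalue > 0.01


# ---------------------------------------------------------------------------
# tube masks


def test_tube_cross_section_is_digital_disk():
    path = np.array([[10.5, 10.5, 3.0], [10.5, 10.5, 17.0]])
    tube = generate_tube_mask((21, 21, 20), (1, 1, 1), path, radius_mm=3.0)
    sl = tube.mask[:, :, 10]
    yy, xx = np.mgrid[:21, :21]
    disk = ((yy + 0.5 - 10.5) ** 2 + (xx + 0.5 - 10.5) ** 2) <= 9.0
    assert np.array_equal(sl, disk)


def test_tube_radius_below_half_spacing_raises():
    path = np.array([[8.0, 8.0, 2.0], [8.0, 8.0, 14.0]])
    with pytest.raises(GeometryError):
        generate_tube_mask((16, 16, 16), (2, 2, 2), path, radius_mm=0.5)


def test_tube_path_outside_grid_raises():
    path = np.array([[8.0, 8.0, 2.0], [8.0, 8.0, 40.0]])
    with pytest.raises(GeometryError):
        generate_tube_mask((16, 16, 16), (1, 1, 1), path, radius_mm=2.0)


def test_tube_volume_close_to_analytic_cylinder():
    path = np.array([[15.5, 15.5, 5.0], [15.5, 15.5, 25.0]])
    tube = generate_tube_mask((31, 31, 30), (1, 1, 1), path, radius_mm=5.0)
    analytic = np.pi * 25 * 20
    # the generator closes the tube with hemispherical caps around the path
    cap = 4 / 3 * np.pi * 125
    assert analytic <= tube.n_voxels * 1.0 <= (analytic + cap) * 1.15


# ---------------------------------------------------------------------------
# streamlines


def _two_rois():
    a = np.zeros((20, 20, 20), dtype=bool)
    a[2:6, 2:6, 8:12] = True
    b = np.zeros((20, 20, 20), dtype=bool)
    b[14:18, 14:18, 8:12] = True
    return (
        RegionMask(a, "ROI-A", (1, 1, 1)),
        RegionMask(b, "ROI-B", (1, 1, 1)),
        RegionMask(np.zeros((20, 20, 20), bool), "ROI-C", (1, 1, 1)),
    )


@pytest.mark.parametrize("decoy_fraction,expected_pass", [(0.0, 10), (0.5, 5)])
def test_streamline_decoy_fraction_controls_filter_pass_count(decoy_fraction, expected_pass):
    a, b, c = _two_rois()
    lines = generate_streamlines(a, b, n_lines=10, seed=1, decoy_fraction=decoy_fraction)
    assert lines.count == 10
    kept = filter_streamlines(lines, a, b, c)
    assert kept.count == expected_pass


def test_streamlines_deterministic_for_seed():
    a, b, _ = _two_rois()
    l1 = generate_streamlines(a, b, n_lines=8, seed=9, decoy_fraction=0.25)
    l2 = generate_streamlines(a, b, n_lines=8, seed=9, decoy_fraction=0.25)
    assert l1.count == l2.count
    for x, y in zip(l1.lines, l2.lines):
        assert np.array_equal(x, y)


def test_streamlines_empty_roi_raises():
    a, b, _ = _two_rois()
    empty = RegionMask(np.zeros((20, 20, 20), bool), "ROI-A", (1, 1, 1))
    with pytest.raises(GeometryError):
        generate_streamlines(empty, b, n_lines=5, seed=0)


# ---------------------------------------------------------------------------
# feature-level cohort


def test_make_feature_table_shapes_and_labels():
    tbl, labels = make_feature_table(n_cases=5, n_controls=7, n_noise=3, seed=1)
    assert tbl.data.shape == (12, 4)
    assert list(tbl.data.columns[:1]) == ["OR_FA_mean"]
    assert (labels == "case").sum() == 5


def test_make_feature_table_effect_scaling_doubles_separation():
    t1, l1 = make_feature_table(n_cases=2000, n_controls=2000, n_noise=0, seed=3)
    t2, l2 = make_feature_table(n_cases=2000, n_controls=2000, n_noise=0, seed=3, effect_scale=2.0)
    gap1 = (
        t1.data["OR_FA_mean"][l1 == "control"].mean() - t1.data["OR_FA_mean"][l1 == "case"].mean()
    )
    gap2 = (
        t2.data["OR_FA_mean"][l2 == "control"].mean() - t2.data["OR_FA_mean"][l2 == "case"].mean()
    )
    assert gap2 == pytest.approx(2 * gap1, rel=0.05)
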