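"""Synthetic generator: seasonal profiles, image construction, corpus truth."""

import numpy as np
import pandas as pd
import pytest

from ambientgreen import greenness, synth
from conftest import small_profile


# ---------------------------------------------------------------------------
# seasonal profiles


def test_zero_amplitude_gives_flat_profile():
    prof = synth.seasonal_profile(small_profile(amplitude=0.0, base=0.32))
    assert prof.month_means == (0.32,) * 12


def test_cosine_profile_peak_antipeak_and_quadrature():
    prof = synth.seasonal_profile(small_profile(base=0.34, amplitude=0.04, peak_month=7))
    assert prof.mu(7) == pytest.approx(0.38, abs=1e-12)  # peak
    assert prof.mu(1) == pytest.approx(0.30, abs=1e-12)  # antipeak
    assert prof.mu(4) == pytest.approx(0.34, abs=1e-12)  # quadrature: cos(pi/2)=0
    assert prof.mu(10) == pytest.approx(0.34, abs=1e-12)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(base=1.1),
        dict(base=0.5, amplitude=0.6),
        dict(base=0.02, amplitude=0.05),
        dict(base=0.3, amplitude=-0.1),
        dict(base=0.3, peak_month=13),
        dict(base=0.3, counts=0),
    ],
)
def test_invalid_profiles_rejected(kwargs):
    counts = kwargs.pop("counts", 5)
    with pytest.raises(ValueError):
        small_profile(
            base=kwargs.pop("base"), amplitude=kwargs.pop("amplitude", 0.04),
            monthly_counts=(counts,) * 12, **kwargs,
        )


# ---------------------------------------------------------------------------
# image construction


def oracle_pixel(target: float) -> tuple[int, int, int]:
    """Independent evaluation of the stated rounding rule (noise-free)."""
    g = min(max(int(np.floor(target * 300 + 0.5)), 0), 255)
    rem = 300 - g
    r = rem // 2 + rem % 2  # odd byte to R
    b = rem // 2
    return r, g, b


def test_gray_identity_image():
    arr, realized = synth.generate_image(1 / 3, 4, 3, pixel_noise_sd=0.0)
    assert arr.shape == (3, 4, 3)
    assert (arr == 100).all()
    assert realized == pytest.approx(1 / 3, abs=1e-15)


@pytest.mark.parametrize("target", [0.1, 0.2, 1 / 3, 0.37, 0.4113, 0.55, 0.8])
def test_noise_free_pixels_match_rounding_oracle(target):
    """Each constructed pixel follows round-half-away G, remainder split to R/B."""
    arr, realized = synth.generate_image(target, 1, 1, pixel_noise_sd=0.0)
    r, g, b = oracle_pixel(target)
    assert tuple(int(c) for c in arr[0, 0]) == (r, g, b)
    assert realized == pytest.approx(g / (r + g + b), abs=1e-15)


def test_known_rounding_example():
    # target 0.37: G = round(111.0) = 111, remainder 189 -> R = 95, B = 94
    arr, realized = synth.generate_image(0.37, 1, 1)
    assert tuple(int(c) for c in arr[0, 0]) == (95, 111, 94)
    assert realized == pytest.approx(111 / 300, abs=1e-15)


def test_noisy_image_hits_target_within_monte_carlo_error():
    arr, realized = synth.generate_image(0.35, 64, 64, pixel_noise_sd=0.05, seed=7)
    assert abs(realized - 0.35) < 0.01  # SE of mean over 4096 pixels ~ 0.0008
    # realized is the analysis-side recomputation
    assert realized == pytest.approx(greenness.image_greenness(arr)[0], abs=1e-15)


def test_image_generation_reproducible():
    a1, r1 = synth.generate_image(0.3, 16, 16, 0.04, seed=11)
    a2, r2 = synth.generate_image(0.3, 16, 16, 0.04, seed=11)
    assert (a1 == a2).all() and r1 == r2


@pytest.mark.parametrize(
    "target, sd", [(0.02, 0.0), (0.97, 0.0), (0.3, 0.1), (0.9, 0.02)]
)
def test_unattainable_targets_rejected(target, sd):
    with pytest.raises(ValueError, match="unattainable"):
        synth.generate_image(target, 4, 4, pixel_noise_sd=sd)


def test_bad_dimensions_rejected():
    with pytest.raises(ValueError):
        synth.generate_image(0.3, 0, 4)


# ---------------------------------------------------------------------------
# corpus generation


def test_clean_corpus_counts_and_classes(tmp_path):
    profile = small_profile(counts=5)
    paths = synth.generate_corpus([profile], tmp_path, seed=1, n_months=12,
                                  image_size=(16, 16))
    manifest = pd.read_csv(paths.manifest)
    truth = pd.read_csv(paths.truth)
    assert len(manifest) == sum(profile.monthly_counts)
    assert set(truth["class"]) == {"clean"}
    # truth partitions the manifest exactly
    assert sorted(truth.record_id) == sorted(manifest.record_id)
    assert manifest.record_id.is_unique


def test_duplicates_are_exact_byte_copies(tmp_path, small_corpus):
    profiles, paths = small_corpus
    manifest = pd.read_csv(paths.manifest)
    truth = pd.read_csv(paths.truth).set_index("record_id")
    dup_ids = truth.index[truth["class"] == "duplicate"]
    assert len(dup_ids) > 0
    by_id = manifest.set_index("record_id")
    contents = {
        rid: (paths.out_dir / by_id.loc[rid, "filepath"]).read_bytes()
        for rid in manifest.record_id
    }
    for rid in dup_ids:
        matches = [o for o, data in contents.items()
                   if o != rid and data == contents[rid]]
        assert matches, f"duplicate {rid} has no byte-identical partner"


def test_undersized_files_below_threshold_and_clean_above(small_corpus):
    _, paths = small_corpus
    manifest = pd.read_csv(paths.manifest).set_index("record_id")
    truth = pd.read_csv(paths.truth).set_index("record_id")
    for rid, row in truth.iterrows():
        nbytes = manifest.loc[rid, "bytes"]
        if row["class"] == "undersized":
            assert nbytes < synth.DEFAULT_MIN_BYTES
        else:
            assert nbytes >= synth.DEFAULT_MIN_BYTES
        # manifest byte counts match the files on disk
        assert nbytes == (paths.out_dir / manifest.loc[rid, "filepath"]).stat().st_size


def test_corpus_generation_bit_reproducible(tmp_path):
    profile = small_profile(counts=4, duplicate_rate=0.1, undersized_rate=0.1)
    p1 = synth.generate_corpus([profile], tmp_path / "a", seed=9, n_months=6,
                               image_size=(16, 16))
    p2 = synth.generate_corpus([profile], tmp_path / "b", seed=9, n_months=6,
                               image_size=(16, 16))
    assert p1.manifest.read_text() == p2.manifest.read_text()
    assert p1.truth.read_text() == p2.truth.read_text()
    m = pd.read_csv(p1.manifest)
    for _, row in m.head(3).iterrows():
        assert (p1.out_dir / row.filepath).read_bytes() == \
               (p2.out_dir / row.filepath).read_bytes()


def test_realized_greenness_tracks_target(small_corpus):
    """Every generated image's realized index is near its target."""
    _, paths = small_corpus
    truth = pd.read_csv(paths.truth)
    n_pixels = 24 * 24
    slack = 3 * 0.04 / np.sqrt(n_pixels) + 0.005  # pixel noise SE + rounding
    clean = truth[truth["class"].isin(["clean", "ad"])]
    assert (np.abs(clean.realized_greenness - clean.target_greenness) < slack).all()


def test_truth_table_monthly_means_recover_profile(tmp_path):
    """Park-month truth means reproduce the configured cosine profile."""
    profile = small_profile(base=0.33, amplitude=0.04, counts=40,
                            image_noise_sd=0.02)
    paths = synth.generate_corpus([profile], tmp_path, seed=5, n_months=12,
                                  image_size=(16, 16))
    manifest = pd.read_csv(paths.manifest)
    truth = pd.read_csv(paths.truth)
    merged = manifest.merge(truth, on="record_id")
    merged["month"] = pd.to_datetime(merged.timestamp).dt.month
    prof = synth.seasonal_profile(profile)
    for month, grp in merged.groupby("month"):
        se = 0.02 / np.sqrt(len(grp))
        assert abs(grp.realized_greenness.mean() - prof.mu(month)) < 4 * se + 0.005


def test_sample_observations_matches_model():
    profile = small_profile(base=0.32, amplitude=0.04, counts=400,
                            image_noise_sd=0.03)
    obs = synth.sample_observations(profile, seed=3, n_months=12)
    assert len(obs) == 4800
    prof = synth.seasonal_profile(profile)
    monthly = obs.groupby("month").greenness.mean()
    se = 0.03 / np.sqrt(400)
    for month, mean in monthly.items():
        assert abs(mean - prof.mu(month)) < 4 * se


# ---------------------------------------------------------------------------
# NDVI grids


def _spec(**kwargs):
    defaults = dict(intercept=0.1, slope=0.0, cell_noise_sd=0.0,
                    grid_extent_deg=1.0, grid_step_deg=0.1, park_center=(40.0, -105.0))
    defaults.update(kwargs)
    return synth.NdviCouplingSpec(**defaults)


def test_constant_grid_when_slope_and_noise_zero():
    prof = synth.seasonal_profile(small_profile())
    grid = synth.generate_ndvi_grid(_spec(), prof, seed=0)
    assert len(grid) == 11 * 11 * 12
    assert (grid.ndvi == 0.1).all()


def test_identity_coupling_reproduces_profile():
    prof = synth.seasonal_profile(small_profile(base=0.34, amplitude=0.04))
    grid = synth.generate_ndvi_grid(_spec(intercept=0.0, slope=1.0), prof, seed=0)
    monthly = grid.groupby("month").ndvi.mean()
    for month in range(1, 13):
        assert monthly.loc[month] == pytest.approx(prof.mu(month), abs=1e-12)


def test_noisy_grid_monthly_spatial_mean_within_se():
    prof = synth.seasonal_profile(small_profile(base=0.34, amplitude=0.04))
    grid = synth.generate_ndvi_grid(
        _spec(intercept=0.05, slope=1.0, cell_noise_sd=0.02), prof, seed=21
    )
    monthly = grid.groupby("month").ndvi.mean()
    for month in range(1, 13):  # SE of mean over 121 cells ~ 0.0018
        assert abs(monthly.loc[month] - (0.05 + prof.mu(month))) < 0.01


def test_ndvi_values_clipped_to_valid_range():
    prof = synth.seasonal_profile(small_profile())
    grid = synth.generate_ndvi_grid(
        _spec(intercept=0.9, slope=1.0, cell_noise_sd=0.5), prof, seed=2
    )
    assert grid.ndvi.between(-1.0, 1.0).all()
    assert (grid.ndvi == 1.0).any()  # clipping actually engaged


def test_invalid_coupling_spec_rejected():
    with pytest.raises(ValueError):
        _spec(grid_step_deg=0.0)
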