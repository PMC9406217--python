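"""Synthetic-data generators: determinism, truth labels, stated moments."""

import numpy as np
import pandas as pd
import pytest

from foxscreen import simulate
from foxscreen.de import classify_de
from foxscreen.simulate import (
    ConfigurationError,
    SynthCytometryConfig,
    SynthDEConfig,
    SynthImageConfig,
    SynthPlateConfig,
    SynthPromoterConfig,
    generate_cytometry_events,
    generate_de_table,
    generate_images,
    generate_plate,
    generate_promoters,
)


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

def test_missing_padj_count_is_exact():
    table, _ = generate_de_table(SynthDEConfig(n_genes=100, frac_missing_padj=0.1))
    assert table["p_adj"].isna().sum() == 10


def test_no_differential_genes_when_fraction_zero():
    table, truth = generate_de_table(SynthDEConfig(n_genes=200, frac_differential=0.0))
    present = table["p_adj"].dropna()
    assert (present > 0.05).all()
    assert (truth["true_status"] != "differential").all()


def test_classifier_recovers_generator_truth_exactly():
    cfg = SynthDEConfig(n_genes=1000, frac_differential=0.3, seed=7)
    table, truth = generate_de_table(cfg)
    out = classify_de(table)
    assert (out["status"] == truth["true_status"]).all()
    assert (out["direction"] == truth["true_direction"]).all()


def test_de_table_deterministic():
    a, ta = generate_de_table(SynthDEConfig(seed=42))
    b, tb = generate_de_table(SynthDEConfig(seed=42))
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(ta, tb)


def test_invalid_fraction_raises():
    with pytest.raises(ConfigurationError):
        SynthDEConfig(frac_missing_padj=1.5)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def test_planted_sites_recorded_and_embedded(forkhead_pwm):
    cfg = SynthPromoterConfig(
        n_promoters=3, planted=((0, 100, "+"), (0, 180, "+")), seed=1)
    records, truth = generate_promoters(cfg, forkhead_pwm)
    assert truth["offset"].tolist() == [100, 180]
    _, seq = records[0]
    w = forkhead_pwm.width
    assert seq[100:100 + w] == forkhead_pwm.consensus
    assert seq[180:180 + w] == forkhead_pwm.consensus
    # start-to-start 80 <= 100: cluster-eligible by construction
    assert truth["offset"].diff().iloc[-1] <= 100


def test_no_plants_gives_empty_truth(forkhead_pwm):
    cfg = SynthPromoterConfig(n_promoters=2, gc_content=0.5, seed=0)
    records, truth = generate_promoters(cfg, forkhead_pwm)
    assert truth.empty
    assert len(records[0][1]) == cfg.length


def test_offset_outside_window_rejected(forkhead_pwm):
    with pytest.raises(ConfigurationError, match="offset"):
        generate_promoters(
            SynthPromoterConfig(n_promoters=1, planted=((0, 1995, "+"),)),
            forkhead_pwm)


def test_promoters_deterministic(forkhead_pwm):
    cfg = SynthPromoterConfig(n_promoters=4, planted=((1, 10, "-"),), seed=9)
    a, _ = generate_promoters(cfg, forkhead_pwm)
    b, _ = generate_promoters(cfg, forkhead_pwm)
    assert a == b


def test_promoter_gc_content_tracks_config(forkhead_pwm):
    cfg = SynthPromoterConfig(n_promoters=5, gc_content=0.7, seed=2)
    records, _ = generate_promoters(cfg, forkhead_pwm)
    seq = "".join(s for _, s in records)
    gc = sum(b in "GC" for b in seq) / len(seq)
    assert gc == pytest.approx(0.7, abs=0.02)


# ---------------------------------------------------------------------------
# cytometry
# ---------------------------------------------------------------------------

def test_pure_g1_population():
    cfg = SynthCytometryConfig(n_events=2000, fractions=(1.0, 0.0, 0.0), seed=0)
    events, labels = generate_cytometry_events(cfg)
    assert set(labels) == {"g1"}
    assert events.mean() == pytest.approx(100.0, rel=0.01)


def test_g2m_component_doubles_g1_mean():
    cfg = SynthCytometryConfig(
        n_events=20_000, g1_mean=100.0, fractions=(0.4, 0.2, 0.4), seed=1)
    events, labels = generate_cytometry_events(cfg)
    assert events[labels == "g2m"].mean() == pytest.approx(200.0, rel=0.01)
    assert events[labels == "g1"].mean() == pytest.approx(100.0, rel=0.01)
    s = events[labels == "s"]
    assert s.min() >= 100.0 and s.max() <= 200.0


def test_fractions_must_sum_to_one():
    with pytest.raises(ConfigurationError, match="sum to 1"):
        SynthCytometryConfig(fractions=(0.5, 0.2, 0.2))


def test_cytometry_deterministic():
    a, _ = generate_cytometry_events(SynthCytometryConfig(seed=5))
    b, _ = generate_cytometry_events(SynthCytometryConfig(seed=5))
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------

def test_vehicle_wells_match_vehicle_mean():
    cfg = SynthPlateConfig(vehicle_mean=500.0, n_replicates=200, seed=3)
    plate = generate_plate(cfg)
    vehicle = plate[plate["dose"] == 0.0]["total"]
    assert vehicle.mean() == pytest.approx(500.0, rel=0.03)


def test_flat_curve_when_emax_zero():
    cfg = SynthPlateConfig(emax=0.0, vehicle_mean=1000.0, n_replicates=50, seed=4)
    plate = generate_plate(cfg)
    means = plate.groupby("dose")["total"].mean()
    assert (np.abs(means - 1000.0) < 4 * np.sqrt(1000.0 / 50)).all()


def test_plate_expectation_follows_hill_curve():
    cfg = SynthPlateConfig(
        vehicle_mean=2000.0, doses=(0.5, 1.0, 2.0, 4.0, 8.0),
        ec50=2.0, hill=2.0, emax=0.5, n_replicates=20, seed=6)
    plate = generate_plate(cfg)
    for dose, group in plate[plate["dose"] > 0].groupby("dose"):
        expected = 2000.0 * (1 - 0.5 * dose**2 / (dose**2 + 4.0))
        se = np.sqrt(expected / 20)
        assert abs(group["total"].mean() - expected) < 4 * se


def test_dead_counts_bounded_by_totals():
    plate = generate_plate(SynthPlateConfig(death_emax=0.5, seed=7))
    assert ((plate["dead"] >= 0) & (plate["dead"] <= plate["total"])).all()


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def test_image_stack_shape_and_dtype():
    stack, truth = generate_images(SynthImageConfig(seed=0))
    assert stack.shape == (3, 512, 512)
    assert stack.dtype == np.uint16
    n_colonies = (truth["object"] == "colony").sum()
    n_nuclei = (truth["object"] == "nucleus").sum()
    assert len(truth) == n_colonies + n_nuclei  # one row per drawn object


def test_every_colony_has_a_nucleus_when_no_anuclear():
    _, truth = generate_images(SynthImageConfig(frac_anuclear=0.0, seed=1))
    colonies = truth[truth["object"] == "colony"]
    nuclei = truth[truth["object"] == "nucleus"]
    assert set(colonies["colony_id"]) == set(nuclei["colony_id"])


def test_empty_field_is_background_only():
    cfg = SynthImageConfig(n_colonies=0, seed=2)
    stack, truth = generate_images(cfg)
    assert truth.empty
    # Poisson background at level 100: no pixel plausibly exceeds 180
    assert stack.max() < 180


def test_anuclear_colonies_lack_hoechst_signal():
    cfg = SynthImageConfig(frac_anuclear=1.0, seed=3)
    stack, truth = generate_images(cfg)
    assert (truth["object"] == "colony").all()
    assert stack[0].max() < 180  # Hoechst channel is background only


def test_fragments_stay_within_parent_area_budget():
    cfg = SynthImageConfig(frac_fragmented=1.0, seed=4)
    _, truth = generate_images(cfg)
    nuclei = truth[truth["object"] == "nucleus"]
    assert (nuclei["fragmented"]).all()
    assert nuclei["parent_id"].str.len().gt(0).all()
    counts = nuclei.groupby("parent_id").size()
    assert counts.between(1, 3).all()  # 2-3 drawn, minus placement failures


def test_images_deterministic():
    a, ta = generate_images(SynthImageConfig(seed=8))
    b, tb = generate_images(SynthImageConfig(seed=8))
    assert np.array_equal(a, b)
    pd.testing.assert_frame_equal(ta, tb)
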