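"""Generator contracts: protocol timing, effect injection, truncation,
determinism and the CSV round trip."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from synmix import (
    ConnectionEntry,
    GeneratorParams,
    ParameterError,
    ProtocolParams,
    generate_ecs_dataset,
    generate_experiment,
    generate_scs_database,
    read_connections,
    read_recordings,
    write_connections,
    write_recordings,
)

BIC = [("LTP", 7, 39.9, 14.7), ("LTD", 9, -38.5, 20.4), ("NC", 10, -3.0, 7.6)]


class TestGenerateExperiment:
    def test_protocol_timing(self, protocol):
        rec = generate_experiment(protocol, GeneratorParams(seed=0))
        pre = rec.sweeps[rec.sweeps.epoch == "pre"]
        pair = rec.sweeps[rec.sweeps.epoch == "pairing"]
        post = rec.sweeps[rec.sweeps.epoch == "post"]
        assert len(pre) == 120 and len(pair) == 60 and len(post) == 120
        assert pre.time_s.iloc[-1] - pre.time_s.iloc[0] == pytest.approx(595.0)
        assert pair.time_s.iloc[-1] - pair.time_s.iloc[0] == pytest.approx(590.0)
        assert rec.sweeps.time_s.is_monotonic_increasing
        assert pair.amplitude.isna().all()

    def test_null_generator_epoch_means_agree(self, protocol):
        gen = GeneratorParams(seed=42, true_delta_pct=0.0)
        rec = generate_experiment(protocol, gen)
        se = 0.10 * 375 * np.sqrt(2.0 / 120.0)
        assert abs(rec.pre.mean() - rec.post.mean()) < 3 * se

    def test_ltp_effect_injection(self, protocol):
        gen = GeneratorParams(baseline_mean=100.0, true_delta_pct=59.4, seed=5)
        rec = generate_experiment(protocol, gen)
        sem = 0.10 * 159.4 / np.sqrt(120)
        assert rec.post.mean() == pytest.approx(159.4, abs=3 * sem)

    def test_unit_follows_clamp_mode(self):
        vrec = generate_experiment(ProtocolParams(clamp_mode="V-clamp"), GeneratorParams(seed=0))
        irec = generate_experiment(ProtocolParams(clamp_mode="I-clamp"), GeneratorParams(seed=0))
        assert vrec.unit == "pA" and irec.unit == "mV"
        # clamp-mode default baselines: ~375 pA vs ~4 mV
        assert vrec.pre.mean() > 100 and irec.pre.mean() < 10

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_pre_sweeps": 0},
            {"pre_rate_hz": -0.2},
            {"post_lead_ms": -1},
            {"clamp_mode": "dynamic"},
        ],
    )
    def test_invalid_protocol(self, kwargs):
        with pytest.raises(ParameterError):
            ProtocolParams(**kwargs)

    @pytest.mark.parametrize(
        "kwargs", [{"baseline_mean": -1.0}, {"sweep_noise_cv": -0.1}]
    )
    def test_invalid_generator(self, kwargs):
        with pytest.raises(ParameterError):
            GeneratorParams(**kwargs)


class TestGenerateDataset:
    def test_composition_counts_and_truncation(self, protocol):
        recs = generate_ecs_dataset(BIC, protocol, GeneratorParams(seed=3), condition="bic")
        assert len(recs) == 26
        truths = np.array([r.true_delta_pct for r in recs])
        assert (truths[:7] > 15).all()  # LTP ground truth above the boundary
        assert (truths[7:16] < -15).all()
        assert (np.abs(truths[16:]) <= 15).all()

    def test_zero_sd_nc_composition(self, protocol):
        recs = generate_ecs_dataset([("NC", 5, 0.0, 0.0)], protocol, GeneratorParams(seed=0))
        assert len(recs) == 5
        assert all(r.true_delta_pct == 0.0 for r in recs)

    def test_zero_sd_outside_class_rejected(self, protocol):
        with pytest.raises(ParameterError):
            generate_ecs_dataset([("LTP", 2, 10.0, 0.0)], protocol, GeneratorParams(seed=0))

    def test_empty_composition_rejected(self, protocol):
        with pytest.raises(ParameterError):
            generate_ecs_dataset([], protocol, GeneratorParams(seed=0))

    def test_seed_determinism(self, protocol):
        a = generate_ecs_dataset(BIC, protocol, GeneratorParams(seed=17))
        b = generate_ecs_dataset(BIC, protocol, GeneratorParams(seed=17))
        for ra, rb in zip(a, b):
            pd.testing.assert_frame_equal(ra.sweeps, rb.sweeps)


class TestSCSDatabase:
    def test_default_database(self):
        db = generate_scs_database(seed=1)
        assert len(db) == 43
        df = db.to_frame()
        assert (df.strength_pre_pa > 0).all()
        # delta invariant: delta_n_pct consistent with the strength pair
        expect = 100 * (df.strength_post_pa - df.strength_pre_pa) / df.strength_pre_pa
        np.testing.assert_allclose(df.delta_n_pct, expect)
        # truncation: labels match the ground-truth effect class
        assert (df.loc[df.outcome == "LTP", "delta_n_pct"] > 15).all()
        assert (df.loc[df.outcome == "LTD", "delta_n_pct"] < -15).all()
        assert (df.loc[df.outcome == "NC", "delta_n_pct"].abs() <= 15).all()

    def test_degenerate_probs(self):
        db = generate_scs_database(n=20, outcome_probs=(1.0, 0.0, 0.0), seed=2)
        assert all(e.outcome == "LTP" for e in db.entries)

    def test_strength_law_of_large_numbers(self):
        db = generate_scs_database(n=10_000, seed=4)
        strengths = db.to_frame().strength_pre_pa
        assert strengths.mean() == pytest.approx(19.4, abs=3 * 6.0 / 100.0)

    def test_same_seed_identical(self):
        a = generate_scs_database(seed=9).to_frame()
        b = generate_scs_database(seed=9).to_frame()
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 0},
            {"outcome_probs": (0.5, 0.5, 0.5)},
            {"strength_model": (-5.0, 1.0)},
            {"group_delta_models": {"LTP": (10.0, 0.0)}},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ParameterError):
            generate_scs_database(seed=0, **kwargs)

    def test_connection_entry_invariants(self):
        with pytest.raises(ParameterError):
            ConnectionEntry("c", -1.0, 10.0, "LTP")
        with pytest.raises(ParameterError):
            ConnectionEntry("c", 10.0, 10.0, "LTQ")


class TestCSVRoundTrip:
    def test_recordings(self, protocol, tmp_path):
        recs = generate_ecs_dataset(
            [("NC", 2, 0.0, 5.0)], protocol, GeneratorParams(seed=8), condition="ctl"
        )
        path = write_recordings(recs, tmp_path / "d.csv", manifest={"seed": 8})
        assert (tmp_path / "d.manifest.json").exists()
        back = read_recordings(path)
        assert [r.cell_id for r in back] == [r.cell_id for r in recs]
        for orig, rb in zip(recs, back):
            np.testing.assert_allclose(rb.pre, orig.pre)
            np.testing.assert_allclose(rb.post, orig.post)
            assert rb.vm_mv == orig.vm_mv
            assert rb.clamp_mode == orig.clamp_mode
            np.testing.assert_allclose(
                rb.ra_series.ra_mohm, orig.ra_series.ra_mohm
            )

    def test_connections(self, scs_db, tmp_path):
        path = write_connections(scs_db, tmp_path / "db.csv")
        back = read_connections(path)
        pd.testing.assert_frame_equal(back.to_frame(), scs_db.to_frame())
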