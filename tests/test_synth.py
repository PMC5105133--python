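import numpy as np
import pytest
from scipy import stats as sp_stats

from lfcnet import synth
from lfcnet.coherence import WCEngine
from lfcnet.montage import CHANNELS
from lfcnet.synth import (
    BETA_PAIRS_7,
    DELTA_PAIRS_3,
    THETA_PAIRS_17,
    CouplingSpec,
    SyntheticConfig,
    generate_behavior,
    simulate_cohort,
    simulate_trial,
)


def tiny_config(**kw):
    defaults = dict(
        n_subjects_per_group=1,
        n_sessions=1,
        trials_per_session={"P": 1},
        seed=0,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_defaults_give_800_samples_per_epoch(self):
        cfg = SyntheticConfig()
        assert cfg.fs == 500.0
        assert cfg.epoch_window == (-0.3, 1.3)
        assert cfg.n_samples == 800

    def test_channel_list_must_be_the_canonical_montage(self):
        with pytest.raises(ValueError, match="montage"):
            SyntheticConfig(channels=CHANNELS[:10])

    @pytest.mark.parametrize(
        "spec_kw,msg",
        [
            (dict(band="gamma"), "band"),
            (dict(window=(1.0, 1.5)), "window"),
            (dict(kappa=1.5), "kappa"),
            (dict(group="witness"), "group"),
        ],
    )
    def test_invalid_coupling_entries_rejected(self, spec_kw, msg):
        base = dict(pair=("C4", "Fz"), band="theta")
        base.update(spec_kw)
        with pytest.raises(ValueError, match=msg):
            tiny_config(coupling_plan=(CouplingSpec(**base),))

    def test_designated_sets_have_published_sizes(self):
        assert len(THETA_PAIRS_17) == 17
        assert len(BETA_PAIRS_7) == 7
        assert len(DELTA_PAIRS_3) == 3


class TestSimulateTrial:
    def test_trial_shape_is_channels_by_samples(self):
        cfg = tiny_config()
        arr, meta = simulate_trial(cfg, "guilty", "P", np.random.default_rng(0))
        assert arr.shape == (12, 800)
        assert meta["group"] == "guilty" and meta["stim"] == "P"
        assert meta["rt_ms"] >= 0

    @pytest.mark.parametrize("group,stim", [("suspect", "P"), ("guilty", "Q")])
    def test_unknown_labels_rejected(self, group, stim):
        with pytest.raises(ValueError):
            simulate_trial(tiny_config(), group, stim, np.random.default_rng(0))

    def test_p300_bump_on_guilty_probe_and_targets_only(self):
        cfg = tiny_config(erp_amplitude=8.0, background_sd=0.5)
        rng = lambda: np.random.default_rng(7)
        t = cfg.time_axis
        peak_win = (t > 0.3) & (t < 0.5)
        pz = CHANNELS.index("Pz")

        def peak(group, stim):
            arr, _ = simulate_trial(cfg, group, stim, rng())
            return arr[pz, peak_win].max()

        assert peak("guilty", "P") > 5.0
        assert peak("guilty", "T") > 5.0
        assert peak("innocent", "T") > 5.0
        assert peak("innocent", "P") < 3.0
        assert peak("guilty", "I") < 3.0

    def test_coupling_raises_target_divisional_cell_over_nonplan_pairs(self):
        # kappa=0.8 theta coupling on C4-Fz, 250-600 ms, guilty-P trials:
        # the theta/3# cell on C4-Fz must exceed the mean over non-plan
        # pairs by a margin established with a Monte-Carlo oracle run
        # (60 trials; margin 0.02 is ~3 MC standard errors).
        cfg = tiny_config(
            coupling_plan=(CouplingSpec(pair=("C4", "Fz"), band="theta"),),
            erp_amplitude=0.0,
        )
        eng = WCEngine(cfg.fs, cfg.n_samples, bands=("theta",))
        pair_idx = [
            k for k, (i, j) in enumerate(zip(*np.triu_indices(12, 1)))
            if {CHANNELS[i], CHANNELS[j]} == {"C4", "Fz"}
        ][0]
        rng = np.random.default_rng(11)
        target, others = [], []
        for _ in range(60):
            arr, _ = simulate_trial(cfg, "guilty", "P", rng)
            cells = eng.trial_divisional(arr.astype(np.float64))
            target.append(cells[pair_idx, 0, 2])
            others.append(np.delete(cells[:, 0, 2], pair_idx).mean())
        assert np.mean(target) > np.mean(others) + 0.02

    def test_null_generator_has_no_group_contrast(self):
        # kappa=0 everywhere: guilty and innocent trials are exchangeable
        cfg = tiny_config(
            coupling_plan=(
                CouplingSpec(pair=("C4", "Fz"), band="theta", kappa=0.0),
            ),
            erp_amplitude=0.0,
        )
        rng = np.random.default_rng(3)
        g, _ = simulate_trial(cfg, "guilty", "P", rng)
        rng = np.random.default_rng(3)
        i, _ = simulate_trial(cfg, "innocent", "P", rng)
        np.testing.assert_array_equal(g, i)

    def test_coupling_locality_leaves_prestimulus_and_disjoint_pairs_null(self):
        # theta/3# coupling on C4-Fz must not move (a) the 1# cell of
        # C4-Fz, (b) any cell of the disjoint pair P3-Oz (KS test, a=0.01)
        plan = (CouplingSpec(pair=("C4", "Fz"), band="theta"),)
        coupled = tiny_config(coupling_plan=plan, erp_amplitude=0.0)
        null = tiny_config(erp_amplitude=0.0)
        eng = WCEngine(500.0, 800, bands=("theta",))
        ii, jj = np.triu_indices(12, 1)
        idx_t = [k for k in range(66) if {CHANNELS[ii[k]], CHANNELS[jj[k]]} == {"C4", "Fz"}][0]
        idx_d = [k for k in range(66) if {CHANNELS[ii[k]], CHANNELS[jj[k]]} == {"P3", "Oz"}][0]
        rc, rn = np.random.default_rng(5), np.random.default_rng(6)
        c1, cd, n1, nd = [], [], [], []
        for _ in range(50):
            a, _ = simulate_trial(coupled, "guilty", "P", rc)
            b, _ = simulate_trial(null, "guilty", "P", rn)
            ca = eng.trial_divisional(a.astype(np.float64))
            cb = eng.trial_divisional(b.astype(np.float64))
            c1.append(ca[idx_t, 0, 0]); cd.append(ca[idx_d, 0, 2])
            n1.append(cb[idx_t, 0, 0]); nd.append(cb[idx_d, 0, 2])
        assert sp_stats.ks_2samp(c1, n1).pvalue > 0.01
        assert sp_stats.ks_2samp(cd, nd).pvalue > 0.01


class TestSimulateCohort:
    def test_default_session_structure_gives_1560_probe_trials_per_group(self):
        cfg = SyntheticConfig(seed=1)  # 26 P x 4 sessions x 15 subjects
        assert cfg.n_trials_per_subject == 104
        counts = cfg.n_trials_per_subject * cfg.n_subjects_per_group
        assert counts == 1560

    def test_minimal_cohort_has_two_trials(self):
        ep = simulate_cohort(tiny_config())
        assert ep.n_trials == 2
        assert set(ep.meta["group"]) == {"guilty", "innocent"}

    def test_same_seed_reproduces_cohort_bit_for_bit(self):
        cfg = tiny_config(
            trials_per_session={"P": 3},
            coupling_plan=(CouplingSpec(pair=("C4", "Fz"), band="theta"),),
        )
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.meta.equals(b.meta)

    def test_different_seeds_differ(self):
        a = simulate_cohort(tiny_config(seed=1))
        b = simulate_cohort(tiny_config(seed=2))
        assert not np.array_equal(a.data, b.data)


class TestBehavior:
    def test_tail_fraction_exceeds_700ms_at_binomial_rate(self):
        cfg = tiny_config(rt_tail_frac=0.1)
        beh = generate_behavior(cfg, 1000, np.random.default_rng(0))
        n_slow = int((beh["rt_ms"] > 700).sum())
        # binomial(1000, 0.1): 4 sigma ~ 38
        assert 62 <= n_slow <= 138

    def test_zero_tail_never_exceeds_700ms(self):
        cfg = tiny_config(rt_tail_frac=0.0)
        beh = generate_behavior(cfg, 500, np.random.default_rng(0))
        assert (beh["rt_ms"] <= 700).all()

    def test_empty_request_gives_empty_output(self):
        beh = generate_behavior(tiny_config(), 0, np.random.default_rng(0))
        assert len(beh) == 0

    def test_click_errors_emitted_at_configured_rate(self):
        cfg = tiny_config(click_error_rate=0.1)
        beh = generate_behavior(cfg, 1000, np.random.default_rng(1))
        assert 50 <= int((~beh["click_ok"]).sum()) <= 160
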