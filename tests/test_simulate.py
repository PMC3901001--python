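"""Mixing simulator: conservation, gating, assortment limits, rendering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smcoloc as smc
from smcoloc.simulate import N_SUBUNITS, SubunitColor


def make_config(**kwargs):
    defaults = dict(n_red=40, n_green=40, seed=0, k_ex=1.0, duration_min=20.0)
    defaults.update(kwargs)
    return smc.MixingConfig(**defaults)


class TestHoloenzyme:
    def test_must_be_dodecameric(self):
        with pytest.raises(ValueError):
            smc.Holoenzyme(
                id=0,
                subunit_colors=(SubunitColor.RED,) * 10,
                activated=False,
                pT286=(False,) * 10,
            )

    def test_counts_and_dual_flag(self):
        h = smc.Holoenzyme(
            id=1,
            subunit_colors=(SubunitColor.RED,) * 3
            + (SubunitColor.GREEN,) * 2
            + (SubunitColor.UNLABELED,) * 7,
            activated=True,
            pT286=(True,) * 12,
        )
        assert (h.n_red, h.n_green, h.n_pT286) == (3, 2, 12)
        assert h.is_dual


class TestMixingConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_red=0, n_green=0),
            dict(n_red=-1),
            dict(label_prob=1.5),
            dict(dark_prob=-0.1),
            dict(k_ex=-1.0),
            dict(duration_min=-5.0),
            dict(exchange_unit="trimer"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_config(**kwargs)


class TestSimulateMixing:
    def test_no_exchange_keeps_pools_separate(self):
        """k_ex = 0: population identical to t=0, no dual-color holoenzymes."""
        cfg = make_config(k_ex=0.0, duration_min=100.0, activated_fraction=0.5)
        snaps = smc.simulate_mixing(cfg, [0.0, 100.0])
        assert np.array_equal(snaps[0.0].colors, snaps[100.0].colors)
        assert snaps[100.0].dual_color_fraction() == 0.0

    def test_activation_gating(self):
        """No activated holoenzymes: no exchange at any k_ex."""
        cfg = make_config(activated_fraction=0.0, k_ex=50.0, duration_min=200.0)
        pop = smc.simulate_mixing(cfg)[200.0]
        assert pop.dual_color_fraction() == 0.0

    def test_initial_pools_single_colored(self):
        cfg = make_config(k_ex=5.0)
        pop0 = smc.simulate_mixing(cfg, [0.0])[0.0]
        reds = pop0.colors[: cfg.n_red]
        greens = pop0.colors[cfg.n_red :]
        assert not np.any(reds == SubunitColor.GREEN.value)
        assert not np.any(greens == SubunitColor.RED.value)

    @pytest.mark.parametrize("unit", ["dimer", "monomer"])
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_color_conservation(self, unit, seed):
        """Per-color subunit totals are exactly conserved over any trajectory."""
        cfg = make_config(seed=seed, exchange_unit=unit, k_ex=3.0, n_red=30, n_green=50)
        snaps = smc.simulate_mixing(cfg, [0.0, 5.0, 20.0])
        totals = [snaps[t].color_totals() for t in (0.0, 5.0, 20.0)]
        assert totals[0] == totals[1] == totals[2]

    def test_labeling_probability_scale(self):
        """Mean visible labels per holoenzyme tracks label_prob×(1−dark_prob)×12."""
        cfg = make_config(
            n_red=2000, n_green=0, k_ex=0.0, label_prob=0.3, dark_prob=0.2, seed=4
        )
        pop = smc.simulate_mixing(cfg, [0.0])[0.0]
        mean_visible = pop.n_red_per_holo.mean()
        assert mean_visible == pytest.approx(12 * 0.24, rel=0.1)

    def test_snapshot_validation(self):
        cfg = make_config()
        with pytest.raises(ValueError):
            smc.simulate_mixing(cfg, [-1.0])
        with pytest.raises(ValueError):
            smc.simulate_mixing(cfg, [cfg.duration_min + 1])

    def test_monotone_mixing_with_exposure(self):
        """Mean dual-color fraction rises with k_ex×duration (Mann–Kendall)."""
        exposures = [0.0, 0.05, 0.15, 0.5, 1.5]
        means = []
        for k_ex in exposures:
            vals = [
                smc.simulate_mixing(
                    make_config(seed=s, k_ex=k_ex, duration_min=10.0)
                )[10.0].dual_color_fraction()
                for s in range(20)
            ]
            means.append(np.mean(vals))
        s_stat = sum(
            np.sign(means[j] - means[i])
            for i in range(len(means))
            for j in range(i + 1, len(means))
        )
        assert s_stat >= 8  # strong positive trend out of a maximum of 10


class TestAssortmentLimits:
    def test_closed_form_oracle_by_enumeration(self):
        """Enumerate all 2^12 equally likely colorings: dual fraction 1−2·(1/2)^12."""
        n_dual = sum(
            1
            for coloring in itertools.product((0, 1), repeat=N_SUBUNITS)
            if 0 < sum(coloring) < N_SUBUNITS
        )
        assert n_dual / 2**N_SUBUNITS == 1 - 2 * 0.5**N_SUBUNITS

    def test_full_assortment_monomer_limit(self):
        """Heavily exchanged 50/50 pools approach the random-assortment limit."""
        n = 3000
        cfg = smc.MixingConfig(
            n_red=n // 2,
            n_green=n // 2,
            seed=11,
            label_prob=1.0,
            dark_prob=0.0,
            activated_fraction=1.0,
            k_ex=30.0,
            duration_min=1.0,
            exchange_unit="monomer",
        )
        frac = smc.simulate_mixing(cfg)[1.0].dual_color_fraction()
        expected = 1 - 2 * 0.5**12
        tol = 4 * np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) <= tol

    def test_full_assortment_dimer_limit(self):
        """With intact vertical dimers the limit is over 6 dimer slots: 1−2·(1/2)^6."""
        n = 3000
        cfg = smc.MixingConfig(
            n_red=n // 2,
            n_green=n // 2,
            seed=12,
            label_prob=1.0,
            dark_prob=0.0,
            activated_fraction=1.0,
            k_ex=30.0,
            duration_min=1.0,
            exchange_unit="dimer",
        )
        frac = smc.simulate_mixing(cfg)[1.0].dual_color_fraction()
        expected = 1 - 2 * 0.5**6  # fully labeled dimers stay single-colored
        tol = 4 * np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) <= tol


class TestTrueColocalizationFraction:
    def _holo(self, i, n_red, n_green):
        colors = (
            (SubunitColor.RED,) * n_red
            + (SubunitColor.GREEN,) * n_green
            + (SubunitColor.UNLABELED,) * (12 - n_red - n_green)
        )
        return smc.Holoenzyme(id=i, subunit_colors=colors, activated=False, pT286=(False,) * 12)

    def test_mixed_population_counts_rarer_color(self):
        pop = [self._holo(0, 6, 6), self._holo(1, 12, 0), self._holo(2, 0, 12)]
        assert smc.true_colocalization_fraction(pop) == 0.5

    def test_all_dual(self):
        pop = [self._holo(i, 3, 3) for i in range(5)]
        assert smc.true_colocalization_fraction(pop) == 1.0

    def test_unmixed_pools(self):
        pop = [self._holo(0, 4, 0), self._holo(1, 0, 4)]
        assert smc.true_colocalization_fraction(pop) == 0.0

    def test_unlabeled_population_flagged(self):
        pop = [self._holo(0, 0, 0)]
        with pytest.warns(UserWarning):
            assert np.isnan(smc.true_colocalization_fraction(pop))

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            smc.true_colocalization_fraction([])


class TestRenderField:
    def test_empty_sample_background_only(self):
        spec = smc.FieldSpec(width_px=64, height_px=64, n_spots=0, seed=1, background=50.0)
        pop = smc.population_with_dual_fraction(1, 0.0, seed=0)
        images, records = smc.render_field(pop, spec)
        assert records == []
        assert images["red"].mean() == pytest.approx(50.0, rel=0.05)

    def test_noiseless_rendering_linearity(self):
        """Integrated signal above background = n_visible × unit_brightness."""
        pop = smc.Population(
            colors=np.array([[1, 1, 1] + [0] * 9], dtype=np.uint8),
            activated=np.zeros(1, bool),
            pT286=np.zeros((1, 12), bool),
        )
        for brightness in (500.0, 1000.0):
            spec = smc.FieldSpec(
                width_px=64,
                height_px=64,
                n_spots=1,
                seed=2,
                shot_noise=False,
                read_noise_sd=0.0,
                unit_brightness=brightness,
                background=20.0,
            )
            images, records = smc.render_field(pop, spec)
            signal = images["red"].sum() - 20.0 * images["red"].size
            assert signal == pytest.approx(3 * brightness, rel=1e-3)
            assert np.allclose(images["green"], 20.0)

    def test_ground_truth_row_per_spot(self):
        pop = smc.population_with_dual_fraction(100, 0.5, seed=3)
        spec = smc.FieldSpec(n_spots=50, seed=4)
        _, records = smc.render_field(pop, spec)
        assert len(records) == 50
        for r in records:
            assert 0 <= r.n_red_visible + r.n_green_visible <= 12
            assert spec.margin_px <= r.x_px <= spec.width_px - 1 - spec.margin_px
            assert spec.margin_px <= r.y_px <= spec.height_px - 1 - spec.margin_px

    def test_oversampling_requires_replacement(self):
        pop = smc.population_with_dual_fraction(10, 0.5, seed=5)
        spec = smc.FieldSpec(n_spots=20, seed=6, width_px=128, height_px=128)
        with pytest.raises(ValueError):
            smc.render_field(pop, spec)
        _, records = smc.render_field(pop, spec, replace=True)
        assert len(records) == 20

    def test_high_density_warning(self):
        pop = smc.population_with_dual_fraction(600, 0.5, seed=8)
        spec = smc.FieldSpec(width_px=64, height_px=64, n_spots=500, seed=8, margin_px=5)
        with pytest.warns(UserWarning, match="density"):
            smc.render_field(pop, spec)

    def test_antibody_channel_counts(self):
        colors = np.zeros((4, 12), dtype=np.uint8)
        colors[:, 0] = 1
        pt = np.zeros((4, 12), dtype=bool)
        pt[:2] = True  # two fully phosphorylated holoenzymes
        pop = smc.Population(colors, np.zeros(4, bool), pt)
        spec = smc.FieldSpec(
            width_px=96,
            height_px=96,
            n_spots=4,
            seed=9,
            shot_noise=False,
            read_noise_sd=0.0,
            channels=("red", "pT286"),
            antibody_mode="per_holoenzyme",
            min_separation_px=10.0,
        )
        images, records = smc.render_field(pop, spec)
        total_ab = images["pT286"].sum() - spec.background * images["pT286"].size
        assert total_ab == pytest.approx(2 * spec.unit_brightness, rel=1e-3)
        assert sum(r.n_pT286 > 0 for r in records) == 2


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    k_ex=st.floats(0.0, 5.0),
    n_red=st.integers(1, 60),
    n_green=st.integers(1, 60),
)
def test_conservation_property(seed, k_ex, n_red, n_green):
    """Color totals are conserved for arbitrary pool sizes and rates."""
    cfg = smc.MixingConfig(
        n_red=n_red, n_green=n_green, seed=seed, k_ex=k_ex, duration_min=5.0
    )
    snaps = smc.simulate_mixing(cfg, [0.0, 5.0])
    assert snaps[0.0].color_totals() == snaps[5.0].color_totals()
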