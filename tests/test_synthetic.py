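"""Synthetic cohort generator: geometry, cohort structure, waveforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plaquestress as ps
from plaquestress.labels import Label


def _plaque_voxel_count(stenosis, seed, voxel=0.3):
    """Voxel-counting oracle: plaque annulus size via an all-calcific run."""
    p = ps.GeometryParams(
        stenosis_degree=stenosis, calcific_fraction=1.0, lipid_fraction=0.0,
        voxel_size=voxel, seed=seed,
    )
    return ps.generate_vessel_labelmap(p).count(Label.CALCIFIC)


class TestVesselLabelmap:
    def test_no_stenosis_is_plain_tube(self):
        vol = ps.generate_vessel_labelmap(ps.GeometryParams(stenosis_degree=0.0, voxel_size=0.5))
        assert vol.count(Label.CALCIFIC) == 0
        assert vol.count(Label.LIPID) == 0
        areas = vol.mask(Label.LUMEN).sum(axis=(0, 1))
        assert np.all(areas == areas[0])  # constant-radius lumen

    def test_all_calcific_fills_plaque(self):
        p = ps.GeometryParams(stenosis_degree=0.6, calcific_fraction=1.0, voxel_size=0.5, seed=3)
        vol = ps.generate_vessel_labelmap(p)
        assert vol.count(Label.CALCIFIC) == _plaque_voxel_count(0.6, 3, voxel=0.5)
        assert vol.count(Label.LIPID) == 0

    @pytest.mark.parametrize(
        "stenosis,fc,fl,seed", [(0.7, 0.3, 0.1, 7), (0.5, 0.15, 0.25, 1), (0.8, 0.5, 0.3, 2)]
    )
    def test_component_fractions_recovered(self, stenosis, fc, fl, seed):
        p = ps.GeometryParams(
            stenosis_degree=stenosis, calcific_fraction=fc, lipid_fraction=fl, seed=seed
        )
        vol = ps.generate_vessel_labelmap(p)
        n_plaque = _plaque_voxel_count(stenosis, seed)
        assert vol.count(Label.CALCIFIC) / n_plaque == pytest.approx(fc, abs=0.05)
        assert vol.count(Label.LIPID) / n_plaque == pytest.approx(fl, abs=0.05)

    def test_deterministic_per_seed(self):
        p = ps.GeometryParams(stenosis_degree=0.6, calcific_fraction=0.2, lipid_fraction=0.1,
                              voxel_size=0.5, seed=11)
        a = ps.generate_vessel_labelmap(p)
        b = ps.generate_vessel_labelmap(p)
        assert np.array_equal(a.data, b.data)

    def test_coarse_voxels_rejected(self):
        p = ps.GeometryParams(stenosis_degree=0.3, voxel_size=2.0)
        with pytest.raises(ValueError, match="coarse"):
            ps.generate_vessel_labelmap(p)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"voxel_size": -0.1},
            {"stenosis_degree": 1.0},
            {"calcific_fraction": 0.8, "lipid_fraction": 0.4},
            {"lipid_fraction": -0.2},
        ],
    )
    def test_invalid_geometry_params(self, kwargs):
        with pytest.raises(ValueError):
            ps.GeometryParams(**kwargs)

    def test_bifurcated_lumen_splits(self):
        p = ps.GeometryParams(stenosis_degree=0.5, voxel_size=0.5, bifurcated=True,
                              vessel_length=40.0)
        vol = ps.generate_vessel_labelmap(p)
        from scipy import ndimage

        k = vol.data.shape[2] - 1
        n_comp = ndimage.label(vol.mask(Label.LUMEN)[:, :, k])[1]
        assert n_comp == 2  # two branch lumens at the distal end

    @settings(max_examples=15, deadline=None)
    @given(
        stenosis=st.one_of(st.just(0.0), st.floats(0.35, 0.8)),
        fc=st.floats(0.0, 0.5),
        fl=st.floats(0.0, 0.4),
        seed=st.integers(0, 1000),
    )
    def test_labels_partition_property(self, stenosis, fc, fl, seed):
        """Every voxel has exactly one label drawn from the input label set."""
        p = ps.GeometryParams(
            stenosis_degree=stenosis, calcific_fraction=fc, lipid_fraction=fl,
            voxel_size=0.6, vessel_length=15.0, stenosis_length=8.0, seed=seed,
        )
        vol = ps.generate_vessel_labelmap(p)
        assert set(np.unique(vol.data)) <= {0, 1, 2, 3}
        from scipy import ndimage

        assert ndimage.label(vol.mask(Label.LUMEN))[1] == 1


class TestCohort:
    def test_sizes_and_groups(self):
        pats = ps.generate_cohort(0, 5, seed=1)
        assert len(pats) == 5
        assert all(p.record.group == "stable" for p in pats)
        with pytest.raises(ValueError):
            ps.generate_cohort(-1, 5)

    def test_deterministic(self):
        a = ps.generate_cohort(3, 3, seed=9)
        b = ps.generate_cohort(3, 3, seed=9)
        assert [p.record for p in a] == [p.record for p in b]
        assert [p.histology for p in a] == [p.histology for p in b]

    def test_record_invariants(self):
        for p in ps.generate_cohort(20, 20, seed=4):
            r = p.record
            assert r.systolic_pressure > r.diastolic_pressure > 0
            assert r.plaque_shear_speed >= 0
            g = p.geometry
            assert g.calcific_fraction + g.lipid_fraction <= 1

    def test_class_conditional_medians(self):
        """Monte-Carlo check of the configured class contrasts: vulnerable
        plaques are softer, lipid-richer and less calcified."""
        pats = ps.generate_cohort(10_000, 10_000, seed=5)
        ym = lambda r: ps.swe_young_modulus(r.plaque_shear_speed)
        vul = [p for p in pats if p.record.group == "vulnerable"]
        sta = [p for p in pats if p.record.group == "stable"]
        assert np.median([ym(p.record) for p in vul]) < np.median([ym(p.record) for p in sta])
        assert np.median([p.geometry.lipid_fraction for p in vul]) > np.median(
            [p.geometry.lipid_fraction for p in sta]
        )
        assert np.median([p.geometry.calcific_fraction for p in vul]) < np.median(
            [p.geometry.calcific_fraction for p in sta]
        )
        # converted medians sit near the configured population values (kPa)
        assert np.median([ym(p.record) for p in vul]) == pytest.approx(12.40, rel=0.15)
        assert np.median([ym(p.record) for p in sta]) == pytest.approx(34.70, rel=0.15)


class TestWaveform:
    def _record(self):
        return ps.PatientRecord(
            "T0", "stable", 16.0, 10.6, 2.0, 1.5, 1.5, 70.0, "M", 25.0, 8.0, 300.0
        )

    def test_noiseless_excursion_exact(self):
        w = ps.generate_distension_waveform(self._record(), 8.0, 300.0, noise_sd=0.0)
        assert w.n_cycles >= 6
        for seg in np.array_split(w.diameter, w.n_cycles):
            assert (seg.max() - seg.min()) * 1000.0 == pytest.approx(300.0, abs=1e-9)

    def test_zero_distension_constant(self):
        w = ps.generate_distension_waveform(self._record(), 8.0, 0.0, noise_sd=0.0)
        assert np.ptp(w.diameter) == 0.0

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            ps.generate_distension_waveform(self._record(), 8.0, 300.0, noise_sd=-1.0)

    def test_noisy_excursion_bias_bounded(self):
        """Per-cycle max/min extraction of a noisy trace over-estimates the
        excursion by at most the extreme-value envelope of the sample noise
        (sigma = 10 um, ~90 samples/cycle: 2 sigma sqrt(2 ln 90) ~ 60 um),
        with small seed-to-seed spread."""
        rec = self._record()
        vals = []
        for seed in range(40):
            w = ps.generate_distension_waveform(rec, 8.0, 300.0, noise_sd=10.0, seed=seed)
            vals.append(ps.measure_distension(w).distension)
        vals = np.asarray(vals)
        envelope = 2 * 10.0 * np.sqrt(2 * np.log(90))
        assert 300.0 < vals.mean() < 300.0 + envelope
        assert vals.std() < 15.0
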