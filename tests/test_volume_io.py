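"""Masking, pad/trim, channel stacking, NIfTI and record round-trips."""

import numpy as np
import pytest

from vbmnet import volume_io as vio
from vbmnet.volume_io import (DataLossError, PhenotypeRecord, RecordParseError,
                              SampleTensor, TissueVolumePair,
                              apply_background_mask, cohort_brain_mask,
                              pad_to_cube, stack_channels, unstack_channels)

from conftest import make_sample, random_pair


class TestApplyBackgroundMask:
    def test_all_true_mask_is_identity(self):
        rng = np.random.default_rng(0)
        pair = random_pair(rng)
        out = apply_background_mask(pair, np.ones(pair.shape, bool))
        assert np.array_equal(out.gm, pair.gm)
        assert np.array_equal(out.wm, pair.wm)

    def test_all_false_mask_sets_everything(self):
        rng = np.random.default_rng(1)
        out = apply_background_mask(random_pair(rng), np.zeros((8, 8, 8), bool))
        assert np.all(out.gm == -1.0) and np.all(out.wm == -1.0)

    def test_checkerboard_voxelwise(self):
        rng = np.random.default_rng(2)
        pair = random_pair(rng)
        idx = np.indices(pair.shape).sum(axis=0)
        mask = (idx % 2).astype(bool)
        out = apply_background_mask(pair, mask)
        # direct voxel-by-voxel oracle
        assert np.array_equal(out.gm[mask], pair.gm[mask])
        assert np.all(out.gm[~mask] == -1.0)
        assert np.array_equal(out.wm[mask], pair.wm[mask])
        assert np.all(out.wm[~mask] == -1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        pair = random_pair(rng)
        mask = rng.random(pair.shape) > 0.5
        once = apply_background_mask(pair, mask)
        twice = apply_background_mask(once, mask)
        assert np.array_equal(once.gm, twice.gm)

    def test_shape_mismatch(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            apply_background_mask(random_pair(rng), np.ones((4, 4, 4), bool))

    def test_cohort_mask_is_union(self):
        gm1 = np.full((4, 4, 4), -1.0, np.float32)
        gm1[0, 0, 0] = 0.5
        gm2 = np.full((4, 4, 4), -1.0, np.float32)
        gm2[1, 1, 1] = 0.5
        wm = np.full((4, 4, 4), -1.0, np.float32)
        mask = cohort_brain_mask([TissueVolumePair("a", gm1, wm),
                                  TissueVolumePair("b", gm2, wm)])
        assert mask[0, 0, 0] and mask[1, 1, 1] and mask.sum() == 2


def _brainy_volume(shape, rng, margin=3):
    """Background everywhere except a random interior blob."""
    vol = np.full(shape, -1.0, np.float32)
    sl = tuple(slice(margin, s - margin) for s in shape)
    vol[sl] = rng.uniform(0, 1, tuple(s - 2 * margin for s in shape)).astype(np.float32)
    return vol


class TestPadToCube:
    def test_mni_grid_to_128(self):
        rng = np.random.default_rng(0)
        gm = _brainy_volume((121, 145, 121), rng, margin=13)
        pair = TissueVolumePair("s", gm, gm.copy())
        out = pad_to_cube(pair, 128)
        assert out.shape == (128, 128, 128)
        in_brain = np.sort(gm[gm != -1.0])
        assert np.array_equal(np.sort(out.gm[out.gm != -1.0]), in_brain)

    def test_identity_when_already_cubic(self):
        rng = np.random.default_rng(1)
        pair = random_pair(rng, shape=(16, 16, 16))
        assert pad_to_cube(pair, 16) is pair

    def test_padding_is_background_and_centred(self):
        vol = np.zeros((4, 4, 4), np.float32) + 0.3
        pair = TissueVolumePair("s", vol, vol.copy())
        out = pad_to_cube(pair, 9)
        # odd remainder 5 -> 2 before, 3 after
        assert out.shape == (9, 9, 9)
        assert np.all(out.gm[:2] == -1.0) and np.all(out.gm[-3:] == -1.0)
        assert np.all(out.gm[2:6, 2:6, 2:6] == 0.3)

    def test_trim_refuses_to_remove_brain(self):
        vol = np.full((32, 40, 32), -1.0, np.float32)
        vol[5, 1, 5] = 0.7  # in-brain voxel at plane 1 of axis 1
        pair = TissueVolumePair("s", vol, np.full_like(vol, -1.0))
        with pytest.raises(DataLossError):
            pad_to_cube(pair, 32)

    def test_conserves_in_brain_multiset_on_random_shapes(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            shape = tuple(rng.integers(10, 30, 3))
            vol = _brainy_volume(shape, rng)
            pair = TissueVolumePair("s", vol, vol.copy())
            target = int(rng.integers(max(shape) - 2, max(shape) + 10))
            ref = np.sort(vol[vol != -1.0])
            try:
                out = pad_to_cube(pair, max(8, target))
            except DataLossError:
                continue
            assert np.array_equal(np.sort(out.gm[out.gm != -1.0]), ref)

    def test_sample_tensor_supported(self):
        values = np.full((6, 6, 6, 2), -1.0, np.float32)
        values[2:4, 2:4, 2:4] = 0.5
        sample = make_sample(values)
        out = pad_to_cube(sample, 8)
        assert out.values.shape == (8, 8, 8, 2)
        assert (out.values == 0.5).sum() == 2 * 8


class TestStackChannels:
    def test_constant_channels(self):
        gm = np.full((4, 4, 4), 0.5, np.float32)
        wm = np.full((4, 4, 4), 0.3, np.float32)
        ph = PhenotypeRecord("s", 10.0, 1, 0)
        t = stack_channels(TissueVolumePair("s", gm, wm), ph)
        assert np.all(t.values[..., 0] == 0.5)
        assert np.all(t.values[..., 1] == 0.3)

    def test_round_trip_and_means(self):
        rng = np.random.default_rng(5)
        pair = random_pair(rng)
        ph = PhenotypeRecord(pair.subject_id, 12.0, 0, 1)
        t = stack_channels(pair, ph)
        back = unstack_channels(t)
        assert np.array_equal(back.gm, pair.gm)
        assert np.array_equal(back.wm, pair.wm)
        assert t.values[..., 0].mean() == pytest.approx(pair.gm.mean())
        assert t.values[..., 1].mean() == pytest.approx(pair.wm.mean())


class TestRecords:
    def _samples(self, n, rng):
        return [make_sample(rng.uniform(-1, 1, (5, 6, 7, 2)).astype(np.float32),
                            subject_id=f"s{i}", age=float(rng.uniform(6, 20)),
                            gender=int(rng.integers(2)), diagnosis=int(rng.integers(2)))
                for i in range(n)]

    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(11)
        samples = self._samples(10, rng)
        path = tmp_path / "x.rec"
        assert vio.write_records(samples, path) == 10
        back = vio.read_records(path)
        assert len(back) == 10
        for a, b in zip(samples, back):
            assert np.array_equal(a.values, b.values)
            assert a.phenotype == b.phenotype

    def test_empty_file_is_valid(self, tmp_path):
        path = tmp_path / "empty.rec"
        vio.write_records([], path)
        assert vio.read_records(path) == []

    def test_truncation_names_record_index(self, tmp_path):
        rng = np.random.default_rng(12)
        path = tmp_path / "x.rec"
        vio.write_records(self._samples(3, rng), path)
        data = path.read_bytes()
        (tmp_path / "trunc.rec").write_bytes(data[:-50])
        with pytest.raises(RecordParseError, match="record 2"):
            vio.read_records(tmp_path / "trunc.rec")

    def test_streaming_iteration(self, tmp_path):
        rng = np.random.default_rng(13)
        path = tmp_path / "x.rec"
        vio.write_records(self._samples(4, rng), path)
        it = vio.iter_records(path)
        first = next(it)
        assert first.phenotype.subject_id == "s0"

    def test_not_a_record_file(self, tmp_path):
        path = tmp_path / "junk.rec"
        path.write_bytes(b"NOTMAGIC" + b"\x00" * 20)
        with pytest.raises(RecordParseError):
            vio.read_records(path)


class TestNifti:
    def test_round_trip_data_and_affine(self, tmp_path):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(5, 6, 7)).astype(np.float32)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        vio.write_nifti(data, tmp_path / "v.nii.gz", affine)
        back, aff = vio.read_nifti(tmp_path / "v.nii.gz")
        assert np.allclose(back, data, atol=0)
        assert np.allclose(aff, affine)


class TestPhenotypeRecord:
    def test_rejects_implausible_age(self):
        with pytest.raises(ValueError):
            PhenotypeRecord("s", 40.0, 0, 0)

    def test_csv_round_trip(self, tmp_path):
        phen = [PhenotypeRecord("a", 8.5, 1, 0), PhenotypeRecord("b", 17.0, 0, 1)]
        vio.write_phenotypes_csv(phen, tmp_path / "p.csv")
        assert vio.read_phenotypes_csv(tmp_path / "p.csv") == phen


class TestPadToCubeProperties:
    """Property-based conservation checks."""

    from hypothesis import given, settings, strategies as st

    @given(
        shape=st.tuples(*[st.integers(9, 20)] * 3),
        target=st.integers(8, 24),
        seed=st.integers(0, 2 ** 16),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_conservation_or_explicit_refusal(self, shape, target, seed):
        rng = np.random.default_rng(seed)
        vol = _brainy_volume(shape, rng, margin=2)
        pair = TissueVolumePair("s", vol, vol.copy())
        ref = np.sort(vol[vol != -1.0])
        try:
            out = pad_to_cube(pair, target)
        except DataLossError:
            # refusal is only legal when trimming would really hit the blob
            assert any(s - target > 0 for s in shape)
            return
        assert out.shape == (target,) * 3
        assert np.array_equal(np.sort(out.gm[out.gm != -1.0]), ref)

    @given(seed=st.integers(0, 2 ** 16))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_masking_idempotent_and_partitioning(self, seed):
        rng = np.random.default_rng(seed)
        pair = random_pair(rng)
        mask = rng.random(pair.shape) > 0.4
        once = apply_background_mask(pair, mask)
        twice = apply_background_mask(once, mask)
        assert np.array_equal(once.gm, twice.gm)
        assert np.array_equal(once.wm, twice.wm)
        assert np.all((once.gm == -1.0) | mask)
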