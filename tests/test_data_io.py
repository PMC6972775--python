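"""Readers, splitting and the synthetic image generator."""

import csv

import numpy as np
import pytest

from vcnas import SplitSpec, generate_synthetic, read_idx, subsample_split
from vcnas.data_io import (
    DatasetBundle,
    FormatError,
    load_bundle_npz,
    read_cifar_batches,
    read_patch_folder,
    save_bundle_npz,
    write_idx,
)


@pytest.fixture
def small_bundle():
    return generate_synthetic(2, [3, 3], size=8, channels=1, noise_sd=0.1, seed=3)


class TestIdx:
    def test_round_trip(self, small_bundle, tmp_path):
        ip, lp = tmp_path / "imgs.idx", tmp_path / "lbls.idx"
        write_idx(small_bundle, ip, lp)
        back = read_idx(ip, lp)
        assert back.images.shape == small_bundle.images.shape
        np.testing.assert_allclose(back.images, small_bundle.images, atol=1 / 255)
        np.testing.assert_array_equal(back.labels, small_bundle.labels)

    def test_bad_magic(self, small_bundle, tmp_path):
        ip, lp = tmp_path / "imgs.idx", tmp_path / "lbls.idx"
        write_idx(small_bundle, ip, lp)
        data = bytearray(ip.read_bytes())
        data[3] = 0xFF
        ip.write_bytes(bytes(data))
        with pytest.raises(FormatError, match="magic"):
            read_idx(ip, lp)

    def test_truncated_pixels(self, small_bundle, tmp_path):
        ip, lp = tmp_path / "imgs.idx", tmp_path / "lbls.idx"
        write_idx(small_bundle, ip, lp)
        ip.write_bytes(ip.read_bytes()[:-5])
        with pytest.raises(FormatError, match="truncated"):
            read_idx(ip, lp)

    def test_label_count_mismatch(self, small_bundle, tmp_path):
        ip, lp = tmp_path / "imgs.idx", tmp_path / "lbls.idx"
        write_idx(small_bundle, ip, lp)
        import struct

        labels = small_bundle.labels.astype(np.uint8).tobytes()
        lp.write_bytes(struct.pack(">II", 0x00000801, 2) + labels[:2])
        with pytest.raises(FormatError, match="does not match"):
            read_idx(ip, lp)


class TestCifar:
    def _write_batch(self, path, n=10, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        labels = rng.integers(0, 10, size=n, dtype=np.uint8)
        pixels = rng.integers(0, 256, size=(n, 3072), dtype=np.uint8)
        for lab, pix in zip(labels, pixels):
            rows.append(bytes([lab]) + pix.tobytes())
        path.write_bytes(b"".join(rows))
        return labels, pixels

    def test_reads_planar_rgb(self, tmp_path):
        labels, pixels = self._write_batch(tmp_path / "data_batch_1.bin")
        bundle = read_cifar_batches(tmp_path)
        assert bundle.images.shape == (10, 32, 32, 3)
        np.testing.assert_array_equal(bundle.labels, labels)
        # red plane of image 0 is the first 1024 bytes, row-major
        np.testing.assert_allclose(
            bundle.images[0, :, :, 0].ravel(), pixels[0, :1024] / 255.0
        )

    def test_corrupt_row_length(self, tmp_path):
        self._write_batch(tmp_path / "data_batch_1.bin")
        path = tmp_path / "data_batch_1.bin"
        path.write_bytes(path.read_bytes()[:-7])
        with pytest.raises(FormatError, match="multiple"):
            read_cifar_batches(tmp_path)


class TestPatchFolder:
    def _write_patches(self, tmp_path, entries):
        from PIL import Image

        rng = np.random.default_rng(0)
        manifest = tmp_path / "manifest.csv"
        with open(manifest, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["filename", "label"])
            for name, label in entries:
                arr = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
                fmt = "TIFF" if name.endswith(".tif") else "PNG"
                Image.fromarray(arr).save(tmp_path / name, format=fmt)
                writer.writerow([name, label])
        return manifest

    def test_two_class_imbalanced_folder(self, tmp_path):
        entries = [(f"p{i}.png", "mitosis") for i in range(2)]
        entries += [(f"n{i}.tif", "normal") for i in range(4)]
        manifest = self._write_patches(tmp_path, entries)
        bundle = read_patch_folder(tmp_path, manifest)
        assert len(bundle) == 6 and bundle.image_shape == (16, 16, 3)
        # ids follow sorted label order: mitosis=0, normal=1
        assert np.bincount(bundle.labels).tolist() == [2, 4]

    def test_missing_file_names_the_culprit(self, tmp_path):
        manifest = self._write_patches(tmp_path, [("a.png", "x")])
        with open(manifest, "a", newline="") as fh:
            csv.writer(fh).writerow(["ghost.png", "x"])
        with pytest.raises(FileNotFoundError, match="ghost.png"):
            read_patch_folder(tmp_path, manifest)


class TestSplits:
    @pytest.mark.parametrize(
        "total,spec",
        [
            (1000, (800, 200, 0)),
            (500, (400, 100, 0)),
            (100, (60, 40, 0)),
            (4290, (2500, 800, 990)),
        ],
    )
    def test_study_split_sizes(self, total, spec):
        bundle = DatasetBundle(
            np.zeros((total, 8, 8, 1)), np.zeros(total, dtype=int), 2
        )
        train, val, test = subsample_split(bundle, SplitSpec(*spec, seed=0))
        assert (len(train), len(val), len(test)) == spec

    def test_splits_disjoint_and_deterministic(self, small_bundle):
        spec = SplitSpec(3, 2, 1, seed=9)
        first = subsample_split(small_bundle, spec)
        second = subsample_split(small_bundle, spec)
        for a, b in zip(first, second):
            np.testing.assert_array_equal(a.images, b.images)
        flat = np.concatenate([p.images.reshape(len(p), -1) for p in first])
        assert len(np.unique(flat, axis=0)) == len(flat)

    def test_infeasible_sizes(self, small_bundle):
        with pytest.raises(ValueError):
            subsample_split(small_bundle, SplitSpec(10, 10, 0, seed=0))


class TestSynthetic:
    def test_imbalance_ratio(self):
        bundle = generate_synthetic(2, [20, 40], size=16, channels=3, seed=4)
        assert np.bincount(bundle.labels).tolist() == [20, 40]
        assert bundle.image_shape == (16, 16, 3)

    def test_same_seed_identical(self):
        a = generate_synthetic(3, 5, size=10, noise_sd=0.1, seed=11)
        b = generate_synthetic(3, 5, size=10, noise_sd=0.1, seed=11)
        np.testing.assert_array_equal(a.images, b.images)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_different_seeds_differ(self):
        a = generate_synthetic(3, 5, size=10, noise_sd=0.1, seed=11)
        b = generate_synthetic(3, 5, size=10, noise_sd=0.1, seed=12)
        assert not np.array_equal(a.images, b.images)

    def test_noise_free_classes_are_learnable(self):
        # a minimal conv+output model reaches perfect training accuracy
        from vcnas import (
            EnumerationConfig,
            TensorShape,
            TrainConfig,
            decode_structure,
            train_model,
        )

        bundle = generate_synthetic(3, 30, size=12, channels=1, noise_sd=0.0, seed=2)
        config = EnumerationConfig(TensorShape(12, 12, 1), 3, 1e9)
        model = decode_structure("Conv5 → MP2 → Full", config)
        result = train_model(
            model, bundle, bundle, TrainConfig(batch_size=30, seed=1, max_epochs=50)
        )
        assert result.best_val_error == 0.0

    def test_npz_round_trip(self, small_bundle, tmp_path):
        save_bundle_npz(small_bundle, tmp_path / "b.npz")
        back = load_bundle_npz(tmp_path / "b.npz")
        np.testing.assert_array_equal(back.images, small_bundle.images)
        assert back.provenance == small_bundle.provenance
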