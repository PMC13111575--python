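import numpy as np
import pytest

from mammoprep import (
    BinaryMask,
    CaseRecord,
    GrayImage,
    ManifestError,
    read_image,
    read_manifest,
    read_mask,
    standardize_image,
    write_image,
    write_manifest,
    write_mask,
)


class TestGrayImage:
    def test_rejects_out_of_range_pixels(self):
        with pytest.raises(ValueError, match="outside"):
            GrayImage(np.array([[0, 300]]), levels=256)

    def test_rejects_non_integer(self):
        with pytest.raises(ValueError, match="integer"):
            GrayImage(np.array([[0.5, 1.0]]), levels=256)

    def test_rejects_wrong_ndim(self):
        with pytest.raises(ValueError, match="2-D"):
            GrayImage(np.zeros((2, 2, 3), dtype=int))


class TestBinaryMask:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0, 1"):
            BinaryMask(np.array([[0, 2]]))

    def test_area(self):
        assert BinaryMask(np.eye(4, dtype=int)).area() == 4


class TestImageRoundTrips:
    @pytest.mark.parametrize("suffix,levels,maxval", [
        (".png", 256, 255), (".tif", 256, 255),
        (".png", 65536, 40000), (".tif", 65536, 40000),
    ])
    def test_write_read_identity(self, tmp_path, rng, suffix, levels, maxval):
        pix = rng.integers(0, maxval + 1, size=(9, 7))
        img = GrayImage(pix, levels)
        p = tmp_path / f"img{suffix}"
        write_image(img, p)
        back = read_image(p)
        assert back.levels == levels
        np.testing.assert_array_equal(back.pixels, pix)

    def test_8bit_ramp_preserved(self, tmp_path):
        ramp = np.arange(16).reshape(4, 4)
        p = tmp_path / "ramp.png"
        write_image(GrayImage(ramp), p)
        np.testing.assert_array_equal(read_image(p).pixels, ramp)

    def test_16bit_tiff_levels_inferred(self, tmp_path, rng):
        pix = rng.integers(0, 40001, size=(6, 6))
        pix.flat[0] = 40000
        p = tmp_path / "img.tif"
        write_image(GrayImage(pix, 65536), p)
        # independent reader confirms both content and declared depth
        import tifffile
        ref = tifffile.imread(p)
        assert ref.dtype == np.uint16 and ref.max() == 40000
        img = read_image(p)
        assert img.levels == 65536 and img.pixels.max() == 40000

    def test_missing_file_errors_with_path(self, tmp_path):
        with pytest.raises(IOError, match="nowhere.png"):
            read_image(tmp_path / "nowhere.png")

    def test_multichannel_rejected(self, tmp_path):
        import imageio.v3 as iio
        p = tmp_path / "rgb.png"
        iio.imwrite(p, np.zeros((4, 4, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="grayscale"):
            read_image(p)

    def test_mask_round_trip(self, tmp_path, rng):
        mask = BinaryMask(rng.integers(0, 2, size=(8, 8)))
        p = tmp_path / "m.png"
        write_mask(mask, p)
        np.testing.assert_array_equal(read_mask(p).pixels, mask.pixels)


class TestDicom:
    def test_read_with_rescale(self, tmp_path, rng):
        pydicom = pytest.importorskip("pydicom")
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        pix = rng.integers(0, 1000, size=(8, 8)).astype(np.uint16)
        meta = FileMetaDataset()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.MediaStorageSOPClassUID = generate_uid()
        meta.MediaStorageSOPInstanceUID = generate_uid()
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.Rows, ds.Columns = 8, 8
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = 2.0
        ds.RescaleIntercept = 10.0
        ds.PixelData = pix.tobytes()
        p = tmp_path / "img.dcm"
        ds.save_as(p, enforce_file_format=True)

        img = read_image(p)
        assert img.levels == 65536
        np.testing.assert_array_equal(img.pixels, pix.astype(np.int64) * 2 + 10)


class TestStandardize:
    def test_identity_at_target_size(self, rng):
        img = GrayImage(rng.integers(0, 256, size=(64, 64)))
        out = standardize_image(img, side=64)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_resizes_to_square(self, rng):
        img = GrayImage(rng.integers(0, 256, size=(60, 80)))
        out = standardize_image(img, side=128)
        assert out.shape == (128, 128)

    def test_constant_stays_constant(self):
        img = GrayImage(np.full((30, 40), 77, dtype=int))
        out = standardize_image(img, side=64)
        # content region stays 77; padding adds 0s and a thin blended margin
        assert out.pixels.min() >= 0 and out.pixels.max() == 77
        plateau = ((out.pixels == 77) | (out.pixels == 0)).sum()
        assert plateau > 0.9 * out.pixels.size
        assert (out.pixels == 77).sum() > 0.5 * out.pixels.size

    def test_constant_square_stays_constant_everywhere(self):
        img = GrayImage(np.full((30, 30), 77, dtype=int))
        out = standardize_image(img, side=64)
        assert (out.pixels == 77).all()

    def test_idempotent(self, rng):
        img = GrayImage(rng.integers(0, 256, size=(50, 70)))
        once = standardize_image(img, side=96)
        twice = standardize_image(once, side=96)
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_rejects_tiny_side(self, rng):
        img = GrayImage(rng.integers(0, 256, size=(8, 8)))
        with pytest.raises(ValueError):
            standardize_image(img, side=1)


MANIFEST_HEADER = "case_id,laterality,view,label,image_path\n"


class TestManifest:
    def test_well_formed(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(MANIFEST_HEADER
                     + "c1,L,CC,benign,a.png\n"
                     + "c1,L,MLO,benign,b.png\n"
                     + "c2,R,CC,malignant,c.png\n")
        records = read_manifest(p)
        assert len(records) == 3
        assert records[2].label == "malignant"

    def test_header_only_is_empty(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(MANIFEST_HEADER)
        assert read_manifest(p) == []

    def test_label_conflict_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(MANIFEST_HEADER
                     + "c1,L,CC,benign,a.png\n"
                     + "c1,L,MLO,malignant,b.png\n")
        with pytest.raises(ManifestError, match="c1"):
            read_manifest(p)

    def test_all_violations_reported(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(MANIFEST_HEADER
                     + "c1,L,CC,benign,a.png\n"
                     + "c1,L,CC,benign,a.png\n"      # duplicate key
                     + "c2,L,CC,benign,b.png\n"
                     + "c2,L,MLO,malignant,c.png\n"  # label conflict
                     + "c3,X,CC,benign,d.png\n")     # bad laterality
        with pytest.raises(ManifestError) as err:
            read_manifest(p)
        assert len(err.value.violations) == 3

    def test_round_trip(self, tmp_path):
        cases = [
            CaseRecord("c1", "L", "CC", "benign", image_ref="a.png", split="train"),
            CaseRecord("c1", "L", "MLO", "benign", image_ref="b.png", split="train"),
        ]
        p = tmp_path / "m.csv"
        write_manifest(cases, p)
        back = read_manifest(p)
        assert [(c.case_id, c.view, c.split) for c in back] == [
            ("c1", "CC", "train"), ("c1", "MLO", "train")]
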