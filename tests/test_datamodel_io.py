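import numpy as np
import pytest
from PIL import Image

from nsseg.datamodel import (
    BinaryMask,
    DatasetManifest,
    DuplicateIdError,
    ImageLoadError,
    ManifestNotFoundError,
    MalformedRowError,
    MaskConsistencyError,
    SampleRecord,
    load_mask_file,
    load_sample,
    nearest_resize,
    read_manifest,
    save_mask,
    write_manifest,
)


def _record(tmp_path, sid, provenance="real", split="train", with_mask=True):
    return SampleRecord(
        id=sid,
        image_path=tmp_path / f"{sid}.png",
        mask_path=(tmp_path / f"{sid}_m.png") if with_mask else None,
        provenance=provenance,
        split=split,
    )


class TestManifestRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        manifest = DatasetManifest(
            records=[
                _record(tmp_path, "a"),
                _record(tmp_path, "b", provenance="pseudo", split="val"),
                _record(tmp_path, "c", provenance="unlabeled", with_mask=False),
            ]
        )
        path = tmp_path / "m.csv"
        write_manifest(manifest, path)
        back = read_manifest(path)
        assert back.records == manifest.records
        assert [r.id for r in back] == ["a", "b", "c"]

    def test_write_is_byte_stable(self, tmp_path):
        manifest = DatasetManifest(records=[_record(tmp_path, "x")])
        p1, p2 = tmp_path / "1.csv", tmp_path / "2.csv"
        write_manifest(manifest, p1)
        write_manifest(manifest, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_manifest_is_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_manifest(DatasetManifest(records=[]), path)
        assert path.read_text() == "id,image_path,mask_path,provenance,split\n"
        assert len(read_manifest(path)) == 0


class TestManifestValidation:
    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(ManifestNotFoundError):
            read_manifest(tmp_path / "nope.csv")

    def test_bad_header_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,path\nx,y\n")
        with pytest.raises(MalformedRowError):
            read_manifest(path)

    def test_duplicate_id_raises(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "id,image_path,mask_path,provenance,split\n"
            "a,a.png,a_m.png,real,train\n"
            "a,b.png,b_m.png,real,train\n"
        )
        with pytest.raises(DuplicateIdError):
            read_manifest(path)

    def test_unlabeled_with_mask_raises(self, tmp_path):
        path = tmp_path / "inc.csv"
        path.write_text(
            "id,image_path,mask_path,provenance,split\n"
            "a,a.png,a_m.png,unlabeled,train\n"
        )
        with pytest.raises(MaskConsistencyError):
            read_manifest(path)

    def test_real_without_mask_raises(self, tmp_path):
        with pytest.raises(MaskConsistencyError):
            SampleRecord(
                id="a", image_path=tmp_path / "a.png", mask_path=None,
                provenance="real", split="train",
            )

    def test_relative_paths_resolve_against_manifest_dir(self, tmp_path):
        path = tmp_path / "rel.csv"
        path.write_text(
            "id,image_path,mask_path,provenance,split\n"
            "a,images/a.png,,unlabeled,train\n"
        )
        rec = read_manifest(path).records[0]
        assert rec.image_path == tmp_path / "images/a.png"


class TestImageLoading:
    def test_binary_png_scales_to_exact_endpoints(self, tmp_path):
        arr = np.zeros((16, 16, 3), dtype=np.uint8)
        arr[:8] = 255
        img_path = tmp_path / "img.png"
        Image.fromarray(arr).save(img_path)
        mask_path = tmp_path / "mask.png"
        Image.fromarray(np.full((16, 16), 255, np.uint8), "L").save(mask_path)
        rec = SampleRecord(
            id="a", image_path=img_path, mask_path=mask_path,
            provenance="real", split="train",
        )
        image, mask = load_sample(rec, target_size=16)
        assert set(np.unique(image)) <= {0.0, 1.0}
        assert mask.values.shape == (16, 16)

    def test_full_mask_of_any_size_stays_full(self, tmp_path):
        mask_path = tmp_path / "m.png"
        Image.fromarray(np.full((37, 37), 255, np.uint8), "L").save(mask_path)
        mask = load_mask_file(mask_path, target_size=16)
        assert mask.values.shape == (16, 16)
        assert (mask.values == 1).all()
        assert mask.foreground_count == 256

    def test_checkerboard_downsample_matches_index_map_oracle(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        small = nearest_resize(board.astype(np.uint8), 4)
        # independent oracle: output pixel i samples index floor((i+0.5)*in/out)
        idx = [int(np.floor((i + 0.5) * 8 / 4)) for i in range(4)]
        expected = board[np.ix_(idx, idx)]
        assert np.array_equal(small, expected)

    def test_antialiased_mask_binarizes_above_127(self, tmp_path):
        raw = np.array([[0, 100], [127, 128]], dtype=np.uint8)
        path = tmp_path / "gray.png"
        Image.fromarray(np.kron(raw, np.ones((8, 8), np.uint8)), "L").save(path)
        mask = load_mask_file(path, target_size=16)
        assert np.array_equal(np.unique(mask.values), [0, 1])
        assert mask.values[:8, :8].sum() == 0 and mask.values[8:, 8:].min() == 1

    def test_unreadable_image_raises(self, tmp_path):
        bad = tmp_path / "bad.png"
        bad.write_bytes(b"not a png")
        with pytest.raises(ImageLoadError):
            load_mask_file(bad, 16)

    def test_mask_size_mismatch_warns(self, tmp_path, caplog):
        Image.fromarray(np.zeros((16, 16, 3), np.uint8)).save(tmp_path / "i.png")
        Image.fromarray(np.full((8, 8), 255, np.uint8), "L").save(tmp_path / "m.png")
        rec = SampleRecord(
            id="a", image_path=tmp_path / "i.png", mask_path=tmp_path / "m.png",
            provenance="real", split="train",
        )
        with caplog.at_level("WARNING", logger="nsseg"):
            _, mask = load_sample(rec, 16)
        assert mask.values.shape == (16, 16)
        assert any("mask size" in r.message for r in caplog.records)


class TestMaskSaving:
    def test_zero_mask_saves_as_all_black(self, tmp_path):
        path = tmp_path / "z.png"
        save_mask(np.zeros((8, 8), np.uint8), path)
        assert np.asarray(Image.open(path)).max() == 0

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        mask = (rng.random((32, 32)) > 0.5).astype(np.uint8)
        path = tmp_path / "m.png"
        save_mask(mask, path)
        back = load_mask_file(path, 32)
        assert np.array_equal(back.values, mask)

    def test_save_is_byte_deterministic(self, tmp_path):
        mask = BinaryMask(np.eye(8, dtype=np.uint8))
        p1, p2 = tmp_path / "1.png", tmp_path / "2.png"
        save_mask(mask, p1)
        save_mask(mask, p2)
        assert p1.read_bytes() == p2.read_bytes()


def test_binary_mask_rejects_non_binary_values():
    with pytest.raises(ValueError):
        BinaryMask(np.array([[0, 2]], dtype=np.uint8))
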