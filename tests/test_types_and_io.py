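"""Domain-type invariants and file-format round trips."""

import json

import numpy as np
import pytest
import tifffile
from imageio import v3 as iio

from spinetrack import (
    AnnotationSet,
    Box2D,
    Detection2D,
    ImageStack,
    PipelineConfig,
    SpineTrack3D,
    io,
)


class TestBox2D:
    def test_properties(self):
        b = Box2D(2, 3, 7, 5)
        assert (b.width, b.height, b.area) == (5, 2, 10)
        assert b.center == (4.5, 4.0)

    @pytest.mark.parametrize(
        "coords",
        [(5, 5, 5, 10), (5, 5, 10, 5), (-1, 0, 5, 5), (0, 0, float("nan"), 5)],
    )
    def test_invalid_boxes_rejected(self, coords):
        with pytest.raises(ValueError):
            Box2D(*coords)

    def test_from_xywh(self):
        assert Box2D.from_xywh(10, 20, 30, 15) == Box2D(10, 20, 40, 35)


class TestDetection2D:
    def test_confidence_bounds(self):
        with pytest.raises(ValueError):
            Detection2D(box=Box2D(0, 0, 1, 1), slice_index=0, confidence=1.2)

    def test_negative_slice_rejected(self):
        with pytest.raises(ValueError):
            Detection2D(box=Box2D(0, 0, 1, 1), slice_index=-1, confidence=0.5)


class TestSpineTrack3D:
    def test_coverage_enforced(self):
        with pytest.raises(ValueError):
            SpineTrack3D(
                spine_id=0, z_first=0, z_second=2,
                boxes_by_slice={0: Box2D(0, 0, 1, 1), 2: Box2D(0, 0, 1, 1)},
                mean_box=Box2D(0, 0, 1, 1),
            )

    def test_from_boxes_computes_mean(self):
        t = SpineTrack3D.from_boxes(
            0, {3: Box2D(0, 0, 10, 10), 4: Box2D(2, 2, 12, 12)}
        )
        assert t.z_interval == (3, 4)
        assert t.mean_box == Box2D(1, 1, 11, 11)


class TestStackIO:
    def test_multipage_tiff_roundtrip(self, tmp_path):
        arr = np.random.default_rng(0).integers(0, 256, size=(10, 32, 32)).astype(np.uint8)
        path = tmp_path / "stack.tif"
        tifffile.imwrite(path, arr)
        stack = io.read_stack(path)
        assert stack.depth == 10 and stack.shape == (32, 32)
        assert np.array_equal(stack.as_array(), arr)

    def test_directory_read_in_name_order(self, tmp_path):
        for i in (2, 0, 1):  # written out of order on purpose
            img = np.full((16, 16), i * 10, dtype=np.uint8)
            iio.imwrite(tmp_path / f"s{i:03d}.png", img)
        stack = io.read_stack(tmp_path)
        assert [s[0, 0] for s in stack.slices] == [0, 10, 20]

    def test_inconsistent_shapes_rejected(self, tmp_path):
        iio.imwrite(tmp_path / "a0.png", np.zeros((16, 16), dtype=np.uint8))
        iio.imwrite(tmp_path / "a1.png", np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            io.read_stack(tmp_path)

    def test_missing_path(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            io.read_stack(tmp_path / "nope.tif")

    def test_clip_intensity(self):
        stack = ImageStack(slices=[np.array([[0.0, 100.0, 255.0, 400.0]])])
        clipped = io.clip_intensity(stack, 255)
        assert clipped.slices[0].tolist() == [[0.0, 100.0, 255.0, 255.0]]
        twice = io.clip_intensity(clipped, 255)  # idempotent
        assert np.array_equal(twice.slices[0], clipped.slices[0])
        zero = io.clip_intensity(ImageStack(slices=[np.zeros((2, 2))]), 255)
        assert not zero.slices[0].any()


class TestViaAnnotations:
    def doc(self, regions, fname="img_0004.png"):
        return {
            "_via_img_metadata": {
                f"{fname}-1": {
                    "filename": fname,
                    "size": -1,
                    "regions": regions,
                    "file_attributes": {},
                }
            }
        }

    def test_rect_region_coordinates(self):
        doc = self.doc(
            [{"shape_attributes": {"name": "rect", "x": 10, "y": 20, "width": 30, "height": 15},
              "region_attributes": {}}]
        )
        ann = io.read_via_annotations(doc)
        assert ann.boxes == [(4, Box2D(10, 20, 40, 35))]

    def test_empty_project(self):
        ann = io.read_via_annotations(self.doc([]))
        assert ann.boxes == []

    def test_polygon_skipped_and_counted(self, caplog):
        doc = self.doc(
            [
                {"shape_attributes": {"name": "polygon", "all_points_x": [0], "all_points_y": [0]},
                 "region_attributes": {}},
                {"shape_attributes": {"name": "rect", "x": 1, "y": 1, "width": 2, "height": 2},
                 "region_attributes": {}},
            ]
        )
        with caplog.at_level("WARNING"):
            ann = io.read_via_annotations(doc)
        assert len(ann.boxes) == 1 and ann.skipped_regions == 1

    def test_export_reimport_roundtrip(self, tmp_path):
        ann = AnnotationSet(
            annotator_id="a",
            boxes=[(0, Box2D(1.5, 2.5, 10.25, 12.0)), (3, Box2D(5, 5, 9, 9))],
        )
        path = tmp_path / "via.json"
        io.write_via_annotations(ann, path)
        back = io.read_via_annotations(json.loads(path.read_text()))
        assert sorted((z, b.as_tuple()) for z, b in back.boxes) == sorted(
            (z, b.as_tuple()) for z, b in ann.boxes
        )

    def test_slice_index_from_filename(self):
        assert io.slice_index_from_filename("stack1_s007.png") == 7
        with pytest.raises(ValueError):
            io.slice_index_from_filename("no_digits.png")


class TestDetectionCsv:
    def test_roundtrip_lossless(self, tmp_path):
        dets = [
            Detection2D(box=Box2D(1.123456, 2.5, 10.654321, 12.0), slice_index=3, confidence=0.875),
            Detection2D(box=Box2D(0, 0, 5, 5), slice_index=0, confidence=0.5),
            Detection2D(box=Box2D(7, 7, 9, 9), slice_index=0, confidence=0.9),
        ]
        path = tmp_path / "dets.csv"
        io.write_detections_csv(dets, path)
        back = io.read_detections_csv(path)
        # sorted by (slice, confidence desc) on write
        assert [d.slice_index for d in back] == [0, 0, 3]
        assert back[0].confidence == 0.9
        orig = sorted((d.slice_index, d.box.as_tuple(), d.confidence) for d in dets)
        got = sorted((d.slice_index, d.box.as_tuple(), d.confidence) for d in back)
        for (s1, b1, c1), (s2, b2, c2) in zip(orig, got):
            assert s1 == s2 and c1 == pytest.approx(c2, abs=1e-6)
            assert all(x == pytest.approx(y, abs=1e-6) for x, y in zip(b1, b2))

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("slice,x_min,y_min,x_max,y_max\n0,0,0,5,5\n")
        with pytest.raises(ValueError, match="missing columns"):
            io.read_detections_csv(path)

    def test_out_of_range_confidence(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("slice,x_min,y_min,x_max,y_max,confidence\n0,0,0,5,5,1.2\n")
        with pytest.raises(ValueError):
            io.read_detections_csv(path)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("slice,x_min,y_min,x_max,y_max,confidence\n")
        assert io.read_detections_csv(path) == []


class TestTrackCsv:
    def test_roundtrip(self, tmp_path):
        tracks = [
            SpineTrack3D.from_boxes(
                0, {2: Box2D(1, 1, 9, 9), 3: Box2D(2, 2, 10, 10)}, confidence=0.8,
                interpolated_slices=frozenset({3}),
            ),
            SpineTrack3D.from_boxes(1, {0: Box2D(50, 50, 60, 60)}, confidence=0.9),
        ]
        path = tmp_path / "tracks.csv"
        io.write_tracks_csv(tracks, path)
        back = io.read_tracks_csv(path)
        assert [(t.spine_id, t.z_interval) for t in back] == [(0, (2, 3)), (1, (0, 0))]
        assert back[0].interpolated_slices == frozenset({3})
        assert back[0].mean_box.as_tuple() == pytest.approx(tracks[0].mean_box.as_tuple())


class TestPipelineConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            PipelineConfig(confidence_threshold=1.5)
        with pytest.raises(ValueError):
            PipelineConfig(max_consecutive_misses=-1)

    def test_json_and_yaml_files(self, tmp_path):
        cfg = PipelineConfig(confidence_threshold=0.7, matching_mode="one_to_one")
        jpath = tmp_path / "cfg.json"
        jpath.write_text(json.dumps(cfg.to_dict()))
        assert PipelineConfig.from_file(jpath) == cfg
        import yaml

        ypath = tmp_path / "cfg.yaml"
        ypath.write_text(yaml.safe_dump(cfg.to_dict()))
        assert PipelineConfig.from_file(ypath) == cfg
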