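"""Round-trips and structural checks for every reader/writer pair."""

import json

import numpy as np
import pandas as pd
import pytest

from ieegloc.core import Contact, Electrode, VolumeImage
from ieegloc.ela import ContactProbabilities
from ieegloc.formats_io import (
    FormatError,
    read_contacts,
    read_label_table,
    read_stl,
    read_surface,
    read_volume,
    write_bids_electrodes,
    write_contacts,
    write_label_table,
    write_probability_table,
    write_stl,
    write_surface,
    write_volume,
)
from ieegloc.synthetic import make_head


class TestVolumeIO:
    def test_roundtrip_grid_and_affine(self, tmp_path, rng):
        grid = rng.integers(0, 9, (16, 16, 16)).astype(np.int32)
        affine = np.diag([1.0, 1.2, 0.9, 1.0])
        affine[:3, 3] = (-8, -9, -7)
        vol = VolumeImage(grid, affine)
        path = tmp_path / "vol.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        assert np.array_equal(back.grid, grid)
        assert np.allclose(back.affine, affine, atol=1e-6)

    def test_truncated_file_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.nii"
        path.write_bytes(b"\x00" * 64)
        with pytest.raises(FormatError, match="bad.nii"):
            read_volume(path)


class TestSurfaceIO:
    def test_roundtrip_counts_and_vertices(self, tmp_path):
        import trimesh

        ico = trimesh.creation.icosphere(subdivisions=3, radius=40.0)
        from ieegloc.core import SurfaceMesh

        mesh = SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        path = tmp_path / "lh.pial"
        write_surface(mesh, path)
        back = read_surface(path)
        assert back.n_vertices == mesh.n_vertices
        assert back.n_faces == mesh.n_faces
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-4)

    def test_companion_volume_restores_scanner_frame(self, tmp_path):
        head = make_head(R_pial=20, R_white=16, n_wedges=2, subcortical=(),
                         mesh_subdivisions=2)
        path = tmp_path / "lh.pial"
        write_surface(head.pial, path, companion_volume=head.parcellation)
        back = read_surface(path, companion_volume=head.parcellation)
        assert back.frame == "scanner_ras"
        assert np.allclose(back.vertices, head.pial.vertices, atol=1e-4)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "broken.surf"
        path.write_bytes(b"")
        with pytest.raises(FormatError):
            read_surface(path)


class TestLabelTable:
    def test_canonical_names_get_categories(self, tmp_path):
        path = tmp_path / "lut.txt"
        path.write_text(
            "# comment line\n"
            "0 Unknown 0 0 0 0\n"
            "17 Left-Hippocampus 220 216 20 0\n"
            "1001 ctx-lh-bankssts 25 100 40 0\n"
            "2 Left-Cerebral-White-Matter 245 245 245 0\n"
            "4 Left-Lateral-Ventricle 120 18 134 0\n"
        )
        lut = read_label_table(path)
        assert lut.category(17) == "subcortical_grey"
        assert lut.category(1001) == "cortical_grey"
        assert lut.category(2) == "white"
        assert lut.category(4) == "csf"
        assert lut.category(0) == "background"

    def test_id_range_rule_for_unknown_name(self, tmp_path):
        path = tmp_path / "lut.txt"
        path.write_text("0 Unknown 0 0 0 0\n1500 some-new-area 1 2 3 0\n")
        lut = read_label_table(path)
        assert lut.category(1500) == "cortical_grey"

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "lut.txt"
        path.write_text("17 Left-Hippocampus 0 0 0 0\n17 Right-Hippocampus 0 0 0 0\n")
        with pytest.raises(FormatError, match="17"):
            read_label_table(path)

    def test_roundtrip(self, tmp_path, head):
        path = tmp_path / "lut.txt"
        write_label_table(head.labels, path)
        back = read_label_table(path)
        assert len(back) == len(head.labels)
        for e in head.labels:
            assert back.category(e.id) == e.category
            assert back.name(e.id) == e.name


class TestContactIO:
    def test_single_electrode_order_preserved(self, tmp_path):
        path = tmp_path / "picks.csv"
        lines = ["electrode,contact,x,y,z"]
        for i in range(8):
            lines.append(f"RA,{i + 1},{i * 5.0},1.0,2.0")
        path.write_text("\n".join(lines))
        (e,) = read_contacts(path)
        assert e.name == "RA" and len(e) == 8
        assert [c.label for c in e.contacts] == [str(i + 1) for i in range(8)]

    def test_interleaved_electrodes_grouped_in_file_order(self, tmp_path):
        path = tmp_path / "picks.csv"
        rows = [("A", "1"), ("B", "1"), ("A", "2"), ("B", "2"), ("A", "3")]
        lines = ["electrode,contact,x,y,z"] + [
            f"{e},{c},{i}.0,0.0,0.0" for i, (e, c) in enumerate(rows)
        ]
        path.write_text("\n".join(lines))
        electrodes = {e.name: e for e in read_contacts(path)}
        assert [c.label for c in electrodes["A"].contacts] == ["1", "2", "3"]
        assert [c.label for c in electrodes["B"].contacts] == ["1", "2"]
        # within-electrode order follows the file, not sorting
        assert np.allclose(electrodes["A"].positions[:, 0], [0, 2, 4])

    def test_non_numeric_coordinate_reports_line(self, tmp_path):
        path = tmp_path / "picks.csv"
        path.write_text("electrode,contact,x,y,z\nRA,3,1.0,foo,2.0\n")
        with pytest.raises(FormatError, match=":2"):
            read_contacts(path)

    def test_tab_delimited_and_roundtrip(self, tmp_path, rng):
        electrodes = [
            Electrode("G", [Contact(str(i), rng.uniform(-50, 50, 3), 2.3) for i in range(4)]),
            Electrode("RA", [Contact(str(i), rng.uniform(-50, 50, 3)) for i in range(3)]),
        ]
        path = tmp_path / "picks.csv"
        write_contacts(electrodes, path)
        back = read_contacts(path)
        assert [e.name for e in back] == ["G", "RA"]
        assert np.allclose(back[0].positions, electrodes[0].positions, atol=1e-6)
        assert back[0].contacts[0].size_mm == pytest.approx(2.3)
        assert back[1].contacts[0].size_mm is None


class TestStl:
    def test_roundtrip_counts_and_vertices(self, tmp_path, small_head):
        path = tmp_path / "pial.stl"
        write_stl(small_head.pial, path)
        back = read_stl(path)
        assert back.n_faces == small_head.pial.n_faces
        # STL stores vertices per-triangle; compare triangle soup geometry
        orig = np.sort(small_head.pial.vertices[small_head.pial.faces].reshape(-1, 3), axis=0)
        got = np.sort(back.vertices[back.faces].reshape(-1, 3), axis=0)
        assert np.allclose(orig, got, atol=1e-4)

    def test_empty_mesh_rejected(self):
        from ieegloc.core import SurfaceMesh

        empty = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            write_stl(empty, "/tmp/never.stl")


class TestProbabilityTable:
    def _records(self):
        return [
            ContactProbabilities("RA", "1", {1: 0.6, 100: 0.4}, 1, 0.6, multi_region=True),
            ContactProbabilities("RA", "2", {2: 0.25, 3: 0.5, 100: 0.25}, 3, 0.5,
                                 multi_region=True),
        ]

    def test_shape_and_row_sums(self, tmp_path, head):
        path = tmp_path / "probs.csv"
        write_probability_table(self._records(), head.labels, path)
        df = pd.read_csv(path)
        assert len(df) == 2
        label_cols = ["ctx-wedge-01", "ctx-wedge-02", "ctx-wedge-03", "Cerebral-White-Matter"]
        assert set(label_cols) <= set(df.columns)
        assert "assigned_region" in df.columns and "max_grey_probability" in df.columns
        sums = df[label_cols].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_empty_records_rejected(self, tmp_path, head):
        with pytest.raises(ValueError, match="no probability records"):
            write_probability_table([], head.labels, tmp_path / "x.csv")


class TestBidsElectrodes:
    def _electrodes(self, rng):
        return [
            Electrode(
                "RA",
                [Contact(str(i + 1), rng.uniform(-40, 40, 3), 2.4 if i else None)
                 for i in range(8)],
            )
        ]

    def test_structure_and_roundtrip(self, tmp_path, rng):
        electrodes = self._electrodes(rng)
        cls = {("RA", "1"): ("white", "Cerebral-White-Matter")}
        meas = {("RA", "1"): {"dist_pial": 4.25}}
        tsv, js = write_bids_electrodes(
            electrodes, cls, meas, tmp_path, coordinate_frame_name="ScannerRAS"
        )
        lines = tsv.read_text(encoding="utf-8").splitlines()
        header = lines[0].split("\t")
        assert header[:5] == ["name", "x", "y", "z", "size"]
        assert len(lines) == 1 + 8
        ncols = len(header)
        for line in lines:
            assert len(line.split("\t")) == ncols
            assert line == line.rstrip()
        df = pd.read_csv(tsv, sep="\t", keep_default_na=False)
        assert np.allclose(
            df[["x", "y", "z"]].to_numpy(dtype=float), electrodes[0].positions, atol=1e-6
        )
        # contact without a known size gets the BIDS "n/a"
        assert df.loc[0, "size"] == "n/a"
        meta = json.loads(js.read_text())
        assert meta["iEEGCoordinateSystem"] == "ScannerRAS"
        assert meta["iEEGCoordinateUnits"] == "mm"
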