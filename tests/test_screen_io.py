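"""Export parsing, replicate pooling, store and text-export round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import perturbscreen as ps
from perturbscreen.errors import (
    ExportFormatError,
    HeaderError,
    LabelParseError,
    ReplicateError,
    StoreError,
)
from perturbscreen.screen_io import (
    ChemicalDose,
    ConditionDescriptor,
    RawScreen,
    write_export,
)


class TestDetectHeader:
    def test_header_after_comment_lines(self):
        lines = ["# run", "# device", "# exported", "Date Time\tElapsed\tA, 1, nM, L, 10k"]
        idx, delim = ps.detect_header(lines)
        assert idx == 3 and delim == "\t"

    def test_header_at_first_line(self):
        idx, _ = ps.detect_header(["Date Time\tElapsed\tX, 1, nM, L, 1k"])
        assert idx == 0

    def test_comma_dialect_with_quoted_cells(self):
        idx, delim = ps.detect_header(['Date Time,Elapsed,"A, 1, nM, L, 10k"'])
        assert idx == 0 and delim == ","

    def test_missing_tokens_raises(self):
        with pytest.raises(HeaderError, match="Date Time"):
            ps.detect_header(["Time\tElapsed\tA"])


class TestConditionLabels:
    def test_single_drug_label(self):
        d = ps.parse_condition_label("MK-1775, 45.7, nM, MCF-7, 10k")
        assert d.agents == (ChemicalDose("MK-1775", 45.7, "nM"),)
        assert d.cell_line == "MCF-7" and d.seeding == "10k"
        assert not d.genetic

    def test_vehicle_label_parses_and_is_flagged_later(self):
        d = ps.parse_condition_label("DMSO, 0.34, %, MCF-7, 10k")
        assert d.agents[0].concentration == 0.34
        assert not d.is_control  # flagging happens in layout.identify_controls
        idx = ps.identify_controls([d])
        assert idx == [0]

    def test_comma_decimal_separator_rejected(self):
        with pytest.raises(LabelParseError):
            ps.parse_condition_label("MK-1775, 45,7, nM, MCF-7, 10k")

    def test_genetic_chemical_label(self):
        d = ps.parse_condition_label("SOX11 OE, celastrol, 576.0, nM, SH-EP, 3k")
        assert d.genetic == ("SOX11 OE",)
        assert d.agents == (ChemicalDose("celastrol", 576.0, "nM"),)

    @pytest.mark.parametrize(
        "bad",
        ["", "OnlyOneField, x", "A, -5, nM, L, 1k", "A, nan, nM, L, 1k"],
    )
    def test_malformed_labels_raise(self, bad):
        with pytest.raises(LabelParseError):
            ps.parse_condition_label(bad)

    names = st.text(
        alphabet=st.characters(
            whitelist_categories=("Lu", "Ll", "Nd"), whitelist_characters="-_ "
        ),
        min_size=1,
        max_size=12,
    ).map(str.strip).filter(lambda s: s and not _numeric(s))

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_format_parse_identity(self, data):
        """parse(format(d)) == d for randomized descriptors."""
        n_agents = data.draw(st.integers(0, 3))
        n_gen = data.draw(st.integers(0 if n_agents else 1, 2))
        agents = tuple(
            ChemicalDose(
                data.draw(self.names),
                data.draw(
                    st.floats(0, 1e6, allow_nan=False, allow_infinity=False)
                ),
                data.draw(st.sampled_from(["nM", "uM", "%", "mg/ml"])),
            )
            for _ in range(n_agents)
        )
        genetic = tuple(data.draw(self.names) for _ in range(n_gen))
        d = ConditionDescriptor(
            agents=agents,
            genetic=genetic,
            cell_line=data.draw(self.names),
            seeding=data.draw(self.names),
        )
        assert ps.parse_condition_label(ps.format_condition_label(d)) == d


def _numeric(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


class TestReadExport:
    def test_fixture_counts(self, fixtures):
        path, _ = fixtures["combination"]
        screen = ps.read_export(path)
        assert screen.n_conditions == 136
        assert screen.n_times == 37
        assert screen.n_measurements == 5032

    def test_endpoint_single_row(self, fixtures):
        path, _ = fixtures["endpoint_drug"]
        screen = ps.read_export(path)
        assert screen.is_endpoint and screen.n_times == 1

    def test_write_read_round_trip(self, fixtures, tmp_path):
        path, _ = fixtures["genetic"]
        screen = ps.read_export(path)
        out = tmp_path / "rt.txt"
        write_export(screen, out)
        again = ps.read_export(out)
        np.testing.assert_array_equal(screen.elapsed, again.elapsed)
        np.testing.assert_array_equal(screen.measurements, again.measurements)
        assert screen.labels == again.labels

    def _write(self, tmp_path, rows):
        p = tmp_path / "bad.txt"
        p.write_text("\n".join(rows) + "\n")
        return p

    def test_ragged_row_error_carries_row(self, tmp_path):
        p = self._write(
            tmp_path,
            ["Date Time\tElapsed\tA, 1, nM, L, 1k", "d\t0\t5", "d\t2"],
        )
        with pytest.raises(ExportFormatError, match="row 2"):
            ps.read_export(p)

    def test_duplicate_elapsed_rejected(self, tmp_path):
        p = self._write(
            tmp_path,
            ["Date Time\tElapsed\tA, 1, nM, L, 1k", "d\t0\t5", "d\t0\t6"],
        )
        with pytest.raises(ExportFormatError, match="strictly increasing"):
            ps.read_export(p)

    def test_non_numeric_cell_has_coordinates(self, tmp_path):
        p = self._write(
            tmp_path,
            ["Date Time\tElapsed\tA, 1, nM, L, 1k", "d\t0\toops"],
        )
        with pytest.raises(ExportFormatError, match="column 2"):
            ps.read_export(p)

    def test_empty_cell_becomes_nan(self, tmp_path):
        p = self._write(
            tmp_path,
            [
                "Date Time\tElapsed\tA, 1, nM, L, 1k\tB, 2, nM, L, 1k",
                "d\t0\t\t5",
                "d\t2\t4\t6",
            ],
        )
        screen = ps.read_export(p)
        assert np.isnan(screen.measurements[0, 0])
        assert screen.measurements[1, 0] == 4


class TestMergeReplicates:
    def _screen(self, values, label="A, 1, nM, L, 1k"):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        descs = [ps.parse_condition_label(label) for _ in range(values.shape[1])]
        return RawScreen(
            elapsed=np.arange(values.shape[0], dtype=float),
            measurements=values,
            descriptors=descs,
        )

    def test_identical_replicates_mean_and_zero_sd(self):
        merged = ps.merge_replicates([self._screen([[40.0, 40.0]])])
        assert merged.measurements[0, 0] == 40
        assert merged.sd[0, 0] == 0

    def test_two_point_mean_and_sample_sd(self):
        merged = ps.merge_replicates([self._screen([[40.0, 60.0]])])
        assert merged.measurements[0, 0] == 50
        assert merged.sd[0, 0] == pytest.approx(np.std([40, 60], ddof=1))

    def test_ci_matches_t_interval_oracle(self, rng):
        k = 6
        vals = rng.uniform(10, 100, size=(4, k))
        screens = [self._screen(vals[:, [j]]) for j in range(k)]
        merged = ps.merge_replicates(screens)
        # independent recomputation of the Student-t 95% CI half-width
        for t in range(4):
            sd = np.std(vals[t], ddof=1)
            expect = stats.t.ppf(0.975, k - 1) * sd / np.sqrt(k)
            assert merged.ci95[t, 0] == pytest.approx(expect, rel=1e-12)

    def test_permutation_invariant(self, rng):
        vals = rng.uniform(10, 100, size=(3, 4))
        screens = [self._screen(vals[:, [j]]) for j in range(4)]
        a = ps.merge_replicates(screens)
        b = ps.merge_replicates(screens[::-1])
        np.testing.assert_allclose(a.measurements, b.measurements)
        np.testing.assert_allclose(a.sd, b.sd)

    def test_mismatched_grids_rejected(self):
        s1 = self._screen([[1.0], [2.0]])
        s2 = self._screen([[1.0], [2.0]])
        s2.elapsed = np.array([0.0, 5.0])
        with pytest.raises(ReplicateError):
            ps.merge_replicates([s1, s2])


class TestStore:
    def test_round_trip_two_branch_screen(self, fixtures, tmp_path):
        path, _ = fixtures["genetic_chemical"]
        screen = ps.read_export(path)
        layout = ps.build_layout(screen.descriptors, confirmed=True)
        screen.descriptors = list(layout.descriptors)
        results = {"scores": np.arange(12.0).reshape(3, 4)}
        store = tmp_path / "s.h5"
        ps.write_store(store, screen, layout, results)
        screen2, layout2, results2 = ps.read_store(store)
        np.testing.assert_array_equal(screen.measurements, screen2.measurements)
        np.testing.assert_array_equal(screen.elapsed, screen2.elapsed)
        assert screen.labels == screen2.labels
        assert layout2.experiment_type == layout.experiment_type
        assert len(layout2.branches) == len(layout.branches)
        assert layout2.control_indices == layout.control_indices
        np.testing.assert_array_equal(results2["scores"], results["scores"])

    def test_one_group_per_branch(self, fixtures, tmp_path):
        import h5py

        path, _ = fixtures["genetic_chemical"]
        screen = ps.read_export(path)
        layout = ps.build_layout(screen.descriptors, confirmed=True)
        store = tmp_path / "s.h5"
        ps.write_store(store, screen, layout)
        with h5py.File(store) as f:
            assert len(f["layout/branches"]) == len(layout.branches)

    def test_corrupted_file_raises_store_error(self, tmp_path):
        p = tmp_path / "junk.h5"
        p.write_bytes(b"not an hdf5 file at all")
        with pytest.raises(StoreError):
            ps.read_store(p)

    def test_wrong_format_rejected(self, tmp_path):
        import h5py

        p = tmp_path / "other.h5"
        with h5py.File(p, "w") as f:
            f.attrs["format"] = "something-else"
        with pytest.raises(StoreError, match="not a"):
            ps.read_store(p)


class TestResultsText:
    def test_shape_and_nd_sentinel(self, tmp_path):
        df = pd.DataFrame(
            {
                "condition": ["a", "a", "b", "b", "c", "c"],
                "time_h": [0.0, 2.0] * 3,
                "effect": [0.1, 0.2, 0.3, np.nan, 0.5, 0.6],
            }
        )
        (path,) = ps.export_results_text({"effects": df}, tmp_path)
        text = open(path).read()
        assert text.count("\n") == 7  # header + 6 data rows
        assert "ND" in text

    def test_reparse_reproduces_full_precision(self, tmp_path, rng):
        df = pd.DataFrame({"x": rng.standard_normal(50), "tag": ["q"] * 50})
        (path,) = ps.export_results_text({"t": df}, tmp_path)
        back = ps.read_results_text(path)
        np.testing.assert_array_equal(back["x"].to_numpy(), df["x"].to_numpy())
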