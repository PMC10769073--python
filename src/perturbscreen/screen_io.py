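"""Device-export parsing, replicate pooling, hierarchical storage and text export.

The input dialect is the one real-time imagers (Incucyte-style) produce:
optional comment lines, then a header row whose first two columns are
literally ``Date Time`` and ``Elapsed``, followed by one column per
experimental condition.  Each condition header encodes, comma-separated,
one or more perturbagens (a chemical agent as a ``name, concentration,
unit`` triple, a genetic perturbagen as a bare label), then the cell line
and the seeding density.  ``.`` is the decimal separator; the field
separator inside a condition header is always the comma, so comma-delimited
files must quote the condition cells (csv quoting is honoured).
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ExportFormatError,
    HeaderError,
    LabelParseError,
    ReplicateError,
    StoreError,
)

HEADER_TOKENS = ("Date Time", "Elapsed")
#: sentinel used in text exports for metrics that could not be determined
ND = "ND"

STORE_FORMAT = "perturbscreen-store"
STORE_VERSION = 1


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ChemicalDose:
    """One chemical agent at one dose (``name, concentration, unit``)."""

    name: str
    concentration: float
    unit: str

    def __post_init__(self):
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise ValueError(
                f"concentration must be finite and >= 0, got {self.concentration!r}"
            )


@dataclass(frozen=True)
class ConditionDescriptor:
    """Parsed description of one experimental condition (one export column).

    ``agents`` holds the chemical perturbagens with their doses; ``genetic``
    holds genetic perturbagen labels (knockdown / overexpression), which
    carry no concentration.  ``seeding`` is verbatim text (e.g. ``"10k"``)
    used only as a grouping key.  ``is_control`` and ``raw_label`` do not
    take part in equality.
    """

    agents: tuple[ChemicalDose, ...]
    genetic: tuple[str, ...]
    cell_line: str
    seeding: str
    is_control: bool = field(default=False, compare=False)
    raw_label: str = field(default="", compare=False)

    @property
    def perturbagens(self) -> tuple[str, ...]:
        """Ordered agent names: chemical agents first, then genetic labels."""
        return tuple(a.name for a in self.agents) + self.genetic

    @property
    def n_perturbagens(self) -> int:
        return len(self.agents) + len(self.genetic)

    @property
    def is_combination(self) -> bool:
        return self.n_perturbagens >= 2

    def dose_of(self, agent: str) -> float:
        for a in self.agents:
            if a.name == agent:
                return a.concentration
        raise KeyError(agent)

    def with_control(self, flag: bool = True) -> "ConditionDescriptor":
        return replace(self, is_control=flag)


@dataclass
class RawScreen:
    """A parsed export: time vector, measurement matrix, one descriptor per column."""

    elapsed: np.ndarray  # strictly increasing, hours
    measurements: np.ndarray  # [time x condition]
    descriptors: list[ConditionDescriptor]
    datetimes: list[str] | None = None
    sd: np.ndarray | None = None
    ci95: np.ndarray | None = None  # half-width of the 95% CI on replicate means
    n_replicates: np.ndarray | None = None  # per condition

    def __post_init__(self):
        self.elapsed = np.asarray(self.elapsed, dtype=float)
        self.measurements = np.asarray(self.measurements, dtype=float)
        if self.measurements.shape != (len(self.elapsed), len(self.descriptors)):
            raise ValueError(
                "measurements must be [len(elapsed) x len(descriptors)], got "
                f"{self.measurements.shape}"
            )

    @property
    def n_times(self) -> int:
        return len(self.elapsed)

    @property
    def n_conditions(self) -> int:
        return len(self.descriptors)

    @property
    def n_measurements(self) -> int:
        return self.measurements.size

    @property
    def is_endpoint(self) -> bool:
        return self.n_times == 1

    @property
    def labels(self) -> list[str]:
        return [format_condition_label(d) for d in self.descriptors]

    def column(self, index: int) -> np.ndarray:
        return self.measurements[:, index]


# ---------------------------------------------------------------------------
# condition-label grammar


def _parses_float(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _as_number(token: str) -> float | None:
    try:
        value = float(token)
    except ValueError:
        return None
    return value if math.isfinite(value) else None


def _format_number(x: float) -> str:
    # repr of float is the shortest string that round-trips
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def parse_condition_label(text: str) -> ConditionDescriptor:
    """Parse one condition header cell into a :class:`ConditionDescriptor`.

    Grammar: comma-separated fields; the last two are cell line and seeding;
    the leading fields are consumed left to right as either a chemical
    ``name, concentration, unit`` triple (unit must be non-numeric, which also
    rejects a comma used as decimal separator) or a single genetic label.
    """
    tokens = [t.strip() for t in text.split(",")]
    if len(tokens) < 3:
        raise LabelParseError(
            "expected at least <perturbagen>, <cell line>, <seeding>", text
        )
    body, cell_line, seeding = tokens[:-2], tokens[-2], tokens[-1]
    if not cell_line or not seeding:
        raise LabelParseError("empty cell line or seeding field", text)

    agents: list[ChemicalDose] = []
    genetic: list[str] = []
    i = 0
    while i < len(body):
        name = body[i]
        if not name:
            raise LabelParseError("empty perturbagen field", text)
        if _parses_float(name):
            raise LabelParseError(
                f"numeric token {name!r} where a perturbagen name was expected "
                "(check field count and that '.' is the decimal separator)",
                text,
            )
        conc_token = body[i + 1] if i + 1 < len(body) else None
        if conc_token is not None and _parses_float(conc_token) and _as_number(conc_token) is None:
            raise LabelParseError(
                f"non-finite concentration {conc_token!r} for {name!r}", text
            )
        conc = _as_number(conc_token) if conc_token is not None else None
        if conc is not None:
            if i + 2 >= len(body) or _as_number(body[i + 2]) is not None:
                raise LabelParseError(
                    f"concentration {body[i + 1]!r} for {name!r} must be followed "
                    "by a non-numeric unit ('.' is the decimal separator)",
                    text,
                )
            if conc < 0:
                raise LabelParseError(f"negative concentration for {name!r}", text)
            agents.append(ChemicalDose(name, conc, body[i + 2]))
            i += 3
        else:
            genetic.append(name)
            i += 1

    if not agents and not genetic:
        raise LabelParseError("no perturbagen fields found", text)
    return ConditionDescriptor(
        agents=tuple(agents),
        genetic=tuple(genetic),
        cell_line=cell_line,
        seeding=seeding,
        raw_label=text,
    )


def format_condition_label(d: ConditionDescriptor) -> str:
    """Render a descriptor back to the header-cell dialect (inverse of parsing)."""
    parts: list[str] = []
    for a in d.agents:
        parts.extend([a.name, _format_number(a.concentration), a.unit])
    parts.extend(d.genetic)
    parts.extend([d.cell_line, d.seeding])
    return ", ".join(parts)


# ---------------------------------------------------------------------------
# export reading


def detect_header(
    lines: Sequence[str], delimiter: str = "auto"
) -> tuple[int, str]:
    """Locate the data-header row and the delimiter of an export.

    Returns ``(row_index, delimiter)`` for the first line whose first two
    delimited fields are exactly ``Date Time`` and ``Elapsed``; all preceding
    lines are comments.  ``delimiter`` may be ``"auto"`` (try tab, then
    comma), ``"tab"`` or ``"comma"``.
    """
    if not lines:
        raise HeaderError(
            "empty input: no header row with 'Date Time' and 'Elapsed' found"
        )
    candidates = {"auto": ["\t", ","], "tab": ["\t"], "comma": [","]}.get(delimiter)
    if candidates is None:
        candidates = [delimiter]
    for idx, line in enumerate(lines):
        for delim in candidates:
            fields = next(csv.reader([line], delimiter=delim))
            if (
                len(fields) >= 2
                and fields[0].strip() == HEADER_TOKENS[0]
                and fields[1].strip() == HEADER_TOKENS[1]
            ):
                return idx, delim
    raise HeaderError(
        "no header row found: the first two columns must be exactly "
        f"{HEADER_TOKENS[0]!r} and {HEADER_TOKENS[1]!r}"
    )


def read_export(path: str | os.PathLike, delimiter: str = "auto") -> RawScreen:
    """Read a device text export into a :class:`RawScreen`.

    A single data row yields an endpoint screen.  Empty cells become NaN
    (that time/condition pair is unavailable downstream); any other
    non-numeric cell raises with row/column coordinates.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    lines = [ln for ln in lines if True]
    header_idx, delim = detect_header(lines, delimiter)

    header = next(csv.reader([lines[header_idx]], delimiter=delim))
    descriptors = [parse_condition_label(cell) for cell in header[2:]]
    if not descriptors:
        raise ExportFormatError("no condition columns after 'Elapsed'", row=header_idx)

    elapsed: list[float] = []
    datetimes: list[str] = []
    values: list[list[float]] = []
    for offset, line in enumerate(lines[header_idx + 1 :]):
        row_no = header_idx + 1 + offset
        if not line.strip():
            continue
        fields = next(csv.reader([line], delimiter=delim))
        if len(fields) != len(header):
            raise ExportFormatError(
                f"ragged row: {len(fields)} fields, header has {len(header)}",
                row=row_no,
            )
        t = _as_number(fields[1])
        if t is None:
            raise ExportFormatError(
                f"non-numeric 'Elapsed' value {fields[1]!r}", row=row_no, column=1
            )
        row_vals: list[float] = []
        for col, cell in enumerate(fields[2:], start=2):
            if cell.strip() == "":
                row_vals.append(np.nan)
                continue
            v = _as_number(cell)
            if v is None:
                raise ExportFormatError(
                    f"non-numeric measurement {cell!r}", row=row_no, column=col
                )
            row_vals.append(v)
        elapsed.append(t)
        datetimes.append(fields[0])
        values.append(row_vals)

    if not values:
        raise ExportFormatError("no data rows below the header", row=header_idx)
    t_arr = np.asarray(elapsed, dtype=float)
    if np.any(np.diff(t_arr) <= 0):
        bad = int(np.flatnonzero(np.diff(t_arr) <= 0)[0]) + 1
        raise ExportFormatError(
            f"'Elapsed' values must be strictly increasing (offending value "
            f"{t_arr[bad]!r})",
            row=header_idx + 1 + bad,
            column=1,
        )
    return RawScreen(
        elapsed=t_arr,
        measurements=np.asarray(values, dtype=float),
        descriptors=descriptors,
        datetimes=datetimes,
    )


def write_export(screen: RawScreen, path: str | os.PathLike, delimiter: str = "\t") -> None:
    """Write a :class:`RawScreen` back out in the device text dialect."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(HEADER_TOKENS) + screen.labels)
        for i, t in enumerate(screen.elapsed):
            dt = screen.datetimes[i] if screen.datetimes else ""
            row = [dt, _format_number(float(t))]
            for v in screen.measurements[i]:
                row.append("" if np.isnan(v) else repr(float(v)))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# replicate pooling


def _descriptor_key(d: ConditionDescriptor):
    return (d.agents, d.genetic, d.cell_line, d.seeding)


def merge_replicates(screens: Sequence[RawScreen] | RawScreen) -> RawScreen:
    """Pool technical/biological replicates into mean, SD and 95% CI.

    Replicates may live in independent screens or as duplicate-descriptor
    columns of one screen; all screens must share the elapsed grid exactly
    (no interpolation).  The CI half-width is the Student-t 95% interval on
    the replicate mean; SD/CI are NaN where fewer than two replicates cover
    a cell.
    """
    if isinstance(screens, RawScreen):
        screens = [screens]
    if not screens:
        raise ReplicateError("no screens to merge")
    ref = screens[0]
    for s in screens[1:]:
        if s.n_times != ref.n_times or not np.allclose(s.elapsed, ref.elapsed):
            raise ReplicateError(
                "replicate screens must share the same 'Elapsed' time grid"
            )

    order: list[tuple] = []
    columns: dict[tuple, list[np.ndarray]] = {}
    descriptors: dict[tuple, ConditionDescriptor] = {}
    for s in screens:
        for j, d in enumerate(s.descriptors):
            key = _descriptor_key(d)
            if key not in columns:
                order.append(key)
                columns[key] = []
                descriptors[key] = d
            columns[key].append(s.measurements[:, j])

    n_t = ref.n_times
    n_c = len(order)
    mean = np.empty((n_t, n_c))
    sd = np.full((n_t, n_c), np.nan)
    ci = np.full((n_t, n_c), np.nan)
    n_rep = np.zeros(n_c, dtype=int)
    for j, key in enumerate(order):
        stack = np.column_stack(columns[key])  # [time x replicate]
        n_rep[j] = stack.shape[1]
        counts = np.sum(~np.isnan(stack), axis=1)
        with np.errstate(invalid="ignore"):
            mean[:, j] = np.where(counts > 0, np.nanmean(stack, axis=1), np.nan)
            has2 = counts >= 2
            if np.any(has2):
                s_j = np.nanstd(stack, axis=1, ddof=1)
                sd[has2, j] = s_j[has2]
                tcrit = stats.t.ppf(0.975, counts[has2] - 1)
                ci[has2, j] = tcrit * s_j[has2] / np.sqrt(counts[has2])
    return RawScreen(
        elapsed=ref.elapsed.copy(),
        measurements=mean,
        descriptors=[descriptors[k] for k in order],
        datetimes=list(ref.datetimes) if ref.datetimes else None,
        sd=sd,
        ci95=ci,
        n_replicates=n_rep,
    )


# ---------------------------------------------------------------------------
# hierarchical store


def write_store(
    path: str | os.PathLike,
    screen: RawScreen,
    layout=None,
    results: dict[str, np.ndarray] | None = None,
) -> None:
    """Persist a screen (plus optional layout and named result arrays) to HDF5.

    One group is created per branch (cell line / seeding / genetic condition /
    agents); numeric arrays round-trip losslessly.
    """
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["format"] = STORE_FORMAT
        f.attrs["version"] = STORE_VERSION
        g = f.create_group("screen")
        g.create_dataset("elapsed", data=screen.elapsed)
        g.create_dataset("measurements", data=screen.measurements)
        g.create_dataset("labels", data=np.array(screen.labels, dtype=object), dtype=str_dt)
        g.create_dataset(
            "is_control",
            data=np.array([d.is_control for d in screen.descriptors], dtype=bool),
        )
        if screen.datetimes is not None:
            g.create_dataset(
                "datetimes", data=np.array(screen.datetimes, dtype=object), dtype=str_dt
            )
        for name, arr in (
            ("sd", screen.sd),
            ("ci95", screen.ci95),
            ("n_replicates", screen.n_replicates),
        ):
            if arr is not None:
                g.create_dataset(name, data=np.asarray(arr))
        if layout is not None:
            lg = f.create_group("layout")
            lg.attrs["experiment_type"] = layout.experiment_type
            lg.create_dataset(
                "controls", data=np.asarray(layout.control_indices, dtype=int)
            )
            for i, br in enumerate(layout.branches):
                bg = lg.create_group(f"branches/{i}")
                bg.attrs["cell_line"] = br.cell_line
                bg.attrs["seeding"] = br.seeding
                bg.create_dataset(
                    "genetic", data=np.array(list(br.genetic), dtype=object), dtype=str_dt
                )
                bg.create_dataset("members", data=np.asarray(br.members, dtype=int))
        if results:
            rg = f.create_group("results")
            for name, arr in results.items():
                rg.create_dataset(name, data=np.asarray(arr))


def read_store(path: str | os.PathLike):
    """Inverse of :func:`write_store`; returns ``(screen, layout, results)``."""
    from . import layout as layout_mod  # deferred: layout imports this module

    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise StoreError(f"cannot open store {path!r}: {exc}") from exc
    with f:
        if f.attrs.get("format") != STORE_FORMAT:
            raise StoreError(f"{path!r} is not a {STORE_FORMAT} file")
        if int(f.attrs.get("version", -1)) != STORE_VERSION:
            raise StoreError(
                f"store version {f.attrs.get('version')!r} unsupported "
                f"(expected {STORE_VERSION})"
            )
        g = f["screen"]
        labels = [s.decode() if isinstance(s, bytes) else s for s in g["labels"][()]]
        descriptors = [parse_condition_label(lab) for lab in labels]
        flags = g["is_control"][()]
        descriptors = [d.with_control(bool(fl)) for d, fl in zip(descriptors, flags)]
        datetimes = None
        if "datetimes" in g:
            datetimes = [
                s.decode() if isinstance(s, bytes) else s for s in g["datetimes"][()]
            ]
        screen = RawScreen(
            elapsed=g["elapsed"][()],
            measurements=g["measurements"][()],
            descriptors=descriptors,
            datetimes=datetimes,
            sd=g["sd"][()] if "sd" in g else None,
            ci95=g["ci95"][()] if "ci95" in g else None,
            n_replicates=g["n_replicates"][()] if "n_replicates" in g else None,
        )
        layout_obj = None
        if "layout" in f:
            lg = f["layout"]
            control_idx = [int(i) for i in lg["controls"][()]]
            branches = []
            if "branches" in lg:
                for key in sorted(lg["branches"], key=int):
                    bg = lg["branches"][key]
                    members = [int(i) for i in bg["members"][()]]
                    branches.append(
                        layout_mod.Branch.from_members(
                            [screen.descriptors[i] for i in members],
                            members,
                            cell_line=bg.attrs["cell_line"],
                            seeding=bg.attrs["seeding"],
                        )
                    )
            layout_obj = layout_mod.Layout(
                branches=branches,
                control_indices=control_idx,
                descriptors=screen.descriptors,
                experiment_type=lg.attrs["experiment_type"],
            )
        results = None
        if "results" in f:
            results = {name: f["results"][name][()] for name in f["results"]}
    return screen, layout_obj, results


# ---------------------------------------------------------------------------
# tabular text export


def export_results_text(
    tables: dict[str, pd.DataFrame], out_dir: str | os.PathLike, prefix: str = ""
) -> list[str]:
    """Write result tables as tab-separated text with ``.`` decimals.

    ``tables`` maps a short name (``effects``, ``fits``, ``synergy`` ...) to a
    DataFrame; NaN / undetermined metrics are rendered as the sentinel
    ``"ND"``.  Floats are printed with ``repr`` precision so that re-parsing
    the file reproduces the stored values exactly.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name, df in tables.items():
        out = os.path.join(out_dir, f"{prefix}{name}.txt")
        df.to_csv(out, sep="\t", index=False, na_rep=ND)
        paths.append(out)
    return paths


def read_results_text(path: str | os.PathLike) -> pd.DataFrame:
    """Re-read a table written by :func:`export_results_text`."""
    return pd.read_csv(
        path, sep="\t", na_values=[ND], keep_default_na=True,
        float_precision="round_trip",
    )
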