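"""Readers and writers for the two tab-delimited input formats.

The expression file carries one row per probe: a unique probe id, an optional
gene symbol, and one log2 expression value per array (empty cells or ``NA``
denote missing measurements).  The label (design) file describes each array
with a treatment, a replicate number and a measurement time, plus an optional
``paired`` row.  Arrays belonging to the same (treatment, replicate) form one
time-course profile; times need not agree across replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "DesignMetadata",
    "Dataset",
    "parse_expression_file",
    "parse_label_file",
    "assemble_dataset",
    "write_expression_tsv",
    "write_label_tsv",
    "write_results_tsv",
]

_MISSING_TOKENS = {"", "na"}


def _read_lines(source) -> list[str]:
    """Return logical lines from a path or text stream, dropping trailing blanks."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = text.splitlines()
    while lines and not lines[-1].strip():
        lines.pop()
    return lines


def _is_numeric_or_missing(token: str) -> bool:
    t = token.strip()
    if t.lower() in _MISSING_TOKENS:
        return True
    try:
        float(t)
    except ValueError:
        return False
    return True


def _parse_cell(token: str, lineno: int) -> float:
    t = token.strip()
    if t.lower() in _MISSING_TOKENS:
        return math.nan
    try:
        v = float(t)
    except ValueError:
        raise FormatError(
            f"line {lineno}: expression value {token!r} is not numeric"
        ) from None
    if not math.isfinite(v):
        raise FormatError(f"line {lineno}: expression value {token!r} is not finite")
    return v


@dataclass
class ExpressionMatrix:
    """Probe-by-array expression values with optional gene symbols.

    ``values`` is a float array of shape (n_probes, n_arrays); NaN marks a
    missing cell.
    """

    probe_ids: list[str]
    array_names: list[str]
    values: np.ndarray
    symbols: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe ids")
        if len(set(self.array_names)) != len(self.array_names):
            raise ValidationError("duplicate array names")
        if len(self.probe_ids) < 1 or len(self.array_names) < 2:
            raise ValidationError("need at least 1 probe and 2 arrays")
        if self.values.shape != (len(self.probe_ids), len(self.array_names)):
            raise ValidationError("values shape does not match ids")
        if self.symbols is not None and len(self.symbols) != len(self.probe_ids):
            raise ValidationError("symbols length does not match probe ids")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_arrays(self) -> int:
        return len(self.array_names)


@dataclass
class DesignMetadata:
    """Per-array treatment, replicate and measurement time, plus pairing."""

    array_names: list[str]
    treatment: list[str]
    replicate: list[int]
    time: list[float]
    paired: bool = False

    def __post_init__(self) -> None:
        n = len(self.array_names)
        if len(set(self.array_names)) != n:
            raise ValidationError("duplicate array names in design")
        if not (len(self.treatment) == len(self.replicate) == len(self.time) == n):
            raise ValidationError("design rows have inconsistent lengths")
        for t in self.time:
            if not math.isfinite(t):
                raise ValidationError("non-finite time value in design")
        triples = list(zip(self.treatment, self.replicate, self.time))
        if len(set(triples)) != n:
            dup = next(t for t in triples if triples.count(t) > 1)
            raise ValidationError(
                f"duplicate (treatment, replicate, time) triple {dup!r}: array identity is ambiguous"
            )
        if self.paired:
            by_trt: dict[str, set[int]] = {}
            for trt, rep in zip(self.treatment, self.replicate):
                by_trt.setdefault(trt, set()).add(rep)
            sets = list(by_trt.values())
            if any(s != sets[0] for s in sets[1:]):
                raise ValidationError(
                    "paired design requires identical replicate numbers across treatments"
                )

    @property
    def treatments(self) -> list[str]:
        out: list[str] = []
        for t in self.treatment:
            if t not in out:
                out.append(t)
        return out


@dataclass
class Dataset:
    """Assembled time-course data: (probe, treatment, replicate) -> profile.

    Each profile is a pair of aligned arrays (times strictly increasing,
    log2 values).  Replicate profiles may differ in length and time grid.
    """

    profiles: dict[tuple[str, str, int], tuple[np.ndarray, np.ndarray]]
    probe_ids: list[str]
    treatments: list[str]
    symbols: Mapping[str, str] = field(default_factory=dict)
    paired: bool = False

    def replicates(self, treatment: str) -> list[int]:
        reps = sorted({r for (_, t, r) in self.profiles if t == treatment})
        return reps

    def profile(self, probe: str, treatment: str, replicate: int):
        key = (probe, treatment, replicate)
        if key not in self.profiles:
            raise KeyError(f"no profile for {key!r}")
        return self.profiles[key]

    def has_profile(self, probe: str, treatment: str, replicate: int) -> bool:
        return (probe, treatment, replicate) in self.profiles

    def symbol(self, probe: str) -> str:
        return self.symbols.get(probe, "")


def parse_expression_file(source) -> ExpressionMatrix:
    """Parse the tab-delimited expression format.

    The first header field names the probe-id column; an optional second
    field names the symbol column; the rest are array names.  The symbol
    column is detected from content: it is present when any data row's second
    field is neither numeric nor a missing marker.
    """
    lines = _read_lines(source)
    if len(lines) < 2:
        raise FormatError("expression file needs a header line and at least one data row")
    header = lines[0].split("\t")
    if len(header) < 3:
        raise FormatError("expression header needs an id column and at least 2 arrays")
    n_fields = len(header)
    rows = [(i + 2, ln.split("\t")) for i, ln in enumerate(lines[1:])]
    for lineno, fields in rows:
        if len(fields) != n_fields:
            raise FormatError(
                f"line {lineno}: expected {n_fields} tab-delimited fields, found {len(fields)}"
            )
    has_symbol = any(not _is_numeric_or_missing(f[1]) for _, f in rows)
    if has_symbol and n_fields < 4:
        raise FormatError("expression file with a symbol column needs at least 2 arrays")
    first_data = 2 if has_symbol else 1
    array_names = [h.strip() for h in header[first_data:]]
    probe_ids: list[str] = []
    symbols: list[str] | None = [] if has_symbol else None
    seen: set[str] = set()
    values = np.empty((len(rows), len(array_names)), dtype=float)
    for i, (lineno, fields) in enumerate(rows):
        pid = fields[0].strip()
        if not pid:
            raise FormatError(f"line {lineno}: empty probe id")
        if pid in seen:
            raise FormatError(f"line {lineno}: duplicate probe id {pid!r}")
        seen.add(pid)
        probe_ids.append(pid)
        if has_symbol:
            symbols.append(fields[1].strip())  # type: ignore[union-attr]
        for j, tok in enumerate(fields[first_data:]):
            values[i, j] = _parse_cell(tok, lineno)
    return ExpressionMatrix(probe_ids, array_names, values, symbols)


def parse_label_file(source) -> DesignMetadata:
    """Parse the tab-delimited design format.

    Row order: header with array names, treatment row, replicate row, time
    row, and an optional paired row (``yes``/``no``, case-insensitive; absent
    means unpaired).  The first field of every row is a row label.
    """
    lines = _read_lines(source)
    if len(lines) < 4:
        raise FormatError("label file needs header, treatment, replicate and time rows")
    if len(lines) > 5:
        raise FormatError(f"label file has {len(lines)} rows; at most 5 expected")
    split = [ln.split("\t") for ln in lines]
    array_names = [f.strip() for f in split[0][1:]]
    if len(array_names) < 2:
        raise FormatError("label file must name at least 2 arrays")
    for rowno, fields in enumerate(split[1:4], start=2):
        if len(fields) != len(array_names) + 1:
            raise FormatError(
                f"row {rowno}: expected {len(array_names) + 1} fields, found {len(fields)}"
            )
    treatment = [f.strip() for f in split[1][1:]]
    replicate: list[int] = []
    for tok in split[2][1:]:
        t = tok.strip()
        try:
            replicate.append(int(t))
        except ValueError:
            raise FormatError(f"replicate number {tok!r} is not an integer") from None
    time: list[float] = []
    for tok in split[3][1:]:
        try:
            time.append(float(tok.strip()))
        except ValueError:
            raise FormatError(f"time point {tok!r} is not numeric") from None
    paired = False
    if len(lines) == 5:
        cells = [f.strip().lower() for f in split[4][1:] if f.strip()]
        if not cells:
            raise FormatError("paired row present but empty")
        if len(set(cells)) > 1:
            raise FormatError(f"paired row has conflicting values {sorted(set(cells))}")
        if cells[0] not in ("yes", "no"):
            raise FormatError(f"paired row value {cells[0]!r} must be 'yes' or 'no'")
        paired = cells[0] == "yes"
    return DesignMetadata(array_names, treatment, replicate, time, paired)


def assemble_dataset(
    expr: ExpressionMatrix, design: DesignMetadata, apply_log2: bool = False
) -> Dataset:
    """Join the expression matrix with the design into per-replicate profiles.

    Array names must match between the two files (order-independently).  With
    ``apply_log2`` the stored values are log2 of the input; missing cells are
    simply omitted from profiles, and a replicate whose cells are all missing
    for a probe contributes no profile (warned once).
    """
    e_names, d_names = set(expr.array_names), set(design.array_names)
    if e_names != d_names:
        only_e = sorted(e_names - d_names)
        only_d = sorted(d_names - e_names)
        raise ValidationError(
            "array names differ between expression and label files: "
            f"only in expression {only_e}, only in labels {only_d}"
        )
    col = {name: j for j, name in enumerate(expr.array_names)}
    values = expr.values
    if apply_log2:
        with np.errstate(invalid="ignore", divide="ignore"):
            if np.nanmin(values) <= 0:
                raise ValidationError(
                    "cannot log2-transform: expression contains non-positive values"
                )
            values = np.log2(values)

    profiles: dict[tuple[str, str, int], tuple[np.ndarray, np.ndarray]] = {}
    n_dropped = 0
    for i, probe in enumerate(expr.probe_ids):
        per_rep: dict[tuple[str, int], list[tuple[float, float]]] = {}
        for name, trt, rep, t in zip(
            design.array_names, design.treatment, design.replicate, design.time
        ):
            v = values[i, col[name]]
            per_rep.setdefault((trt, rep), [])
            if not math.isnan(v):
                per_rep[(trt, rep)].append((t, v))
        for (trt, rep), pts in per_rep.items():
            if not pts:
                n_dropped += 1
                continue
            pts.sort(key=lambda p: p[0])
            times = np.array([p[0] for p in pts])
            vals = np.array([p[1] for p in pts])
            profiles[(probe, trt, rep)] = (times, vals)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} fully-missing (probe, treatment, replicate) profile(s)",
            stacklevel=2,
        )
    symbols = (
        dict(zip(expr.probe_ids, expr.symbols)) if expr.symbols is not None else {}
    )
    return Dataset(
        profiles=profiles,
        probe_ids=list(expr.probe_ids),
        treatments=design.treatments,
        symbols=symbols,
        paired=design.paired,
    )


def write_expression_tsv(matrix: ExpressionMatrix, destination: IO[str]) -> None:
    """Write an expression matrix in the input format (full float precision)."""
    header = ["ID"]
    if matrix.symbols is not None:
        header.append("Symbol")
    header.extend(matrix.array_names)
    destination.write("\t".join(header) + "\n")
    for i, pid in enumerate(matrix.probe_ids):
        fields = [pid]
        if matrix.symbols is not None:
            fields.append(matrix.symbols[i])
        for v in matrix.values[i]:
            fields.append("" if math.isnan(v) else repr(float(v)))
        destination.write("\t".join(fields) + "\n")


def write_label_tsv(design: DesignMetadata, destination: IO[str]) -> None:
    """Write a design in the input format, including an explicit paired row."""
    destination.write("\t".join(["Array"] + list(design.array_names)) + "\n")
    destination.write("\t".join(["Treatment"] + list(design.treatment)) + "\n")
    destination.write("\t".join(["Replicate"] + [str(r) for r in design.replicate]) + "\n")
    destination.write("\t".join(["Time"] + [repr(float(t)) for t in design.time]) + "\n")
    flag = "yes" if design.paired else "no"
    destination.write("\t".join(["Paired"] + [flag] * len(design.array_names)) + "\n")


def write_results_tsv(
    table: pd.DataFrame,
    destination: IO[str],
    sig_digits: int = 6,
    header_lines: Sequence[str] = (),
) -> None:
    """Write a tabular result as TSV: optional ``#`` header, then header row.

    Floats are rendered with ``sig_digits`` significant digits; row order is
    preserved.  Raises on an empty table.
    """
    if table is None or len(table) == 0:
        raise UsageError("refusing to write an empty results table")
    for line in header_lines:
        destination.write(f"# {line}\n")
    fmt = f"%.{sig_digits}g"
    table.to_csv(destination, sep="\t", index=False, float_format=fmt, na_rep="NA")
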