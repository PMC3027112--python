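"""Synthetic short time-course datasets in the package's own input formats.

The generator emulates the data model the analysis targets: a few treatments,
a few replicates each, short and possibly irregular time grids, log2-scale
values with i.i.d. normal noise, and optional missing cells.  Null genes
share their mean profile across treatments; alternative genes add a template
effect profile (constant shift, ramp, or peak) to the second treatment, which
also provides ground-truth cluster structure.  Output is emitted as
expression/label file text so that every generated dataset exercises the
parsers, plus a truth table for evaluating downstream calls.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import (
    Dataset,
    DesignMetadata,
    ExpressionMatrix,
    assemble_dataset,
    parse_expression_file,
    parse_label_file,
    write_expression_tsv,
    write_label_tsv,
)
from .mtc import PValueSet

__all__ = ["SimulationSpec", "simulate_dataset", "simulate_to_dataset", "simulate_pvalues"]

_EFFECT_SHAPES = ("constant", "ramp", "peak")


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Defaults follow the short-series regime the methods target: two
    treatments, 4 replicates each, 4 irregular-capable time points, log2
    noise SD 0.3 and a unit constant log2 shift for alternative genes.
    """

    n_genes: int = 500
    fraction_alternative: float = 0.0
    treatments: tuple[str, str] = ("control", "alpha")
    replicates: int = 4
    times: tuple[float, ...] = (0.0, 2.0, 8.0, 24.0)
    jitter: float = 0.0  # max absolute uniform jitter added per replicate time
    noise_sd: float = 0.3
    missing_rate: float = 0.0
    paired: bool = False
    effect: str = "constant"  # template shape when templates not given
    effect_size: float = 1.0  # log2 units
    templates: tuple[str, ...] | None = None  # overrides `effect`; alt genes cycle over these
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_alternative <= 1.0:
            raise ParameterError("fraction_alternative must be in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ParameterError("missing_rate must be in [0, 0.5]")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        if len(self.times) < 2:
            raise ParameterError("at least 2 time points are required")
        shapes = self.templates if self.templates is not None else (self.effect,)
        for s in shapes:
            if s not in _EFFECT_SHAPES:
                raise ParameterError(f"unknown effect shape {s!r}; choose from {_EFFECT_SHAPES}")
        if self.jitter < 0:
            raise ParameterError("jitter must be >= 0")
        gaps = np.diff(np.asarray(self.times, dtype=float))
        if np.any(gaps <= 0):
            raise ParameterError("times must be strictly increasing")
        if self.jitter >= gaps.min() / 2:
            raise ParameterError("jitter must be smaller than half the smallest time gap")


def _effect_profile(shape: str, t: np.ndarray, size: float, t0: float, t1: float) -> np.ndarray:
    span = t1 - t0
    if shape == "constant":
        return np.full_like(t, size)
    if shape == "ramp":
        return size * (t - t0) / span
    # peak: bump centered mid-course, back near baseline at the ends
    mid = 0.5 * (t0 + t1)
    return size * np.exp(-(((t - mid) / (0.25 * span)) ** 2))


def simulate_dataset(spec: SimulationSpec):
    """Generate (expression file text, label file text, truth table).

    The truth table has one row per gene with columns ``gene``, ``status``
    (null/alt) and ``template``.  Byte-identical output for equal specs.
    """
    rng = np.random.default_rng(spec.seed)
    base = np.asarray(spec.times, dtype=float)
    t0, t1 = base[0], base[-1]
    shapes = spec.templates if spec.templates is not None else (spec.effect,)

    # per (treatment, replicate) time grid; paired replicates share jitter
    grids: dict[tuple[str, int], np.ndarray] = {}
    for rep in range(1, spec.replicates + 1):
        shared = base + rng.uniform(-spec.jitter, spec.jitter, base.size) if spec.jitter else base
        for trt in spec.treatments:
            if spec.paired:
                grids[(trt, rep)] = shared
            else:
                grids[(trt, rep)] = (
                    base + rng.uniform(-spec.jitter, spec.jitter, base.size)
                    if spec.jitter
                    else base
                )

    array_names, a_trt, a_rep, a_time = [], [], [], []
    for trt in spec.treatments:
        for rep in range(1, spec.replicates + 1):
            for j, t in enumerate(grids[(trt, rep)]):
                array_names.append(f"{trt}_r{rep}_t{j}")
                a_trt.append(trt)
                a_rep.append(rep)
                a_time.append(float(t))

    n_alt = int(round(spec.fraction_alternative * spec.n_genes))
    status = np.array(["alt"] * n_alt + ["null"] * (spec.n_genes - n_alt))
    template = np.array(
        [shapes[i % len(shapes)] if status[i] == "alt" else "" for i in range(spec.n_genes)],
        dtype=object,
    )
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)

    values = np.empty((spec.n_genes, len(array_names)))
    times_arr = np.array(a_time)
    for j, (trt, _rep, t) in enumerate(zip(a_trt, a_rep, times_arr)):
        mean = baseline.copy()
        if trt == spec.treatments[1] and n_alt:
            for shape in set(template[:n_alt]):
                sel = template == shape
                mean[sel] += _effect_profile(shape, np.array([t]), spec.effect_size, t0, t1)[0]
        values[:, j] = mean
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, values.shape)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values[mask] = np.nan

    genes = [f"g{i + 1:04d}" for i in range(spec.n_genes)]
    symbols = [f"GENE{i + 1}" for i in range(spec.n_genes)]
    matrix = ExpressionMatrix(genes, array_names, values, symbols)
    design = DesignMetadata(array_names, a_trt, a_rep, a_time, paired=spec.paired)

    expr_buf, label_buf = _io.StringIO(), _io.StringIO()
    write_expression_tsv(matrix, expr_buf)
    write_label_tsv(design, label_buf)
    truth = pd.DataFrame({"gene": genes, "status": status, "template": template})
    return expr_buf.getvalue(), label_buf.getvalue(), truth


def simulate_to_dataset(spec: SimulationSpec):
    """Convenience: simulate and parse straight back into a Dataset.

    Parsing the emitted text (rather than building the Dataset directly)
    keeps the generator honest about the file formats.  Returns
    ``(dataset, truth)``.
    """
    expr_text, label_text, truth = simulate_dataset(spec)
    matrix = parse_expression_file(_io.StringIO(expr_text))
    design = parse_label_file(_io.StringIO(label_text))
    return assemble_dataset(matrix, design), truth


def simulate_pvalues(
    m: int, pi0: float, alt_dist: tuple[float, float] = (0.05, 1.0), seed: int | None = None
):
    """Draw m p-values: pi0·m uniform nulls, the rest Beta(a, b) alternatives.

    Returns ``(PValueSet, is_null)`` with ``is_null`` a boolean array in the
    same order (nulls first).
    """
    if m < 1:
        raise ParameterError("m must be >= 1")
    if not 0.0 <= pi0 <= 1.0:
        raise ParameterError("pi0 must be in [0, 1]")
    a, b = alt_dist
    if a <= 0 or b <= 0:
        raise ParameterError("beta parameters must be positive")
    rng = np.random.default_rng(seed)
    n_null = int(round(pi0 * m))
    p = np.concatenate([rng.uniform(0, 1, n_null), rng.beta(a, b, m - n_null)])
    is_null = np.arange(m) < n_null
    return PValueSet.from_values(p), is_null
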