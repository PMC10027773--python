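"""Turning screened series into matched AB graphs and a factorial study.

Each screened 30-point series yields three sibling AB graphs that share
the same latent data and differ only in where baseline (phase A) ends:

* ``fixed`` — phase A stops at the minimum length (3 or 5 sessions);
* ``response_guided`` — phase A continues until the stability statistic
  (trend angle, or SD of the last three points) first drops to or below
  the maximum allowable value, capped so phase B still fits;
* ``random`` — phase-A lengths drawn without replacement from the
  response-guided lengths of the same design cell, so the two schemes
  have identical length distributions.

An effect is simulated by adding the standardized mean difference (SMD)
to every phase-B point (scaled by 1.73 in the variability experiment to
match the larger innovation SD).  Sharing the latent series across
schemes isolates the effect of the baseline-termination rule itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator

import numpy as np
import pandas as pd

from .generator import (
    TREND,
    VARIABILITY,
    ConditionSpec,
    _screening_stat,
    sample_screened_batch,
    trend_angles,
)

SCHEMES = ("fixed", "response_guided", "random")

INCREASING = "increasing"
DECREASING = "decreasing"


@dataclass(frozen=True)
class ABGraph:
    """A concrete two-phase graph derived from one simulated series."""

    phase_a: np.ndarray
    phase_b: np.ndarray
    scheme: str
    spec: ConditionSpec
    series_id: int = -1
    initial_trend_sign: str | None = None

    @property
    def n_points(self) -> int:
        return len(self.phase_a) + len(self.phase_b)


@dataclass(frozen=True)
class StudyDesign:
    """Replicate counts and seed for one experiment's factorial study.

    The full-scale study uses 5,000 null series plus 1,000 per SMD value
    (1-5) in each of the 16 factorial cells: 160,000 series and 480,000
    graphs.  Scaled-down designs keep the 50/50 null-vs-effect split and
    the uniform SMD distribution.
    """

    experiment: str
    n_series_per_cell_null: int = 5000
    n_series_per_cell_per_smd: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in (TREND, VARIABILITY):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.n_series_per_cell_null < 1 or self.n_series_per_cell_per_smd < 1:
            raise ValueError("replicate counts must be positive")
        if self.n_series_per_cell_null != 5 * self.n_series_per_cell_per_smd:
            raise ValueError(
                "null series per cell must equal 5x the per-SMD count so that "
                "half of all series are null"
            )

    @property
    def cells(self) -> list[ConditionSpec]:
        thresholds = (15.0, 30.0) if self.experiment == TREND else (1.0, 1.5)
        return [
            ConditionSpec(self.experiment, min_a, n_b, a, thr)
            for min_a, n_b, a, thr in product((3, 5), (5, 10), (0.0, 0.4), thresholds)
        ]

    @property
    def n_series_per_cell(self) -> int:
        return self.n_series_per_cell_null + 5 * self.n_series_per_cell_per_smd

    @property
    def n_series(self) -> int:
        return 16 * self.n_series_per_cell


def response_guided_length(
    values: np.ndarray, spec: ConditionSpec
) -> tuple[int, bool]:
    """First phase-A length beyond the minimum at which baseline is stable.

    Returns ``(length, capped)``: the smallest ``t > min_a`` at which the
    stability statistic over the first ``t`` points is at or below the
    maximum allowable value.  If stability is never reached before phase B
    must start, the length is capped at ``30 - n_b`` and ``capped`` is True.
    """
    values = np.asarray(values, dtype=float).ravel()
    cap = spec.max_a
    for t in range(spec.min_a + 1, cap + 1):
        if _screening_stat(values[None, :], spec, t)[0] <= spec.stability_threshold:
            return t, False
    return cap, True


def response_guided_lengths(
    values: np.ndarray, spec: ConditionSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise :func:`response_guided_length` over a stack of series."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = len(values)
    cap = spec.max_a
    lengths = np.full(n, cap, dtype=int)
    capped = np.ones(n, dtype=bool)
    pending = np.ones(n, dtype=bool)
    for t in range(spec.min_a + 1, cap + 1):
        stable = _screening_stat(values, spec, t) <= spec.stability_threshold
        newly = pending & stable
        lengths[newly] = t
        capped[newly] = False
        pending &= ~stable
        if not pending.any():
            break
    return lengths, capped


def assign_random_lengths(
    rg_lengths: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw phase-A lengths without replacement from the response-guided ones.

    A uniformly random permutation, so the random-length scheme has exactly
    the same frequency distribution of baseline lengths as the
    response-guided scheme it is matched to.
    """
    rg_lengths = np.asarray(rg_lengths, dtype=int)
    if rg_lengths.size == 0:
        raise ValueError("rg_lengths must be non-empty")
    return rng.permutation(rg_lengths)


def build_graphs(
    values: np.ndarray,
    spec: ConditionSpec,
    rg_length: int,
    random_length: int,
    series_id: int = -1,
) -> tuple[ABGraph, ABGraph, ABGraph]:
    """Build the three sibling AB graphs of one screened series.

    Phase A is the first ``L`` points (``L`` = min, response-guided or
    random length); phase B is the next ``n_b`` points with the effect
    delta added to every point.  Phase A is never altered.
    """
    values = np.asarray(values, dtype=float).ravel()
    for name, L in (("rg_length", rg_length), ("random_length", random_length)):
        if not spec.min_a <= L <= spec.max_a:
            raise ValueError(
                f"{name}={L} outside [{spec.min_a}, {spec.max_a}] for {spec}"
            )
    sign = None
    if spec.experiment == TREND:
        angle = trend_angles(values[None, : spec.min_a])[0]
        sign = INCREASING if angle >= 0 else DECREASING
    graphs = []
    for scheme, L in zip(SCHEMES, (spec.min_a, rg_length, random_length)):
        phase_a = values[:L].copy()
        phase_b = values[L : L + spec.n_b] + spec.effect_delta
        graphs.append(
            ABGraph(phase_a, phase_b, scheme, spec, series_id, sign)
        )
    return tuple(graphs)


@dataclass
class StudyDataset:
    """All series of one experiment, with per-series design metadata.

    ``values`` holds the raw 30-point latent series (no effect added);
    ``series`` holds one row per series: the factorial cell, the injected
    SMD, the three phase-A lengths, and bookkeeping flags.  Graphs are
    materialised on demand (:meth:`iter_graphs`) or consumed column-wise
    by the vectorised analyzers.
    """

    design: StudyDesign
    series: pd.DataFrame
    values: np.ndarray

    @property
    def experiment(self) -> str:
        return self.design.experiment

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def n_graphs(self) -> int:
        return 3 * len(self.series)

    def spec_for_row(self, row: pd.Series) -> ConditionSpec:
        return ConditionSpec(
            self.experiment,
            int(row["min_a"]),
            int(row["n_b"]),
            float(row["autocorr"]),  # bracket access: Series.autocorr is a method
            float(row["stability_threshold"]),
            int(row["smd"]),
        )

    def scheme_lengths(self, scheme: str) -> np.ndarray:
        if scheme == "fixed":
            return self.series["min_a"].to_numpy()
        if scheme == "response_guided":
            return self.series["rg_length"].to_numpy()
        if scheme == "random":
            return self.series["random_length"].to_numpy()
        raise ValueError(f"unknown scheme {scheme!r}")

    def iter_graphs(self) -> Iterator[ABGraph]:
        for _, row in self.series.iterrows():
            spec = self.spec_for_row(row)
            yield from build_graphs(
                self.values[int(row.series_id)],
                spec,
                int(row.rg_length),
                int(row.random_length),
                int(row.series_id),
            )


def build_study(design: StudyDesign) -> StudyDataset:
    """Generate the full counterbalanced factorial dataset for one experiment.

    Every factorial cell is generated from its own named random substream
    spawned from the master seed, so scaling one cell up or down does not
    perturb the others; the random-length permutation uses a second
    substream per cell.
    """
    root = np.random.SeedSequence(design.seed)
    gen_root, perm_root = root.spawn(2)
    cells = design.cells
    gen_streams = gen_root.spawn(len(cells))
    perm_streams = perm_root.spawn(len(cells))

    smds = np.repeat(
        np.arange(6),
        [design.n_series_per_cell_null] + [design.n_series_per_cell_per_smd] * 5,
    )

    frames = []
    blocks = []
    offset = 0
    for cell, gen_ss, perm_ss in zip(cells, gen_streams, perm_streams):
        n_cell = design.n_series_per_cell
        vals = sample_screened_batch(cell, n_cell, np.random.default_rng(gen_ss))
        rg, capped = response_guided_lengths(vals, cell)
        rnd = assign_random_lengths(rg, np.random.default_rng(perm_ss))
        frame = pd.DataFrame(
            {
                "series_id": offset + np.arange(n_cell),
                "cell_id": _cell_id(cell),
                "min_a": cell.min_a,
                "n_b": cell.n_b,
                "autocorr": cell.autocorr,
                "stability_threshold": cell.stability_threshold,
                "smd": smds,
                "rg_length": rg,
                "random_length": rnd,
                "rg_capped": capped,
            }
        )
        if design.experiment == TREND:
            angles = trend_angles(vals[:, : cell.min_a])
            frame["initial_trend_sign"] = np.where(angles >= 0, INCREASING, DECREASING)
        else:
            frame["initial_trend_sign"] = pd.NA
        frames.append(frame)
        blocks.append(vals)
        offset += n_cell
    series = pd.concat(frames, ignore_index=True)
    return StudyDataset(design, series, np.vstack(blocks))


def _cell_id(cell: ConditionSpec) -> str:
    return (
        f"a{cell.min_a}_b{cell.n_b}_ac{cell.autocorr:g}_"
        f"thr{cell.stability_threshold:g}"
    )
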