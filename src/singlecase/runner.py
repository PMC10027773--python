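"""End-to-end experiment orchestration.

``run_experiment`` reproduces one full experiment from a single config:
generate the counterbalanced factorial dataset, build the three matched
AB graphs per series, apply the requested analyzers, and produce the
overall and per-factor rate tables plus a JSON manifest (config, seed,
library versions, row counts, output digests).  Everything is a pure
function of (config, seed): per-cell random substreams are spawned from
the master seed, and the surrogate classifier trains on its own
independent substream and corpus.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cdc import DEFAULT_ALPHA, cdc_effects
from .evaluation import (
    compute_rates,
    plot_rate_bars,
    round_rates,
    stratified_report,
    trend_direction_report,
)
from .generator import TREND, UNIFORM_SMD_SCALE, VARIABILITY
from .phases import SCHEMES, StudyDataset, StudyDesign, build_study
from .svc import SVCModel, extract_features_batch, train_default_surrogate

logger = logging.getLogger(__name__)

METHODS = ("cdc", "svc")

#: Full-scale replicate counts per factorial cell (scale = 1.0).
FULL_SCALE_NULL_PER_CELL = 5000
FULL_SCALE_PER_SMD_PER_CELL = 1000

STRATA_FACTORS = ("min_a", "n_b", "autocorr", "stability_threshold", "smd")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end experiment run.

    ``scale`` multiplies the full-scale replicate counts (1.0 means
    160,000 series; 0.02 — the quick-look default of the command-line
    tool — means 3,200 series, keeping the Monte Carlo standard error of
    any reported rate below 0.01).
    """

    experiment: str = TREND
    scale: float = 1.0
    seed: int = 0
    methods: tuple[str, ...] = METHODS
    output_dir: str | None = None
    alpha: float = DEFAULT_ALPHA
    svc_corpus_graphs: int = 40_000
    pooled_z: bool = True
    continue_session_index: bool = False
    write_decisions: bool = False
    figures: bool = False

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if not self.methods:
            raise ValueError("at least one analysis method is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def design(self) -> StudyDesign:
        n_per_smd = max(1, round(FULL_SCALE_PER_SMD_PER_CELL * self.scale))
        study_seed, _ = _child_seeds(self.seed)
        return StudyDesign(
            self.experiment,
            n_series_per_cell_null=5 * n_per_smd,
            n_series_per_cell_per_smd=n_per_smd,
            seed=study_seed,
        )


def _child_seeds(seed: int) -> tuple[int, int]:
    """Independent (study, svc-training) seeds derived from the master seed."""
    state = np.random.SeedSequence(seed).generate_state(2)
    return int(state[0]), int(state[1])


def graph_arrays(
    dataset: StudyDataset, schemes: Sequence[str] = SCHEMES
) -> Iterator[tuple[str, int, np.ndarray, np.ndarray, np.ndarray]]:
    """Iterate the dataset's graphs as dense equal-shape stacks.

    Yields ``(scheme, phase_a_length, row_indices, phase_a, phase_b)``
    for every (scheme, phase-length, phase-B-length) group, with the
    effect delta already added to phase B.  This is the fast path the
    vectorised analyzers consume; ``StudyDataset.iter_graphs`` yields
    the same graphs one at a time.
    """
    values = dataset.values
    smd = dataset.series["smd"].to_numpy()
    n_b_col = dataset.series["n_b"].to_numpy()
    scale = UNIFORM_SMD_SCALE if dataset.experiment == VARIABILITY else 1.0
    delta = smd * scale
    for scheme in schemes:
        lengths = dataset.scheme_lengths(scheme)
        for L, nb in sorted(set(zip(lengths.tolist(), n_b_col.tolist()))):
            rows = np.nonzero((lengths == L) & (n_b_col == nb))[0]
            a2d = values[rows, :L]
            b2d = values[rows, L : L + nb] + delta[rows, None]
            yield scheme, L, rows, a2d, b2d


def analyze_dataset(
    dataset: StudyDataset,
    methods: Sequence[str] = ("cdc",),
    svc_model: SVCModel | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, int]:
    """Apply the requested analyzers to every graph of the dataset.

    Returns a long decisions frame (one row per graph per method, with
    all design factors) and the number of graphs excluded because an
    analyzer raised on them (degenerate graphs; counted, logged and
    dropped).
    """
    if "svc" in methods and svc_model is None:
        raise ValueError("svc analysis requested but no model supplied")
    n = dataset.n_series
    effects: dict[tuple[str, str], np.ndarray] = {}
    excluded: dict[tuple[str, str], np.ndarray] = {}
    for scheme, _, rows, a2d, b2d in graph_arrays(dataset):
        if "cdc" in methods:
            eff = effects.setdefault(("cdc", scheme), np.zeros(n, dtype=bool))
            eff[rows] = cdc_effects(a2d, b2d, alpha)
        if "svc" in methods:
            feats = extract_features_batch(
                a2d, b2d, svc_model.pooled_z, svc_model.continue_session_index
            )
            bad = np.isnan(feats).any(axis=1)
            eff = effects.setdefault(("svc", scheme), np.zeros(n, dtype=bool))
            mask = excluded.setdefault(("svc", scheme), np.zeros(n, dtype=bool))
            if bad.any():
                mask[rows[bad]] = True
            good = ~bad
            if good.any():
                eff[rows[good]] = svc_model.predict(feats[good])

    meta = dataset.series
    frames = []
    n_excluded = 0
    for (method, scheme), eff in sorted(effects.items()):
        frame = meta.copy()
        frame["scheme"] = scheme
        frame["a_len"] = dataset.scheme_lengths(scheme)
        frame["method"] = method
        frame["effect"] = eff
        bad = excluded.get((method, scheme))
        if bad is not None and bad.any():
            n_excluded += int(bad.sum())
            logger.warning(
                "excluded %d degenerate graphs (method=%s scheme=%s)",
                int(bad.sum()),
                method,
                scheme,
            )
            frame = frame[~bad]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True), n_excluded


@dataclass
class RunResult:
    """In-memory products of one experiment run."""

    config: RunConfig
    dataset: StudyDataset
    decisions: pd.DataFrame
    rates_overall: pd.DataFrame
    stratified: Mapping[str, pd.DataFrame]
    trend_direction: pd.DataFrame | None
    manifest: dict
    svc_model: SVCModel | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config: RunConfig) -> RunResult:
    """Run one experiment end to end; write tables if an output dir is set."""
    _, svc_seed = _child_seeds(config.seed)
    design = config.design()
    logger.info(
        "generating %s experiment: %d series (%d per cell)",
        config.experiment,
        design.n_series,
        design.n_series_per_cell,
    )
    dataset = build_study(design)

    svc_model = None
    if "svc" in config.methods:
        logger.info(
            "training surrogate SVC on %d graphs", config.svc_corpus_graphs
        )
        svc_model = train_default_surrogate(
            seed=svc_seed,
            experiment=config.experiment,
            n_graphs=config.svc_corpus_graphs,
            pooled_z=config.pooled_z,
            continue_session_index=config.continue_session_index,
        )

    decisions, n_excluded = analyze_dataset(
        dataset, config.methods, svc_model, config.alpha
    )
    rates = compute_rates(decisions)
    factors = list(STRATA_FACTORS)
    stratified = stratified_report(decisions, factors)
    trend_dir = (
        trend_direction_report(decisions) if config.experiment == TREND else None
    )

    manifest = {
        "package_version": __version__,
        "config": {**dataclasses.asdict(config), "methods": list(config.methods)},
        "seed": config.seed,
        "n_series": dataset.n_series,
        "n_graphs": dataset.n_graphs,
        "n_decisions": len(decisions),
        "n_excluded_graphs": n_excluded,
        "versions": _library_versions(),
        "outputs": {},
    }

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = {}
        tables = {"rates_overall.csv": rates}
        for factor, table in stratified.items():
            tables[f"rates_by_{factor}.csv"] = table
        if trend_dir is not None:
            tables["rates_by_initial_trend_sign.csv"] = trend_dir
        combined = pd.concat(
            [rates] + list(stratified.values()) + ([trend_dir] if trend_dir is not None else []),
            ignore_index=True,
        )
        tables["rates_long.csv"] = combined
        for name, table in tables.items():
            path = outdir / name
            round_rates(table).to_csv(path, index=False)
            written[name] = _sha256(path)
        if config.write_decisions:
            path = outdir / "decisions.csv"
            decisions.to_csv(path, index=False)
            written["decisions.csv"] = _sha256(path)
        if config.figures:
            fig = outdir / "fig_rates_overall.png"
            plot_rate_bars(rates, fig, title=f"{config.experiment} experiment")
            if trend_dir is not None:
                fig2 = outdir / "fig_trend_direction.png"
                plot_rate_bars(trend_dir, fig2, title="by initial trend direction")
        manifest["outputs"] = written
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunResult(
        config=config,
        dataset=dataset,
        decisions=decisions,
        rates_overall=rates,
        stratified=stratified,
        trend_direction=trend_dir,
        manifest=manifest,
        svc_model=svc_model,
    )


def _library_versions() -> dict:
    import sklearn
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
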