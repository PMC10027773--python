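"""CSV interchange for datasets, graphs and user-supplied AB data.

Two formats are supported:

* a two-column phase CSV (``phase,value`` with phase ``A``/``B``) for
  analysing a single user-supplied AB graph from the command line;
* a long-format dataset CSV (``series_id,cell_id,scheme,smd,phase,
  session,value``) plus a per-series design-manifest CSV for simulated
  studies.  Values are written with 17 significant digits so a write /
  read round-trip reproduces every float bit-exactly.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd

from .phases import StudyDataset
from .runner import graph_arrays

FLOAT_FORMAT = "%.17g"

GRAPH_COLUMNS = ["series_id", "cell_id", "scheme", "smd", "phase", "session", "value"]


def read_phases_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read one AB graph from a two-column ``phase,value`` CSV."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "phase" not in cols or "value" not in cols:
        raise ValueError(f"{path}: expected columns 'phase' and 'value'")
    phase = df[cols["phase"]].astype(str).str.strip().str.upper()
    bad = ~phase.isin(["A", "B"])
    if bad.any():
        raise ValueError(f"{path}: phase column must contain only 'A' or 'B'")
    values = df[cols["value"]].astype(float).to_numpy()
    return values[phase == "A"], values[phase == "B"]


def write_graphs_csv(dataset: StudyDataset, path) -> None:
    """Write every graph of a simulated study in long format."""
    parts = []
    series_ids = dataset.series["series_id"].to_numpy()
    cell_ids = dataset.series["cell_id"].to_numpy()
    smds = dataset.series["smd"].to_numpy()
    for scheme, L, rows, a2d, b2d in graph_arrays(dataset):
        n, n_b = b2d.shape
        graph = np.hstack([a2d, b2d])
        total = L + n_b
        parts.append(
            pd.DataFrame(
                {
                    "series_id": np.repeat(series_ids[rows], total),
                    "cell_id": np.repeat(cell_ids[rows], total),
                    "scheme": scheme,
                    "smd": np.repeat(smds[rows], total),
                    "phase": np.tile(["A"] * L + ["B"] * n_b, n),
                    "session": np.tile(np.arange(total), n),
                    "value": graph.ravel(),
                }
            )
        )
    long = pd.concat(parts, ignore_index=True)
    long = long.sort_values(["series_id", "scheme", "session"], kind="stable")
    long.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_graphs_csv(path) -> pd.DataFrame:
    """Read a long-format graphs CSV back into a DataFrame (bit-exact floats)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(GRAPH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_design_manifest(dataset: StudyDataset, path) -> None:
    """Write the per-series design table (factors, lengths, flags)."""
    dataset.series.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_design_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def iter_long_graphs(
    long: pd.DataFrame,
) -> Iterator[tuple[dict, np.ndarray, np.ndarray]]:
    """Yield ``(metadata, phase_a, phase_b)`` per graph of a long frame."""
    for (series_id, scheme), sub in long.groupby(["series_id", "scheme"], sort=True):
        sub = sub.sort_values("session")
        a = sub.loc[sub["phase"] == "A", "value"].to_numpy()
        b = sub.loc[sub["phase"] == "B", "value"].to_numpy()
        meta = {
            "series_id": series_id,
            "scheme": scheme,
            "cell_id": sub["cell_id"].iloc[0],
            "smd": sub["smd"].iloc[0],
        }
        yield meta, a, b


def analyze_long(
    long: pd.DataFrame,
    methods=("cdc",),
    svc_model=None,
    alpha: float = 0.05,
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-graph analysis of a long-format graphs frame (CSV pipeline path).

    Slower than the in-memory vectorised route but works on any dataset
    round-tripped through CSV.  If a design manifest is supplied its
    factor columns are merged onto the decisions.
    """
    from .cdc import cdc_decision
    from .svc import DegenerateGraphError, extract_features

    if "svc" in methods and svc_model is None:
        raise ValueError("svc analysis requested but no model supplied")
    rows = []
    for meta, a, b in iter_long_graphs(long):
        for method in methods:
            try:
                if method == "cdc":
                    effect = cdc_decision(a, b, alpha).effect
                else:
                    feats = extract_features(
                        a, b, svc_model.pooled_z, svc_model.continue_session_index
                    )
                    effect = bool(svc_model.predict(feats[None, :])[0])
            except (DegenerateGraphError, ValueError):
                continue
            rows.append({**meta, "method": method, "effect": effect})
    decisions = pd.DataFrame(rows)
    if design is not None:
        factor_cols = [
            c
            for c in design.columns
            if c not in ("smd", "cell_id") and c not in decisions.columns
        ]
        decisions = decisions.merge(
            design[["series_id", *factor_cols]], on="series_id", how="left"
        )
    return decisions
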