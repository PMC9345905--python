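"""Measured-versus-simulated fingertip force comparison arithmetic.

Force records carry, per grasping condition and finger, the load (vertical) force F_i, transverse
force F_j, grip (normal) force F_k (N) and the torsional moment M_k about the contact normal
(N m), all in the object-fixed coordinate system.  The comparison statistics are:

* delta   = simulated - measured, componentwise;
* accuracy = mean of the deltas over conditions;
* precision = sample (n-1 denominator) standard deviation of the deltas.

Reference force tables from the two-plate sensing-device experiment (six grasp conditions with
fingertip and finger-pulp grips, plus a free pinch) ship with the package as CSV fixtures.
"""

from __future__ import annotations

import io
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

COMPONENTS = ("F_i", "F_j", "F_k", "M_k")
KEYS = ["condition", "finger"]


def _read(source: str | Path | io.StringIO) -> pd.DataFrame:
    df = pd.read_csv(source, comment="#")
    missing = set(KEYS + list(COMPONENTS)) - set(df.columns)
    if missing:
        raise ValueError(f"force table missing columns: {sorted(missing)}")
    return df


def load_force_table(source: str | Path) -> pd.DataFrame:
    """Read a force-record CSV with columns condition, finger, F_i, F_j, F_k, M_k."""
    return _read(source)


def packaged_table(name: str) -> pd.DataFrame:
    """One of the packaged fixtures: table2_measured, table2_simulated, table2_deltas,
    table3_free_pinch."""
    text = resources.files("precigrip.data").joinpath(f"{name}.csv").read_text()
    df = pd.read_csv(io.StringIO(text), comment="#")
    return df


def compute_deltas(measured: pd.DataFrame, simulated: pd.DataFrame) -> pd.DataFrame:
    """Componentwise differences, simulated - measured, paired on (condition, finger)."""
    m = measured.set_index(KEYS)
    s = simulated.set_index(KEYS)
    if set(m.index) != set(s.index):
        raise KeyError("measured and simulated tables must share (condition, finger) keys")
    d = (s[list(COMPONENTS)] - m[list(COMPONENTS)]).loc[m.index]
    return d.reset_index()


def accuracy_precision(delta_column: np.ndarray | pd.Series) -> tuple[float, float]:
    """Mean (accuracy) and sample standard deviation (precision) of a delta column."""
    x = np.asarray(delta_column, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    return float(np.mean(x)), float(np.std(x, ddof=1))


def summarize_deltas(deltas: pd.DataFrame) -> pd.DataFrame:
    """Accuracy and precision per finger and component, one row per statistic."""
    out = []
    for finger, grp in deltas.groupby("finger", sort=False):
        for comp in COMPONENTS:
            acc, prec = accuracy_precision(grp[comp])
            out.append({"finger": finger, "component": comp, "accuracy": acc, "precision": prec})
    return pd.DataFrame(out)


def comparison_report(
    measured: pd.DataFrame, simulated: pd.DataFrame, use_deltas: pd.DataFrame | None = None
) -> dict[str, pd.DataFrame]:
    """Delta table plus accuracy/precision summary.

    ``use_deltas`` substitutes an externally supplied delta table (e.g. one differenced before
    rounding) for the recomputed one when computing the summary statistics.
    """
    deltas = compute_deltas(measured, simulated)
    summary = summarize_deltas(use_deltas if use_deltas is not None else deltas)
    return {"deltas": deltas, "summary": summary}
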