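"""Hand muscle force model.

37 intrinsic and extrinsic hand muscles, each generating force ``F_i = F_i_max * a_i`` from a
normalized activation ``a_i`` in [0, 1], and converting muscle forces into joint torques through a
constant moment-arm matrix::

    tau = M^T F_max a

where ``M`` is the 37 x 21 moment-arm matrix (meters), ``F_max`` the diagonal matrix of maximum
muscle forces (N) and ``a`` the activation vector.  Moment arms are treated as constant with
respect to joint angle; pennation and force-length/velocity scaling are deliberately absent.

The parameter table ships with the package as ``data/muscles.csv`` (arms in mm; positive means
flexion/adduction torque) and is the single source of truth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: The 21 actuated joint axes, in canonical order.  Thumb: first carpometacarpal (CMC1)
#: flexion-extension and adduction-abduction, first metacarpophalangeal (MP1) flexion-extension
#: and adduction-abduction, interphalangeal (IP1) flexion-extension.  Fingers 2-5: MP
#: flexion-extension, MP adduction-abduction, proximal interphalangeal (PIP) and distal
#: interphalangeal (DIP) flexion-extension.
JOINT_AXES: tuple[str, ...] = (
    "cmc1_fe", "cmc1_aa", "mp1_fe", "mp1_aa", "ip1_fe",
    "mp2_fe", "mp2_aa", "pip2_fe", "dip2_fe",
    "mp3_fe", "mp3_aa", "pip3_fe", "dip3_fe",
    "mp4_fe", "mp4_aa", "pip4_fe", "dip4_fe",
    "mp5_fe", "mp5_aa", "pip5_fe", "dip5_fe",
)

N_MUSCLES = 37
N_JOINTS = 21

#: Newtons of maximum muscle force per printed strength unit, for grasp synthesis.  The packaged
#: table's "max force" column is a normalized strength (tension-fraction) measure: e.g. flexor
#: pollicis longus is listed at 2.7, while its physiological maximum is near 75 N.  Reading the
#: column in newtons would leave the strongest possible index MP flexion torque several-fold
#: short of what any two-finger hold of a ~200 g object demands, so the synthesis pipeline
#: multiplies by this calibration (about 30 N per percent of total hand-muscle tension, the
#: classical tension-fraction conversion).  ``load_muscle_table`` defaults to the verbatim values
#: (scale 1.0); pass ``strength_scale=DEFAULT_STRENGTH_SCALE`` for mechanically realistic maxima.
DEFAULT_STRENGTH_SCALE = 30.0


@dataclass(frozen=True)
class Muscle:
    """A single muscle: maximum force and the (signed) moment arms of the axes it spans."""

    name: str
    abbreviation: str
    finger: str
    f_max: float  # N
    moment_arms_mm: dict[str, float] = field(default_factory=dict)  # axis -> arm [mm]

    def __post_init__(self) -> None:
        if not self.f_max > 0:
            raise ValueError(f"{self.abbreviation}: maximum force must be positive")
        unknown = set(self.moment_arms_mm) - set(JOINT_AXES)
        if unknown:
            raise ValueError(f"{self.abbreviation}: unknown joint axes {sorted(unknown)}")


@dataclass(frozen=True)
class MuscleSet:
    """The full muscle apparatus: 37 muscles and the assembled moment-arm matrix.

    Attributes
    ----------
    muscles:
        Muscle records in table order.
    moment_arm_matrix:
        ``M``, shape (37, 21), meters.  Entry (i, j) is the arm of muscle i about joint axis j;
        exactly zero where the muscle does not span the axis.
    f_max:
        Maximum forces, shape (37,), N (the diagonal of ``F_max``).
    """

    muscles: tuple[Muscle, ...]
    moment_arm_matrix: np.ndarray
    f_max: np.ndarray

    def __post_init__(self) -> None:
        if len(self.muscles) != N_MUSCLES:
            raise ValueError(f"expected {N_MUSCLES} muscles, got {len(self.muscles)}")
        if self.moment_arm_matrix.shape != (N_MUSCLES, N_JOINTS):
            raise ValueError("moment-arm matrix must be 37 x 21")

    def index_of(self, abbreviation: str) -> int:
        for i, m in enumerate(self.muscles):
            if m.abbreviation == abbreviation:
                return i
        raise KeyError(abbreviation)

    @property
    def abbreviations(self) -> list[str]:
        return [m.abbreviation for m in self.muscles]


def _packaged_csv() -> str:
    return resources.files("precigrip.data").joinpath("muscles.csv").read_text()


def load_muscle_table(source: str | Path | None = None, strength_scale: float = 1.0) -> MuscleSet:
    """Load the muscle parameter table and assemble the moment-arm matrix.

    Parameters
    ----------
    source:
        Path to a CSV with columns ``finger, no, name, abbreviation, f_max_N`` followed by one
        column per joint axis (arm in mm, blank where the muscle does not span the axis).
        ``None`` loads the packaged table.
    strength_scale:
        Multiplier applied to the maximum-force column (see :data:`DEFAULT_STRENGTH_SCALE`).
        The default 1.0 keeps the tabulated values.

    Returns
    -------
    MuscleSet with arms converted to meters in the matrix (the per-muscle records keep mm).
    """
    if source is None:
        text = _packaged_csv()
    else:
        text = Path(source).read_text()
    df = pd.read_csv(io.StringIO(text), comment="#")
    missing = {"finger", "name", "abbreviation", "f_max_N"} - set(df.columns)
    if missing:
        raise ValueError(f"muscle table missing columns: {sorted(missing)}")
    for axis in JOINT_AXES:
        if axis not in df.columns:
            raise ValueError(f"muscle table missing joint-axis column {axis!r}")
    if len(df) != N_MUSCLES:
        raise ValueError(f"muscle table must have {N_MUSCLES} rows, found {len(df)}")

    muscles = []
    M = np.zeros((N_MUSCLES, N_JOINTS))
    for i, row in df.iterrows():
        arms = {}
        for j, axis in enumerate(JOINT_AXES):
            v = row[axis]
            if pd.notna(v):
                arms[axis] = float(v)
                M[i, j] = float(v) * 1e-3  # mm -> m
        muscles.append(
            Muscle(
                name=str(row["name"]),
                abbreviation=str(row["abbreviation"]),
                finger=str(row["finger"]),
                f_max=float(row["f_max_N"]) * strength_scale,
                moment_arms_mm=arms,
            )
        )
    f_max = df["f_max_N"].to_numpy(dtype=float) * strength_scale
    return MuscleSet(muscles=tuple(muscles), moment_arm_matrix=M, f_max=f_max)


def export_muscle_table(path: str | Path) -> None:
    """Write the packaged muscle CSV to ``path`` byte-identically."""
    Path(path).write_text(_packaged_csv())


def _check_activations(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape != (N_MUSCLES,):
        raise ValueError(f"activations must have shape ({N_MUSCLES},)")
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValueError("activations must lie in [0, 1]")
    return np.clip(a, 0.0, 1.0)


def muscle_forces(muscle_set: MuscleSet, a: np.ndarray) -> np.ndarray:
    """Muscle forces ``F_i = F_i_max * a_i`` (N)."""
    a = _check_activations(a)
    return muscle_set.f_max * a


def joint_torques(muscle_set: MuscleSet, a: np.ndarray) -> np.ndarray:
    """Joint torques ``tau = M^T F_max a`` (N m), ordered as :data:`JOINT_AXES`."""
    a = _check_activations(a)
    return muscle_set.moment_arm_matrix.T @ (muscle_set.f_max * a)
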