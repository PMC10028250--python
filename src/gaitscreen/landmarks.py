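"""Reading, calibrating and normalizing pose-estimation landmark tables.

Input files follow the DeepLabCut CSV dialect: three header rows
(``scorer`` / ``bodyparts`` / ``coords``) and per landmark the columns
``x``, ``y``, ``likelihood``.  Seventeen landmarks describe a laterally
filmed quadruped: head (snout, eye, ear), back line (withers, croup,
tailbase), forelimb (scapula, shoulder, elbow, carpal, forefetlock,
forehoof) and hindlimb (hip, stifle, tarsal, hindfetlock, hindhoof).

Image coordinates grow downward; on read the y axis is flipped so that
"up" is positive and counter-clockwise angles are positive downstream.
Low-likelihood samples are kept as-is (with their likelihood); deciding
what to do with them is the segmentation stage's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical ordered landmark names.
LANDMARKS: tuple[str, ...] = (
    "snout", "eye", "ear",
    "withers", "croup", "tailbase",
    "scapula", "shoulder", "elbow", "carpal", "forefetlock", "forehoof",
    "hip", "stifle", "tarsal", "hindfetlock", "hindhoof",
)

#: Skeleton segments (connected landmark pairs): head chain, back line,
#: forelimb chain, hindlimb chain.  Used for bone-length plausibility
#: filtering, the size PCA and the dimensionless reference length.
SEGMENTS: tuple[tuple[str, str], ...] = (
    ("snout", "eye"), ("eye", "ear"), ("ear", "withers"),
    ("withers", "croup"), ("croup", "tailbase"),
    ("withers", "scapula"), ("scapula", "shoulder"), ("shoulder", "elbow"),
    ("elbow", "carpal"), ("carpal", "forefetlock"), ("forefetlock", "forehoof"),
    ("croup", "hip"), ("hip", "stifle"), ("stifle", "tarsal"),
    ("tarsal", "hindfetlock"), ("hindfetlock", "hindhoof"),
)

#: Landmark chain whose cumulated length is the dimensionless reference.
AXIS_CHAIN: tuple[str, ...] = ("snout", "eye", "ear", "withers", "croup", "tailbase")


class LandmarkTableError(ValueError):
    """Malformed landmark table (header dialect or missing landmarks)."""


@dataclass
class LandmarkTrajectories:
    """Calibrated 2-D landmark trajectories of one recording.

    Attributes
    ----------
    xy : ndarray, shape (n_frames, n_landmarks, 2)
        Calibrated coordinates in meters, y positive up.
    likelihood : ndarray, shape (n_frames, n_landmarks)
        Pose-estimation confidence in [0, 1].
    frame_rate : float
        Sampling rate in Hz.
    landmark_names : tuple of str
        Ordered landmark names (the canonical 17 unless subsetted).
    """

    xy: np.ndarray
    likelihood: np.ndarray
    frame_rate: float
    landmark_names: tuple[str, ...] = LANDMARKS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[2] != 2:
            raise ValueError("xy must have shape (n_frames, n_landmarks, 2)")
        if self.likelihood.shape != self.xy.shape[:2]:
            raise ValueError("likelihood shape must match xy frames x landmarks")
        finite = self.likelihood[np.isfinite(self.likelihood)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def time(self) -> np.ndarray:
        """Time axis in seconds (frame_index / frame_rate)."""
        return np.arange(self.n_frames) / self.frame_rate

    def index(self, name: str) -> int:
        try:
            return self.landmark_names.index(name)
        except ValueError as exc:
            raise KeyError(f"unknown landmark {name!r}") from exc

    def point(self, name: str) -> np.ndarray:
        """(n_frames, 2) trajectory of one landmark."""
        return self.xy[:, self.index(name), :]

    def segment_lengths(self, segments: tuple[tuple[str, str], ...] = SEGMENTS) -> pd.DataFrame:
        """Frame-wise Euclidean length of each skeleton segment (meters)."""
        data = {
            f"{a}-{b}": np.linalg.norm(self.point(a) - self.point(b), axis=1)
            for a, b in segments
        }
        return pd.DataFrame(data)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: frame, time, landmark, x, y, likelihood."""
        frames = np.repeat(np.arange(self.n_frames), len(self.landmark_names))
        names = np.tile(np.asarray(self.landmark_names, dtype=object), self.n_frames)
        return pd.DataFrame(
            {
                "frame": frames,
                "time": frames / self.frame_rate,
                "landmark": names,
                "x": self.xy[:, :, 0].ravel(),
                "y": self.xy[:, :, 1].ravel(),
                "likelihood": self.likelihood.ravel(),
            }
        )


def read_landmark_table(
    path,
    frame_rate: float = 50.0,
    scale: float = 1.0,
    flip_y: bool = True,
    required: tuple[str, ...] = LANDMARKS,
) -> LandmarkTrajectories:
    """Read a DeepLabCut-dialect CSV into calibrated trajectories.

    Parameters
    ----------
    path : str or Path
        CSV with the three-row header (scorer / bodyparts / coords).
    frame_rate : float
        Recording rate in Hz (default 50).
    scale : float
        Calibration factor in meters per pixel (chessboard calibration is
        performed upstream; this is its scalar result).
    flip_y : bool
        Flip the image y axis so up is positive (default True).
    required : tuple of str
        Landmark names that must all be present; a missing one is a hard
        error naming the absentees.
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, IndexError) as exc:
        raise LandmarkTableError(f"malformed landmark table header in {path}: {exc}") from exc
    if df.columns.nlevels != 3:
        raise LandmarkTableError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    coords = set(df.columns.get_level_values(2))
    if not coords <= {"x", "y", "likelihood"}:
        raise LandmarkTableError(f"{path}: coords row must contain only x/y/likelihood, got {sorted(coords)}")
    missing = [name for name in required if name not in bodyparts]
    if missing:
        raise LandmarkTableError(f"{path}: missing required landmarks: {', '.join(missing)}")

    scorer = df.columns.get_level_values(0)[0]
    n = len(df)
    xy = np.empty((n, len(required), 2))
    lik = np.ones((n, len(required)))
    for j, name in enumerate(required):
        xy[:, j, 0] = df[(scorer, name, "x")].to_numpy(dtype=float) * scale
        y = df[(scorer, name, "y")].to_numpy(dtype=float) * scale
        xy[:, j, 1] = -y if flip_y else y
        if (scorer, name, "likelihood") in df.columns:
            lik[:, j] = df[(scorer, name, "likelihood")].to_numpy(dtype=float)
    if flip_y:
        # shift so the lowest point is at y = 0; offsets are irrelevant for
        # angles and distances but keep coordinates readable
        xy[:, :, 1] -= np.nanmin(xy[:, :, 1])
    return LandmarkTrajectories(
        xy=xy,
        likelihood=np.clip(lik, 0.0, 1.0),
        frame_rate=frame_rate,
        landmark_names=tuple(required),
        meta={"source": str(path), "scale": scale, "scorer": scorer},
    )


def write_landmark_table(traj: LandmarkTrajectories, path, scale: float = 1.0, scorer: str = "gaitscreen") -> None:
    """Write trajectories back to the DeepLabCut CSV dialect.

    Coordinates are divided by ``scale`` (m/px) and the y axis is written
    image-style (growing downward), the inverse of :func:`read_landmark_table`.
    """
    cols = pd.MultiIndex.from_tuples(
        [(scorer, name, c) for name in traj.landmark_names for c in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    y_img = -traj.xy[:, :, 1]
    y_img = y_img - y_img.min()
    data = np.empty((traj.n_frames, 3 * len(traj.landmark_names)))
    data[:, 0::3] = traj.xy[:, :, 0] / scale
    data[:, 1::3] = y_img / scale
    data[:, 2::3] = traj.likelihood
    pd.DataFrame(data, columns=cols).to_csv(path, index_label="frame")


def mirror_horizontal(traj: LandmarkTrajectories, extent: float | None = None) -> LandmarkTrajectories:
    """Mirror trajectories so leftward movement becomes rightward.

    x is mapped to ``extent - x``; if ``extent`` is not given, the
    reflection axis is placed at the recording's own x range
    (``min + max``), which makes the map an exact involution.  All
    inter-landmark distances are preserved; angle signs flip, which is
    exactly the desired effect: the mirrored animal is analyzed as if it
    walked rightward.
    """
    xy = traj.xy.copy()
    if extent is None:
        extent = float(np.nanmin(xy[:, :, 0]) + np.nanmax(xy[:, :, 0]))
    xy[:, :, 0] = extent - xy[:, :, 0]
    return replace(traj, xy=xy, likelihood=traj.likelihood.copy(), meta={**traj.meta, "mirrored": not traj.meta.get("mirrored", False)})
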