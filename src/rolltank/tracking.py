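"""Particle detection and linking in image sequences, plus a synthetic
frame renderer for closed-loop validation.

The experimental validation of the device films slowly moving aggregates
and traces each particle's displacement across a short image series.  This
module provides the computational counterpart: Gaussian-spot rendering of
simulated trajectories onto a chosen projection plane, thresholded
connected-component detection with intensity-weighted (sub-pixel)
centroids, and greedy nearest-neighbour frame-to-frame linking.  Stereo
reconstruction is out of scope; only 2-D projections are tracked.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import measure

from .analysis import DisplacementStat, axial_displacement_stat
from .dynamics import Trajectory

__all__ = [
    "FrameSpec",
    "Track",
    "render_frames",
    "detect_particles",
    "link_tracks",
    "tracks_to_trajectories",
    "axial_stat_from_tracks",
    "save_frames",
    "load_frames",
    "write_tracks",
    "read_tracks",
]


@dataclass(frozen=True)
class FrameSpec:
    """Synthetic camera model for rendering trajectories to frames.

    Frames are (height, width) float arrays.  ``plane="yz"`` maps the axial
    coordinate z to the image column and y to the row (up = -row);
    ``plane="xy"`` maps x to the column and y to the row.  ``center_world``
    is the world point projected onto the image centre.  The defaults
    (512 x 768 px at 0.2 mm/px) frame the mid-tank region where ensembles
    are seeded; they are synthetic stand-ins, no real camera is modelled.
    """

    shape: tuple[int, int] = (512, 768)
    scale: float = 2.0e-4  # m per px
    plane: str = "yz"
    center_world: tuple[float, float, float] = (0.0, 0.0, 0.135)
    background: float = 10.0
    spot_peak: float = 200.0
    spot_sigma_px: float = 2.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.spot_sigma_px < 0.5:
            raise ValueError("spot sigma must be at least half a pixel")
        if self.plane not in ("xy", "yz"):
            raise ValueError(f"unknown projection plane {self.plane!r}")

    def project(self, position) -> tuple[float, float]:
        """World position (m) -> sub-pixel (row, col)."""
        x, y, z = np.asarray(position, dtype=float) - np.asarray(self.center_world)
        horiz = z if self.plane == "yz" else x
        col = self.shape[1] / 2.0 + horiz / self.scale
        row = self.shape[0] / 2.0 - y / self.scale
        return row, col

    def unproject(self, row: float, col: float) -> tuple[float, float]:
        """(row, col) -> the two in-plane world coordinates (m).

        Returns (y, z) for the yz plane, (x, y) for the xy plane.
        """
        y = (self.shape[0] / 2.0 - row) * self.scale + self.center_world[1]
        horiz = (col - self.shape[1] / 2.0) * self.scale
        if self.plane == "yz":
            return y, horiz + self.center_world[2]
        return horiz + self.center_world[0], y


def render_frames(
    trajectories: list[Trajectory],
    frame_spec: FrameSpec,
    times,
    rng_seed: int | None = None,
) -> np.ndarray:
    """Render an image stack (n_frames, H, W) of Gaussian spots.

    Each trajectory contributes one spot per frame at its (interpolated)
    projected position; out-of-frame particles are skipped with a warning.
    Gaussian pixel noise of sigma ``frame_spec.noise_sigma`` is added when
    non-zero; deterministic under a fixed ``rng_seed``.
    """
    times = np.asarray(times, dtype=float)
    H, W = frame_spec.shape
    stack = np.full((len(times), H, W), frame_spec.background, dtype=float)
    sigma = frame_spec.spot_sigma_px
    win = max(3, int(math.ceil(4.0 * sigma)))
    for tr in trajectories:
        pos = tr.position_at(times)
        for k in range(len(times)):
            row, col = frame_spec.project(pos[k])
            if not (0 <= row < H and 0 <= col < W):
                warnings.warn(
                    f"particle at frame {k} projects outside the image; skipped",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            r0, r1 = max(0, int(row) - win), min(H, int(row) + win + 1)
            c0, c1 = max(0, int(col) - win), min(W, int(col) + win + 1)
            rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
            stack[k, r0:r1, c0:c1] += frame_spec.spot_peak * np.exp(
                -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma**2)
            )
    if frame_spec.noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        stack += rng.normal(0.0, frame_spec.noise_sigma, size=stack.shape)
    return stack


def detect_particles(frame: np.ndarray, threshold: float) -> list[tuple[float, float, float]]:
    """Sub-pixel spot centroids in a grayscale frame.

    Pixels at or above *threshold* are grouped into connected components;
    each component yields an intensity-weighted centroid (weights are the
    above-threshold excess, which cancels a uniform background) and its
    integrated intensity.  Returns a list of (row, col, intensity).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("expected a 2-D grayscale frame")
    mask = frame >= threshold
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    out = []
    excess = np.where(mask, frame - threshold, 0.0)
    for region in measure.regionprops(labels, intensity_image=excess):
        weights = region.image_intensity
        total = float(weights.sum())
        if total <= 0:
            continue
        rr, cc = np.nonzero(region.image)
        row = float(np.sum((rr + region.bbox[0]) * weights[rr, cc]) / total)
        col = float(np.sum((cc + region.bbox[1]) * weights[rr, cc]) / total)
        out.append((row, col, total))
    return out


@dataclass
class Track:
    """A linked particle track: ordered (frame, (row, col), intensity)."""

    track_id: int
    entries: list  # of (frame_index, (row, col), intensity)

    @property
    def frames(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries])

    @property
    def centroids(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


def link_tracks(centroid_lists, max_displacement_px: float) -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame linking.

    Candidate (track-end, centroid) pairs between consecutive frames are
    assigned in ascending order of distance (ties broken by track id then
    centroid index); no assignment beyond ``max_displacement_px``.
    Unmatched centroids start new tracks.  Adequate for sparse, slow
    scenes; crossing particles may swap identities.
    """
    tracks: list[Track] = []
    active: list[int] = []  # indices into tracks, open at the previous frame
    for frame_idx, centroids in enumerate(centroid_lists):
        centroids = list(centroids)
        pairs = []
        for ai, ti in enumerate(active):
            last = np.asarray(tracks[ti].entries[-1][1])
            for ci, c in enumerate(centroids):
                d = math.hypot(last[0] - c[0], last[1] - c[1])
                if d <= max_displacement_px:
                    pairs.append((d, ti, ci))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_tracks: set[int] = set()
        used_cents: set[int] = set()
        for d, ti, ci in pairs:
            if ti in used_tracks or ci in used_cents:
                continue
            row, col, inten = centroids[ci]
            tracks[ti].entries.append((frame_idx, (row, col), inten))
            used_tracks.add(ti)
            used_cents.add(ci)
        new_active = list(used_tracks)
        for ci, c in enumerate(centroids):
            if ci in used_cents:
                continue
            tracks.append(Track(len(tracks), [(frame_idx, (c[0], c[1]), c[2])]))
            new_active.append(len(tracks) - 1)
        active = sorted(new_active)
    return tracks


def tracks_to_trajectories(
    tracks: list[Track], frame_spec: FrameSpec, times
) -> list[Trajectory]:
    """Convert image-plane tracks back to world-coordinate trajectories.

    The out-of-plane coordinate is unobserved and set to 0; axial analyses
    (which use z in the yz projection) are unaffected.
    """
    times = np.asarray(times, dtype=float)
    out = []
    for tr in tracks:
        frames = tr.frames
        pos = np.zeros((len(frames), 3))
        for i, (row, col) in enumerate(tr.centroids):
            a, b = frame_spec.unproject(row, col)
            if frame_spec.plane == "yz":
                pos[i, 1], pos[i, 2] = a, b
            else:
                pos[i, 0], pos[i, 1] = a, b
        out.append(
            Trajectory(
                times=times[frames],
                positions=pos,
                velocities=np.zeros_like(pos),
                metadata={"source": "tracking", "track_id": tr.track_id},
            )
        )
    return out


def axial_stat_from_tracks(
    tracks: list[Track],
    frame_spec: FrameSpec,
    times,
    window_s: float = 30.0,
    sample_interval_s: float = 1.0,
    min_length: int | None = None,
) -> DisplacementStat:
    """The axial displacement statistic computed from linked image tracks.

    Only tracks spanning the full window (or at least ``min_length``
    frames) are used, mirroring the practice of selecting particles
    traceable across the whole image series.
    """
    times = np.asarray(times, dtype=float)
    if min_length is None:
        min_length = len(times)
    trajs = [
        t
        for t in tracks_to_trajectories(tracks, frame_spec, times)
        if len(t.times) >= min_length
    ]
    if not trajs:
        raise ValueError("no track spans the requested window")
    return axial_displacement_stat(trajs, window_s, sample_interval_s)


# -- image and track I/O ---------------------------------------------------


def save_frames(stack: np.ndarray, directory, prefix: str = "frame", bit_depth: int = 8):
    """Write a stack as lexicographically ordered grayscale PNGs."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    full = float(np.iinfo(dtype).max)
    paths = []
    for k, frame in enumerate(stack):
        img = np.clip(frame, 0.0, full).astype(dtype)
        p = directory / f"{prefix}_{k:04d}.png"
        iio.imwrite(p, img)
        paths.append(p)
    return paths


def load_frames(directory, pattern: str = "*.png") -> np.ndarray:
    """Read a lexicographically ordered grayscale image stack."""
    import imageio.v3 as iio

    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no {pattern} images in {directory}")
    return np.stack([np.asarray(iio.imread(p), dtype=float) for p in paths])


def write_tracks(tracks: list[Track], path):
    import pandas as pd

    rows = [
        {
            "track_id": t.track_id,
            "frame": f,
            "x_px": c[1],
            "y_px": c[0],
            "intensity": inten,
        }
        for t in tracks
        for (f, c, inten) in t.entries
    ]
    pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px", "intensity"]).to_csv(
        path, index=False
    )


def read_tracks(path) -> list[Track]:
    import pandas as pd

    df = pd.read_csv(path)
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        entries = [
            (int(r.frame), (float(r.y_px), float(r.x_px)), float(r.intensity))
            for r in g.sort_values("frame").itertuples()
        ]
        tracks.append(Track(int(tid), entries))
    return tracks
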