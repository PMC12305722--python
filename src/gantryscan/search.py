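"""Optimal-slice search: zigzag angular sweeps nested in a coarse-to-fine
linear scan, plus the exhaustive oracle, linear-vs-angular comparison and
coverage analysis.

The search variable is a :class:`~gantryscan.geometry.ProbePose`.  At each
rail station the probe first captures the untilted slice (score ``lprob``),
then serpentines through the pitch-roll lattice ``(alpha*i, alpha*j)`` for
``i, j`` in ``[-s_theta, s_theta]`` (best angular score ``aprob``).  After a
full round of stations the linear step is divided by ``refine_factor`` and a
window around the incumbent best position is rescanned, until the step drops
below ``epsilon``.  The result is the pose ``Lmax`` with the maximum
tumor-presence probability ``Pmax``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import ValidationError, pose_key, stable_seed
from .bmode import BModeImage, acquire
from .geometry import (
    GantryGeometry,
    ProbePose,
    enumerate_stations,
    pose_to_plane,
)
from .phantom import Phantom

__all__ = [
    "ScanConfig",
    "SweepTrace",
    "StationResult",
    "RoundSummary",
    "ScanResult",
    "zigzag_indices",
    "angular_sweep",
    "station_scan",
    "optimal_slice_search",
    "brute_force_search",
    "compare_linear_angular",
    "coverage_map",
    "LesionDetection",
    "ComparisonReport",
]


@dataclass(frozen=True)
class ScanConfig:
    """All search parameters.

    ``slin0`` is the initial linear step (mm) and ``nstep`` the number of
    round-0 stations starting at ``x_start``.  The angular sweep covers
    pitch and roll ``alpha * i`` for ``i`` in ``[-s_theta, s_theta]``
    (``alpha`` defaults to the gantry's 2-degree step resolution), bounded
    by ``theta_max`` / ``phi_max``.  Refinement divides the step by
    ``refine_factor`` each round and stops once the step falls below
    ``epsilon``.  ``detection_threshold`` is the probability above which a
    lesion counts as detected.
    """

    slin0: float = 10.0
    nstep: int = 13
    s_theta: int = 7
    alpha: float = 2.0
    epsilon: float = 2.0
    theta_max: float = 16.0
    phi_max: float = 16.0
    refine_factor: float = 2.0
    detection_threshold: float = 0.5
    x_start: float = 10.0
    pixel_spacing: float = 1.0
    attenuation_coeff: float = 0.01
    gain: float = 50.0
    speckle: bool = True

    def validate(self) -> None:
        if not self.slin0 > self.epsilon > 0:
            raise ValidationError(
                f"need slin0 > epsilon > 0, got slin0={self.slin0}, "
                f"epsilon={self.epsilon}"
            )
        if self.nstep < 1:
            raise ValidationError("nstep must be >= 1")
        if self.s_theta < 0:
            raise ValidationError("s_theta must be >= 0")
        if self.alpha <= 0:
            raise ValidationError("alpha must be positive")
        if self.alpha * self.s_theta > min(self.theta_max, self.phi_max) + 1e-9:
            raise ValidationError(
                f"alpha*s_theta = {self.alpha * self.s_theta} deg exceeds the "
                f"gimbal bounds ({self.theta_max}, {self.phi_max}) deg"
            )
        if self.refine_factor <= 1:
            raise ValidationError("refine_factor must be > 1")
        if not 0.0 < self.detection_threshold < 1.0:
            raise ValidationError("detection_threshold must lie in (0, 1)")
        if self.pixel_spacing <= 0:
            raise ValidationError("pixel_spacing must be positive")


@dataclass
class PoseEval:
    """One scored acquisition in visit order."""

    pose: ProbePose
    probability: float
    round_index: int
    order: int
    lesion_probabilities: dict[int, float] = field(default_factory=dict)


@dataclass
class SweepTrace:
    """Record of one zigzag angular sweep."""

    d: int
    visited: list[tuple[int, int]]
    scores: list[float]
    aprob: float
    theta_pos: float
    phi_pos: float


@dataclass
class StationResult:
    x: float
    lprob: float
    trace: SweepTrace | None
    best_pose: ProbePose
    best_score: float


@dataclass
class RoundSummary:
    step: float
    window: tuple[float, float]
    stations: list[float]
    best_pose: ProbePose
    best_score: float
    n_evaluations: int


@dataclass
class ScanResult:
    evaluations: list[PoseEval]
    rounds: list[RoundSummary]
    Lmax: ProbePose
    Pmax: float
    lprob_per_station: list[tuple[float, float]]
    mode: str = "angular"

    @property
    def n_evaluations(self) -> int:
        return len(self.evaluations)


def zigzag_indices(s_theta: int, d: int) -> list[tuple[int, int]]:
    """Serpentine traversal of the pitch-roll index lattice.

    The primary (pitch) range ``P`` runs ``-s..+s`` when the direction
    indicator ``d`` is 1 and is reversed when ``d`` is 0; for the r-th value
    of ``P`` the secondary (roll) range runs forward when ``r`` is even and
    backward when odd, so consecutive poses always differ by a single
    one-step servo move.
    """
    if d not in (0, 1):
        raise ValidationError("direction indicator d must be 0 or 1")
    s = int(s_theta)
    P = list(range(-s, s + 1)) if d == 1 else list(range(s, -s - 1, -1))
    out: list[tuple[int, int]] = []
    for r, i in enumerate(P):
        R = list(range(-s, s + 1))
        if r % 2 == 1:
            R.reverse()
        out.extend((i, j) for j in R)
    return out


class _Evaluator:
    """Renders and scores poses with memoization keyed on the pose lattice.

    The per-pose speckle seed is derived from the global seed and the pose
    key (not the visit order), so a pose scores identically no matter when
    or how often it is visited.
    """

    def __init__(self, phantom: Phantom, geometry: GantryGeometry,
                 scorer, config: ScanConfig, seed: int):
        self.phantom = phantom
        self.geometry = geometry
        self.scorer = scorer
        self.config = config
        self.seed = int(seed)
        self._cache: dict[tuple, tuple[float, dict]] = {}
        self.evaluations: list[PoseEval] = []

    def image(self, pose: ProbePose) -> BModeImage:
        key = pose_key(pose.x, pose.pitch, pose.roll)
        return acquire(
            self.phantom, pose, self.geometry,
            pixel_spacing=self.config.pixel_spacing,
            attenuation_coeff=self.config.attenuation_coeff,
            noise_seed=stable_seed(self.seed, "speckle", key),
            speckle=self.config.speckle,
            gain=self.config.gain,
        )

    def score(self, pose: ProbePose) -> tuple[float, dict]:
        key = pose_key(pose.x, pose.pitch, pose.roll)
        if key not in self._cache:
            out = self.scorer(self.image(pose))
            per_lesion = dict(out.lesion_probabilities or {})
            self._cache[key] = (float(out.probability), per_lesion)
        return self._cache[key]

    def record(self, pose: ProbePose, round_index: int) -> float:
        prob, per_lesion = self.score(pose)
        self.evaluations.append(PoseEval(
            pose=pose, probability=prob, round_index=round_index,
            order=len(self.evaluations), lesion_probabilities=per_lesion,
        ))
        return prob


def angular_sweep(
    x: float,
    config: ScanConfig,
    geometry: GantryGeometry,
    phantom: Phantom,
    scorer,
    d: int,
    seed: int = 0,
    _evaluator: _Evaluator | None = None,
    _round: int = 0,
) -> SweepTrace:
    """Zigzag sweep of the full pitch-roll lattice at one station.

    Returns the visit order, per-pose scores, the best angular score
    ``aprob`` and its angles ``(theta_pos, phi_pos)``; ties are broken in
    favor of the first-visited pose.
    """
    config.validate()
    ev = _evaluator or _Evaluator(phantom, geometry, scorer, config, seed)
    visited = zigzag_indices(config.s_theta, d)
    scores: list[float] = []
    aprob = -1.0
    theta_pos = phi_pos = 0.0
    for (i, j) in visited:
        pose = ProbePose(x=x, pitch=config.alpha * i, roll=config.alpha * j)
        prob = ev.record(pose, _round)
        scores.append(prob)
        if prob > aprob:
            aprob = prob
            theta_pos, phi_pos = pose.pitch, pose.roll
    return SweepTrace(d=d, visited=visited, scores=scores,
                      aprob=max(aprob, 0.0), theta_pos=theta_pos, phi_pos=phi_pos)


def station_scan(
    x: float,
    config: ScanConfig,
    geometry: GantryGeometry,
    phantom: Phantom,
    scorer,
    station_index: int,
    seed: int = 0,
    angular: bool = True,
    _evaluator: _Evaluator | None = None,
    _round: int = 0,
) -> StationResult:
    """Acquire the untilted slice at a station, then (in angular mode) sweep
    the gimbal lattice with direction ``d = station_index mod 2``.

    The station's best pose is the untilted one whenever ``lprob >= aprob``
    (linear wins exact ties); otherwise the sweep's argmax angles.
    """
    config.validate()
    ev = _evaluator or _Evaluator(phantom, geometry, scorer, config, seed)
    zero_pose = ProbePose(x=x, pitch=0.0, roll=0.0)
    lprob = ev.record(zero_pose, _round)
    if not angular or config.s_theta == 0:
        return StationResult(x=x, lprob=lprob, trace=None,
                             best_pose=zero_pose, best_score=lprob)
    trace = angular_sweep(x, config, geometry, phantom, scorer,
                          d=station_index % 2, _evaluator=ev, _round=_round)
    if lprob >= trace.aprob:
        return StationResult(x=x, lprob=lprob, trace=trace,
                             best_pose=zero_pose, best_score=lprob)
    best = ProbePose(x=x, pitch=trace.theta_pos, roll=trace.phi_pos)
    return StationResult(x=x, lprob=lprob, trace=trace,
                         best_pose=best, best_score=trace.aprob)


def _refinement_stations(center: float, prev_step: float, step: float,
                         geometry: GantryGeometry) -> list[float]:
    """Stations ``center + m*step`` covering the window ``center +/- prev_step``,
    clipped to the rail; the incumbent position is always revisited."""
    m_max = int(round(prev_step / step))
    xs = [center + m * step for m in range(-m_max, m_max + 1)]
    return [x for x in xs if -1e-9 <= x <= geometry.rail_length + 1e-9]


def optimal_slice_search(
    config: ScanConfig,
    geometry: GantryGeometry,
    phantom: Phantom,
    scorer,
    seed: int = 0,
    angular: bool = True,
) -> ScanResult:
    """Two-level search for the pose maximizing the tumor-presence score.

    Round 0 scans ``nstep`` stations at step ``slin0`` (each station runs
    :func:`station_scan`).  Each later round halves the step (divides by
    ``refine_factor``), recentring a window of half-width equal to the
    previous step on the incumbent best rail position, and rescans; rounds
    continue while the step is at least ``epsilon``.  Revisited poses hit a
    score cache, so the best-of-round sequence is non-decreasing and the
    global tie-break remains first-visited.
    """
    config.validate()
    stations0 = enumerate_stations(config.x_start, config.slin0, config.nstep, geometry)
    ev = _Evaluator(phantom, geometry, scorer, config, seed)

    best_pose: ProbePose | None = None
    best_score = -1.0
    rounds: list[RoundSummary] = []
    lprob_per_station: list[tuple[float, float]] = []
    station_counter = 0

    step = float(config.slin0)
    stations = stations0
    window = (stations0[0], stations0[-1])
    round_index = 0
    while True:
        n_before = len(ev.evaluations)
        for x in stations:
            res = station_scan(
                x, config, geometry, phantom, scorer,
                station_index=station_counter, angular=angular,
                _evaluator=ev, _round=round_index,
            )
            station_counter += 1
            lprob_per_station.append((x, res.lprob))
            if res.best_score > best_score:
                best_score = res.best_score
                best_pose = res.best_pose
        rounds.append(RoundSummary(
            step=step, window=window, stations=list(stations),
            best_pose=best_pose, best_score=max(best_score, 0.0),
            n_evaluations=len(ev.evaluations) - n_before,
        ))
        prev_step = step
        step = step / config.refine_factor
        if step < config.epsilon - 1e-12:
            break
        center = best_pose.x
        stations = _refinement_stations(center, prev_step, step, geometry)
        window = (max(0.0, center - prev_step),
                  min(geometry.rail_length, center + prev_step))
        round_index += 1

    return ScanResult(
        evaluations=ev.evaluations,
        rounds=rounds,
        Lmax=best_pose,
        Pmax=max(best_score, 0.0),
        lprob_per_station=lprob_per_station,
        mode="angular" if angular else "linear",
    )


def brute_force_search(
    poses: list[ProbePose],
    geometry: GantryGeometry,
    phantom: Phantom,
    scorer,
    config: ScanConfig,
    seed: int = 0,
) -> tuple[ProbePose, float, list[float]]:
    """Exhaustive oracle: score every pose in the given finite lattice and
    return the exact argmax (first-visited wins ties) plus all scores.

    Uses the same per-pose seeding as the search, so a pose scores
    identically here and there."""
    if not poses:
        raise ValidationError("brute_force_search needs a nonempty pose lattice")
    ev = _Evaluator(phantom, geometry, scorer, config, seed)
    scores = []
    best_pose = poses[0]
    best_score = -1.0
    for pose in poses:
        prob, _ = ev.score(pose)
        scores.append(prob)
        if prob > best_score:
            best_score = prob
            best_pose = pose
    return best_pose, best_score, scores


@dataclass
class LesionDetection:
    label: int
    linear_probability: float
    angular_probability: float
    detected_linear: bool
    detected_angular: bool


@dataclass
class ComparisonReport:
    linear: ScanResult
    angular: ScanResult
    lesions: list[LesionDetection]
    detection_threshold: float


def _per_lesion_max(result: ScanResult, labels: list[int]) -> dict[int, float]:
    best = {k: 0.0 for k in labels}
    for ev in result.evaluations:
        for k, p in ev.lesion_probabilities.items():
            if k in best and p > best[k]:
                best[k] = p
    return best


def compare_linear_angular(
    config: ScanConfig,
    geometry: GantryGeometry,
    phantom: Phantom,
    scorer,
    seed: int = 0,
) -> ComparisonReport:
    """Run the search once with the gimbal locked (linear mode: every slice
    untilted) and once with full angular sweeps, and attribute detections
    per lesion via the per-slice lesion labels.

    A lesion with max probability below the detection threshold in a mode is
    flagged undetected in that mode — the scenario of interest being an
    off-axis lesion that no untilted plane intersects (linear probability
    exactly 0) but that the tilted sweep reaches.
    """
    labels = list(range(1, len(phantom.lesions) + 1))
    linear = optimal_slice_search(config, geometry, phantom, scorer,
                                  seed=seed, angular=False)
    angular = optimal_slice_search(config, geometry, phantom, scorer,
                                   seed=seed, angular=True)
    lin_best = _per_lesion_max(linear, labels)
    ang_best = _per_lesion_max(angular, labels)
    tau = config.detection_threshold
    lesions = [
        LesionDetection(
            label=k,
            linear_probability=lin_best[k],
            angular_probability=ang_best[k],
            detected_linear=lin_best[k] >= tau,
            detected_angular=ang_best[k] >= tau,
        )
        for k in labels
    ]
    return ComparisonReport(linear=linear, angular=angular,
                            lesions=lesions, detection_threshold=tau)


def coverage_map(
    poses: list[ProbePose],
    geometry: GantryGeometry,
    phantom: Phantom,
    voxel_stride: int = 1,
):
    """Voxel coverage of a set of acquired planes.

    A voxel counts as covered when its center lies within half the slice
    thickness of some acquired plane and inside that plane's image
    rectangle.  Returns ``(hit, tumor_fraction, total_fraction)`` where
    ``hit`` is a boolean array over the (optionally strided) voxel grid.

    ``voxel_stride`` subsamples the voxel grid for speed on large phantoms;
    fractions are then computed over the sampled centers.
    """
    if not poses:
        raise ValidationError("coverage_map needs at least one pose")
    stride = int(voxel_stride)
    axes = [
        phantom.origin[a] + np.arange(0, phantom.shape[a], stride) * phantom.spacing[a]
        for a in range(3)
    ]
    nx, ny, nz = (len(ax) for ax in axes)
    hit = np.zeros((nx, ny, nz), dtype=bool)
    X = axes[0]
    YZ = np.stack(np.meshgrid(axes[1], axes[2], indexing="ij"), axis=-1)  # (ny,nz,2)
    half = geometry.slice_thickness / 2.0
    hw = geometry.image_width / 2.0

    seen: set[tuple] = set()
    for pose in poses:
        key = pose_key(pose.x, pose.pitch, pose.roll)
        if key in seen:
            continue
        seen.add(key)
        plane = pose_to_plane(pose, geometry)
        # conservative rail-axis band from the rectangle corners
        corners = np.array([
            plane.origin + su * plane.u + sv * plane.v
            for su in (-hw, hw) for sv in (0.0, geometry.image_depth)
        ])
        x_lo = corners[:, 0].min() - half
        x_hi = corners[:, 0].max() + half
        band = np.nonzero((X >= x_lo) & (X <= x_hi))[0]
        if band.size == 0:
            continue
        dyz = YZ - plane.origin[None, None, 1:]  # (ny,nz,2)
        for ix in band:
            dx = X[ix] - plane.origin[0]
            dist = np.abs(dx * plane.n[0] + dyz[..., 0] * plane.n[1]
                          + dyz[..., 1] * plane.n[2])
            su = dx * plane.u[0] + dyz[..., 0] * plane.u[1] + dyz[..., 1] * plane.u[2]
            sv = dx * plane.v[0] + dyz[..., 0] * plane.v[1] + dyz[..., 1] * plane.v[2]
            inside = (dist <= half) & (np.abs(su) <= hw) & (sv >= 0.0) \
                & (sv <= geometry.image_depth)
            hit[ix] |= inside

    lesion = phantom.labels[::stride, ::stride, ::stride] > 0
    n_lesion = int(lesion.sum())
    tumor_fraction = float(hit[lesion].sum()) / n_lesion if n_lesion else 0.0
    total_fraction = float(hit.sum()) / hit.size
    return hit, tumor_fraction, total_fraction
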