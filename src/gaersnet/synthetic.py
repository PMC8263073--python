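"""Synthetic study data with known ground truth.

Emulates the structure of a bilateral 72-region rodent functional-imaging
study: an atlas of mirrored left/right regions in five functional groups
(sensorimotor cortex, association cortex, limbic system, thalamus, basal
ganglia), multi-subject ROI time series drawn from a block-structured
population correlation matrix with strong homotopic (left-right) coupling,
optional group-level edge effects (e.g. stronger intrathalamic coupling in
one group), and fluorescence Ca2+ traces in which ~6 Hz spike-and-wave
bursts alternate with rest epochs.

Every generator is fully seeded and returns its ground truth, so each
downstream stage (connectivity, graph metrics, communities, NBS, brain-state
classification) can be verified against what was planted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal

from .preprocess import RoiTimeSeries

__all__ = [
    "Region",
    "Atlas",
    "CommunitySpec",
    "TargetCorrelation",
    "CaTrace",
    "generate_atlas",
    "default_atlas",
    "default_study_spec",
    "target_correlation",
    "repair_psd",
    "generate_group_timeseries",
    "generate_ca_trace",
    "FUNCTIONAL_GROUPS",
    "DEFAULT_GROUP_SIZES",
]

FUNCTIONAL_GROUPS = (
    "sensorimotor",
    "association",
    "limbic",
    "thalamus",
    "basal_ganglia",
)

# per-hemisphere region counts; 2 x 36 = 72 regions in total
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "sensorimotor": 8,
    "association": 6,
    "limbic": 9,
    "thalamus": 8,
    "basal_ganglia": 5,
}

_GROUP_PREFIX = {
    "sensorimotor": "smc",
    "association": "assoc",
    "limbic": "limb",
    "thalamus": "thal",
    "basal_ganglia": "bg",
}


@dataclass(frozen=True)
class Region:
    abbreviation: str
    hemisphere: str  # "left" | "right"
    functional_group: str


@dataclass(frozen=True)
class Atlas:
    """Ordered bilateral region list; every region has a homotopic partner."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        regions = tuple(self.regions)
        abbrevs = [r.abbreviation for r in regions]
        if len(set(abbrevs)) != len(abbrevs):
            raise ValueError("region abbreviations must be unique")
        for r in regions:
            if r.hemisphere not in ("left", "right"):
                raise ValueError(f"bad hemisphere {r.hemisphere!r}")
            if r.functional_group not in FUNCTIONAL_GROUPS:
                raise ValueError(f"unknown functional group {r.functional_group!r}")
        object.__setattr__(self, "regions", regions)

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.abbreviation for r in self.regions)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(r.functional_group for r in self.regions)

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (left, right) of mirrored regions, by shared stem."""
        stems: dict[tuple[str, str], dict[str, int]] = {}
        for i, r in enumerate(self.regions):
            stem = r.abbreviation
            for suffix in ("_L", "_R"):
                if stem.endswith(suffix):
                    stem = stem[: -len(suffix)]
            stems.setdefault((stem, r.functional_group), {})[r.hemisphere] = i
        pairs = []
        for sides in stems.values():
            if set(sides) != {"left", "right"}:
                raise ValueError("every region needs a homotopic partner")
            pairs.append((sides["left"], sides["right"]))
        return sorted(pairs)


def generate_atlas(
    n_per_hemisphere: int, group_sizes: Mapping[str, int] | None = None
) -> Atlas:
    """Bilateral atlas of ``2 * n_per_hemisphere`` regions.

    ``group_sizes`` maps functional groups to per-hemisphere region counts
    and must sum to ``n_per_hemisphere``.  Abbreviations are mirrored with
    ``_L``/``_R`` suffixes (e.g. ``thal3_L`` / ``thal3_R``).
    """
    if group_sizes is None:
        if n_per_hemisphere != sum(DEFAULT_GROUP_SIZES.values()):
            raise ValueError("group_sizes required for non-default atlas size")
        group_sizes = DEFAULT_GROUP_SIZES
    total = sum(group_sizes.values())
    if total != n_per_hemisphere:
        raise ValueError(
            f"group sizes sum to {total}, expected n_per_hemisphere={n_per_hemisphere}"
        )
    unknown = set(group_sizes) - set(FUNCTIONAL_GROUPS)
    if unknown:
        raise ValueError(f"unknown functional groups: {sorted(unknown)}")
    regions: list[Region] = []
    for hemi, suffix in (("left", "_L"), ("right", "_R")):
        for group in FUNCTIONAL_GROUPS:
            n = group_sizes.get(group, 0)
            prefix = _GROUP_PREFIX[group]
            for i in range(1, n + 1):
                regions.append(Region(f"{prefix}{i}{suffix}", hemi, group))
    return Atlas(tuple(regions))


def default_atlas() -> Atlas:
    """The 72-region bilateral study atlas (36 regions per hemisphere)."""
    return generate_atlas(36, DEFAULT_GROUP_SIZES)


@dataclass(frozen=True)
class CommunitySpec:
    """Target population correlation structure for the generator.

    ``within`` gives the within-functional-group correlation target per
    group; ``between`` the default between-group target, overridden for
    specific group pairs by ``between_overrides`` (keys are frozensets of
    two group names).  ``homotopic`` applies to mirrored left/right pairs
    and overrides the block value.  ``edge_jitter_sd`` adds seeded, subject-
    independent heterogeneity to the per-edge targets, giving the continuous
    edge-weight distribution real connectomes show rather than discrete
    tiers; the jitter is part of the planted "anatomy" and shared across
    groups.  ``edge_deltas`` adds group effects: each entry
    ``(group_a, group_b, delta)`` shifts every target between those
    functional groups (applied before positive-semidefinite repair).
    ``ar_coef`` temporally smooths the innovations with an AR(1) filter to
    mimic hemodynamic autocorrelation (correlation targets are unaffected).
    """

    within: Mapping[str, float]
    between: float = 0.15
    between_overrides: Mapping[frozenset, float] = field(default_factory=dict)
    homotopic: float = 0.6
    noise_sd: float = 1.0
    edge_jitter_sd: float = 0.0
    edge_jitter_seed: int = 7
    edge_deltas: tuple[tuple[str, str, float], ...] = ()
    ar_coef: float = 0.3
    clip: tuple[float, float] = (0.0, 0.85)

    def with_edge_delta(self, group_a: str, group_b: str, delta: float) -> "CommunitySpec":
        from dataclasses import replace

        return replace(self, edge_deltas=self.edge_deltas + ((group_a, group_b, delta),))


def default_study_spec() -> CommunitySpec:
    """Default study conditions for the 72-region atlas.

    Calibrated once to the qualitative features the emulated data must
    show: strong homotopic diagonals, a coherent thalamic block, diffuse
    thalamo-cortical/limbic coupling, cortico-cortical coupling, and a
    group-average network that is fully connected when thresholded to a
    mean degree of 10 (see docs/methods.md for the rationale).
    """
    return CommunitySpec(
        within={
            "sensorimotor": 0.40,
            "association": 0.40,
            "limbic": 0.40,
            "thalamus": 0.50,
            "basal_ganglia": 0.40,
        },
        between=0.15,
        between_overrides={
            frozenset(("thalamus", "sensorimotor")): 0.30,
            frozenset(("thalamus", "association")): 0.30,
            frozenset(("thalamus", "limbic")): 0.30,
            frozenset(("sensorimotor", "association")): 0.30,
            frozenset(("basal_ganglia", "limbic")): 0.28,
        },
        homotopic=0.60,
        edge_jitter_sd=0.08,
        edge_jitter_seed=7,
        ar_coef=0.3,
    )


@dataclass(frozen=True)
class TargetCorrelation:
    """PSD-repaired target correlation matrix with repair bookkeeping."""

    matrix: np.ndarray          # repaired, unit diagonal
    requested: np.ndarray       # pre-repair targets (unit diagonal)
    min_eigenvalue_before: float
    max_abs_adjustment: float   # max |requested - matrix| off-diagonal


def repair_psd(target: np.ndarray, floor: float = 1e-8) -> TargetCorrelation:
    """Make a symmetric target matrix a valid correlation matrix.

    Eigenvalues are clipped at ``floor`` and the matrix renormalized to unit
    diagonal.  Deterministic, and the distortion is reported so callers can
    bound |target - achieved|.
    """
    c = np.asarray(target, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("target must be square")
    if not np.allclose(c, c.T):
        raise ValueError("target must be symmetric")
    w, v = np.linalg.eigh(c)
    min_eig = float(w.min())
    w_clipped = np.clip(w, floor, None)
    repaired = (v * w_clipped) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    w_after = np.linalg.eigvalsh(repaired)
    if w_after.min() < -1e-10:
        raise ValueError(
            f"target covariance not PSD after repair (smallest eigenvalue {w_after.min():.3e})"
        )
    off = ~np.eye(c.shape[0], dtype=bool)
    max_adj = float(np.abs(repaired - c)[off].max()) if c.shape[0] > 1 else 0.0
    return TargetCorrelation(
        matrix=repaired,
        requested=c,
        min_eigenvalue_before=min_eig,
        max_abs_adjustment=max_adj,
    )


def target_correlation(atlas: Atlas, spec: CommunitySpec) -> TargetCorrelation:
    """Assemble and PSD-repair the population correlation target.

    Build order: block targets -> seeded per-edge jitter -> group-effect
    deltas -> clipping to ``spec.clip`` -> PSD repair.
    """
    R = len(atlas)
    groups = atlas.groups
    c = np.full((R, R), spec.between, dtype=float)
    for i in range(R):
        for j in range(R):
            gi, gj = groups[i], groups[j]
            if gi == gj:
                c[i, j] = spec.within[gi]
            else:
                key = frozenset((gi, gj))
                if key in spec.between_overrides:
                    c[i, j] = spec.between_overrides[key]
    for i, j in atlas.homotopic_pairs():
        c[i, j] = c[j, i] = spec.homotopic
    if spec.edge_jitter_sd > 0:
        rng = np.random.default_rng(spec.edge_jitter_seed)
        jit = rng.normal(0.0, spec.edge_jitter_sd, size=(R, R))
        jit = np.triu(jit, 1)
        c = c + jit + jit.T
    for group_a, group_b, delta in spec.edge_deltas:
        mask_a = np.asarray([g == group_a for g in groups])
        mask_b = np.asarray([g == group_b for g in groups])
        sel = np.outer(mask_a, mask_b) | np.outer(mask_b, mask_a)
        np.fill_diagonal(sel, False)
        c[sel] += delta
    lo, hi = spec.clip
    off = ~np.eye(R, dtype=bool)
    c[off] = np.clip(c[off], lo, hi)
    np.fill_diagonal(c, 1.0)
    return repair_psd(c)


def generate_group_timeseries(
    atlas: Atlas,
    spec: CommunitySpec,
    n_subjects: int,
    n_timepoints: int = 900,
    tr: float = 1.0,
    seed: int = 0,
) -> list[RoiTimeSeries]:
    """Draw ``n_subjects`` independent T x R runs from the target process.

    Each subject is a zero-mean Gaussian process whose population
    correlation matrix equals the spec's (repaired) target, realized via the
    Cholesky factor, with optional AR(1) temporal smoothing (which leaves
    cross-regional correlations unchanged).  Identical seeds reproduce
    identical output bit for bit.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if n_timepoints < 3:
        raise ValueError("n_timepoints must be >= 3")
    target = target_correlation(atlas, spec)
    L = np.linalg.cholesky(target.matrix)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subjects):
        z = rng.standard_normal((n_timepoints, len(atlas)))
        innov = z @ L.T
        if spec.ar_coef:
            innov = signal.lfilter([1.0], [1.0, -spec.ar_coef], innov, axis=0)
        out.append(
            RoiTimeSeries(values=spec.noise_sd * innov, tr=tr, labels=atlas.labels)
        )
    return out


@dataclass(frozen=True)
class CaTrace:
    """1-D fluorescence trace with optional ground-truth burst intervals."""

    samples: np.ndarray
    sampling_rate: float
    burst_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dur = s.size / self.sampling_rate
        for a, b in self.burst_intervals:
            if not (0 <= a < b <= dur + 1e-9):
                raise ValueError("burst intervals must lie within the trace")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "burst_intervals", tuple(self.burst_intervals))

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def burst_fraction(self) -> float:
        return sum(b - a for a, b in self.burst_intervals) / self.duration


def _slow_background(
    n: int,
    rng: np.random.Generator,
    sampling_rate: float,
    slow_cutoff_hz: float = 2.0,
    noise_sd: float = 0.1,
) -> np.ndarray:
    """Slow fluorescence background plus small broadband measurement noise.

    The dominant component is 1/f-shaped and rolled off above
    ``slow_cutoff_hz`` (preseizure Ca2+ traces show mainly low-frequency
    fluctuations), normalized to unit SD; white measurement noise of SD
    ``noise_sd`` rides on top.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** -1.0
    hi = freqs > slow_cutoff_hz
    scale[hi] *= np.exp(-(freqs[hi] - slow_cutoff_hz) / 0.5)
    slow = np.fft.irfft(spec * scale, n=n)
    sd = slow.std()
    if sd > 0:
        slow = slow / sd
    return slow + noise_sd * rng.standard_normal(n)


def generate_ca_trace(
    duration: float = 900.0,
    sampling_rate: float = 100.0,
    swd_frequency: float = 6.0,
    burst_duty: float = 0.5,
    seed: int = 0,
    burst_amplitude: float = 3.0,
    mean_burst_length: float = 5.0,
) -> CaTrace:
    """Synthetic Ca2+ trace: slow 1/f-like background with SWD bursts.

    Bursts are an asymmetric sawtooth at ``swd_frequency`` (default 6 Hz,
    the absence-seizure fundamental) plus a small second-harmonic spike
    component, alternating with rest epochs so that bursts occupy
    ``burst_duty`` of the duration.  ``burst_duty=0`` is the preseizure
    preset (background only); ``burst_duty=0.5`` the seizure preset.
    Ground-truth burst intervals are returned with the trace.
    """
    if not 0.0 <= burst_duty <= 1.0:
        raise ValueError("burst_duty must be in [0, 1]")
    if sampling_rate < 10.0 * swd_frequency:
        raise ValueError(
            "sampling_rate must be at least 10x swd_frequency "
            f"(Nyquist/oversampling requirement; got {sampling_rate} Hz for "
            f"{swd_frequency} Hz)"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    if n < 2:
        raise ValueError("trace too short")
    trace = _slow_background(n, rng, sampling_rate)

    intervals: list[tuple[float, float]] = []
    if burst_duty > 0:
        t_cursor = 0.0
        if burst_duty < 1.0:
            rest_len = mean_burst_length * (1.0 - burst_duty) / burst_duty
        else:
            rest_len = 0.0
        # start with a rest epoch half the usual length, then alternate
        t_cursor = rest_len / 2.0 * (0.8 + 0.4 * rng.random())
        while t_cursor < duration:
            b = mean_burst_length * (0.8 + 0.4 * rng.random())
            start, stop = t_cursor, min(t_cursor + b, duration)
            if stop - start >= 1.0:
                intervals.append((start, stop))
            t_cursor = stop
            if rest_len == 0.0:
                if t_cursor >= duration:
                    break
            else:
                t_cursor += rest_len * (0.8 + 0.4 * rng.random())
        t = np.arange(n) / sampling_rate
        swd = signal.sawtooth(2.0 * np.pi * swd_frequency * t, width=0.85)
        swd = swd + 0.4 * np.cos(2.0 * np.pi * 2.0 * swd_frequency * t)
        env = np.zeros(n)
        for a, b in intervals:
            env[int(a * sampling_rate): int(b * sampling_rate)] = 1.0
        trace = trace + burst_amplitude * env * swd
    return CaTrace(
        samples=trace, sampling_rate=sampling_rate, burst_intervals=tuple(intervals)
    )
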