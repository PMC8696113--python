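"""Synthetic single-particle trajectory generator and MSD analysis.

The generator produces labeled multi-class datasets with the statistical
structure the classification pipeline assumes: class-dependent diffusion
regimes (Brownian, confined, fractional Brownian, directed, stalled),
Gaussian localization noise, variable track durations and a controllable
fraction of stalled tracks to exercise the preprocessing filter.

MSD utilities (time-averaged mean-squared displacement and D/L fits) serve
as physical oracles: simulated motion must return its own input parameters
when analysed the classical way.

Conventions
-----------
* Brownian motion with diffusivity ``D`` (µm²/s): per-axis step variance
  ``2·D·dt``, two-dimensional MSD(τ) = 4·D·τ.
* Fractional Brownian motion with Hurst exponent ``H``: per-axis
  MSD(τ) = 2·D·τ^(2H)·t0^(1−2H) with reference time t0 = 1 s, so that the
  unit of ``D`` stays µm²/s regardless of H; H = 0.5 recovers Brownian
  motion exactly.
* Confinement: specular reflection inside a square box of side ``L``
  centred on the track's starting point.  The stationary uniform
  distribution gives an MSD plateau of L²/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import optimize

from .io import DEFAULT_DT, Trajectory, TrajectoryDataset

Regime = Literal["brownian", "confined", "fbm", "directed", "stalled"]


@dataclass(frozen=True)
class MotionSpec:
    """Parameters of one simulated motion regime.

    Parameters
    ----------
    regime : {"brownian", "confined", "fbm", "directed", "stalled"}
    D : float
        Diffusivity in µm²/s (ignored for ``stalled``).
    L : float, optional
        Confinement box side in µm (``confined`` only).
    hurst : float, optional
        Hurst exponent in (0, 1) (``fbm`` only).
    velocity : float, optional
        Drift speed in µm/s (``directed`` only); direction is drawn
        uniformly per track.
    sigma_loc : float
        Localization noise standard deviation per axis, µm.
    dt : float
        Frame interval, seconds.
    """

    regime: Regime
    D: float = 0.0
    L: float | None = None
    hurst: float | None = None
    velocity: float | None = None
    sigma_loc: float = 0.02
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if self.regime not in ("brownian", "confined", "fbm", "directed", "stalled"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.regime == "confined" and (self.L is None or self.L <= 0):
            raise ValueError("confined motion requires L > 0")
        if self.regime == "fbm" and not (self.hurst and 0 < self.hurst < 1):
            raise ValueError("fbm requires 0 < hurst < 1")
        if self.regime == "directed" and (self.velocity is None or self.velocity < 0):
            raise ValueError("directed motion requires velocity >= 0")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


def _fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Standard fractional Gaussian noise, unit-variance increments.

    Davies–Harte circulant embedding; falls back to a Cholesky factorization
    of the autocovariance matrix if the embedding is not positive.
    """
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n)
    k = np.arange(n + 1, dtype=float)
    # autocovariance of standard fGn
    gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma[:-1], gamma[-1:], gamma[-2:0:-1]])
    eig = np.fft.rfft(row).real
    if np.min(eig) >= -1e-10:
        eig = np.clip(eig, 0.0, None)
        m = len(row)
        z = rng.standard_normal(m // 2 + 1) + 1j * rng.standard_normal(m // 2 + 1)
        z[0] = z[0].real * np.sqrt(2)
        z[-1] = z[-1].real * np.sqrt(2)
        w = np.fft.irfft(np.sqrt(eig) * z, n=m) * np.sqrt(m / 2)
        return w[:n]
    cov = np.empty((n, n))
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    cov[:] = gamma[idx]
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return chol @ rng.standard_normal(n)


def simulate_track(
    spec: MotionSpec,
    n_steps: int,
    rng: np.random.Generator,
    track_id: str = "sim-0",
    label: str | None = None,
) -> Trajectory:
    """Simulate one trajectory of ``n_steps`` localizations.

    The noise-free path follows ``spec.regime``; every localization is then
    perturbed by independent Gaussian noise of s.d. ``spec.sigma_loc`` per
    axis, mimicking finite localization precision.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    dt = spec.dt
    step_sd = np.sqrt(2.0 * spec.D * dt)

    if spec.regime in ("brownian", "directed"):
        steps = rng.normal(0.0, step_sd, size=(n_steps - 1, 2))
        if spec.regime == "directed":
            theta = rng.uniform(0, 2 * np.pi)
            steps += (spec.velocity or 0.0) * dt * np.array([np.cos(theta), np.sin(theta)])
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    elif spec.regime == "fbm":
        # increment scale: per-axis Var[x(k·dt)] = D·(k·dt)^{2H}·t0^{1-2H}
        scale = np.sqrt(2.0 * spec.D) * dt ** spec.hurst
        incr = np.column_stack(
            [_fgn(n_steps - 1, spec.hurst, rng) for _ in range(2)]
        ) * scale
        pos = np.vstack([[0.0, 0.0], np.cumsum(incr, axis=0)])
    elif spec.regime == "confined":
        steps = rng.normal(0.0, step_sd, size=(n_steps - 1, 2))
        pos = np.empty((n_steps, 2))
        pos[0] = 0.0
        half = spec.L / 2.0
        cur = np.zeros(2)
        for i, s in enumerate(steps, start=1):
            cur = _reflect(cur + s, -half, half)
            pos[i] = cur
    else:  # stalled: immobile emitter, motion is pure localization noise
        pos = np.zeros((n_steps, 2))

    if spec.sigma_loc > 0:
        pos = pos + rng.normal(0.0, spec.sigma_loc, size=pos.shape)
    return Trajectory(
        track_id=track_id,
        frames=np.arange(n_steps),
        x=pos[:, 0],
        y=pos[:, 1],
        dt=dt,
        label=label,
    )


def _reflect(p: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Specular reflection of a point into [lo, hi] per axis."""
    width = hi - lo
    q = np.mod(p - lo, 2 * width)
    q = np.where(q > width, 2 * width - q, q)
    return q + lo


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for a labeled multi-class synthetic dataset.

    ``stalled_fraction`` of each class's tracks (deterministically
    ``floor(fraction · n_tracks)`` of them) are replaced by stalled
    emitters carrying the class label, so the preprocessing filter always
    has work to do.
    """

    classes: Mapping[str, MotionSpec]
    n_tracks: int = 100
    duration: tuple[int, int] = (300, 1200)
    stalled_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        lo, hi = self.duration
        if lo < 2 or hi < lo:
            raise ValueError("duration bounds must satisfy 2 <= lo <= hi")
        if not 0 <= self.stalled_fraction <= 1:
            raise ValueError("stalled_fraction must be in [0, 1]")
        if not self.classes:
            raise ValueError("at least one class required")


def generate_dataset(spec: DatasetSpec) -> TrajectoryDataset:
    """Generate the dataset described by ``spec``; reproducible from its seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.duration
    trajectories = []
    n_stalled = int(np.floor(spec.stalled_fraction * spec.n_tracks))
    for label in spec.classes:  # insertion order: deterministic
        motion = spec.classes[label]
        stalled = replace(motion, regime="stalled", L=None, hurst=None, velocity=None)
        for i in range(spec.n_tracks):
            n_steps = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            m = stalled if i < n_stalled else motion
            trajectories.append(
                simulate_track(m, n_steps, rng, track_id=f"{label}-{i:05d}", label=label)
            )
    return TrajectoryDataset(
        trajectories,
        provenance=f"synthetic(seed={spec.seed}, n_per_class={spec.n_tracks})",
    )


# Default six-class benchmark: three free-diffusion speeds, two confinement
# sizes, one subdiffusive walker.  Grouped 1/2/3 into three coarse classes to
# mirror a fine-label -> receptor-status style regrouping.
BENCHMARK_CLASSES: dict[str, MotionSpec] = {
    "bro-slow": MotionSpec("brownian", D=0.02),
    "bro-mid": MotionSpec("brownian", D=0.05),
    "bro-fast": MotionSpec("brownian", D=0.12),
    "conf-small": MotionSpec("confined", D=0.1, L=0.3),
    "conf-large": MotionSpec("confined", D=0.1, L=0.6),
    "fbm-sub": MotionSpec("fbm", D=0.08, hurst=0.35),
}

BENCHMARK_COARSE_MAP: dict[str, str] = {
    "bro-slow": "group-A",
    "bro-mid": "group-B",
    "bro-fast": "group-B",
    "conf-small": "group-C",
    "conf-large": "group-C",
    "fbm-sub": "group-C",
}


def benchmark_spec(
    n_tracks: int = 100,
    duration: tuple[int, int] = (300, 1200),
    stalled_fraction: float = 0.1,
    seed: int = 0,
) -> DatasetSpec:
    """The default six-class benchmark DatasetSpec."""
    return DatasetSpec(
        classes=BENCHMARK_CLASSES,
        n_tracks=n_tracks,
        duration=duration,
        stalled_fraction=stalled_fraction,
        seed=seed,
    )


# ----------------------------------------------------------------------------
# MSD analysis


@dataclass
class MSDCurve:
    """Time-averaged mean-squared displacement per lag."""

    lags: np.ndarray  # seconds, strictly increasing
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray  # averaging counts per lag

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")


def compute_msd(traj: Trajectory | np.ndarray, max_lag: int, dt: float | None = None) -> MSDCurve:
    """Time-averaged MSD over all ordered position pairs at each lag.

    MSD(n·dt) = mean over t of |r(t + n·dt) − r(t)|², for n = 1..max_lag.
    Accepts a :class:`Trajectory` (must have contiguous frames for the lag
    interpretation to hold) or a bare (n, 2) position array.
    """
    if isinstance(traj, Trajectory):
        pos = traj.positions
        dt = traj.dt if dt is None else dt
    else:
        pos = np.asarray(traj, dtype=float)
        if dt is None:
            dt = DEFAULT_DT
    n = len(pos)
    if max_lag >= n:
        raise ValueError(f"max_lag ({max_lag}) must be < trajectory length ({n})")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=np.int64)
    for i, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        msd[i] = np.mean(np.sum(d * d, axis=1))
        n_pairs[i] = n - lag
    return MSDCurve(lags=lags * dt, msd=msd, n_pairs=n_pairs)


def average_msd(trajectories: Sequence[Trajectory], max_lag: int) -> MSDCurve:
    """Ensemble average of time-averaged MSDs, weighted by pair counts."""
    curves = [compute_msd(t, min(max_lag, len(t) - 1)) for t in trajectories]
    lags = max(curves, key=lambda c: len(c.lags)).lags
    acc = np.zeros(len(lags))
    cnt = np.zeros(len(lags), dtype=np.int64)
    for c in curves:
        k = len(c.lags)
        acc[:k] += c.msd * c.n_pairs
        cnt[:k] += c.n_pairs
    return MSDCurve(lags=lags, msd=acc / np.maximum(cnt, 1), n_pairs=cnt)


@dataclass
class MSDFit:
    """Result of fitting a diffusion model to an MSD curve."""

    model: str
    D: float  # µm²/s
    L: float | None = None  # µm, confined only
    plateau: float | None = None  # µm², confined only
    intercept: float | None = None  # µm², brownian only (absorbs 4·sigma_loc²)
    tau: float | None = None  # s, confined relaxation time
    residual: float = 0.0


def fit_msd(
    curve: MSDCurve,
    model: Literal["brownian", "confined"] = "brownian",
    fit_lags: int | None = None,
) -> MSDFit:
    """Extract D (and L) from an MSD curve.

    brownian
        Weighted least-squares line over the first ``fit_lags`` lags
        (default: min(10, all)); D = slope / 4, the intercept absorbs the
        localization-noise floor 4·sigma_loc².
    confined
        Fit MSD(τ) = P·(1 − exp(−τ/τc)) + c; the plateau P equals L²/3 for
        a square box of side L under the stationary uniform distribution,
        so L = sqrt(3·P).  D is the initial slope P/(4·τc).
    """
    if len(curve.lags) < 4:
        raise ValueError("need at least 4 lags to fit")
    if model == "brownian":
        k = min(fit_lags or 10, len(curve.lags))
        t, m = curve.lags[:k], curve.msd[:k]
        w = np.sqrt(curve.n_pairs[:k].astype(float))
        A = np.column_stack([t, np.ones_like(t)]) * w[:, None]
        coef, res, *_ = np.linalg.lstsq(A, m * w, rcond=None)
        slope, intercept = coef
        if slope <= 0:
            raise ValueError("degenerate MSD curve: non-positive slope")
        return MSDFit(
            model="brownian",
            D=float(slope / 4.0),
            intercept=float(intercept),
            residual=float(res[0]) if len(res) else 0.0,
        )
    if model == "confined":
        t, m = curve.lags, curve.msd
        p0 = [max(m.max(), 1e-9), max(t[min(3, len(t) - 1)], t[0]), 0.0]

        def f(tau, P, tc, c):
            return P * (1.0 - np.exp(-tau / tc)) + c

        try:
            popt, _ = optimize.curve_fit(f, t, m, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            raise ValueError(f"degenerate MSD curve: confined fit failed ({exc})")
        P, tc, c = popt
        if P <= 0 or tc <= 0:
            raise ValueError("degenerate MSD curve: non-physical confined fit")
        return MSDFit(
            model="confined",
            D=float(P / (4.0 * tc)),
            L=float(np.sqrt(3.0 * P)),
            plateau=float(P),
            tau=float(tc),
            residual=float(np.sum((f(t, *popt) - m) ** 2)),
        )
    raise ValueError(f"unknown MSD model {model!r}")
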