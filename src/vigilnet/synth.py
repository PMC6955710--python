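"""Synthetic EEG sessions with known directed coupling.

The study's recordings are not deposited, so every downstream stage is
exercised on MVAR-generated surrogate sessions whose ground-truth
directed coupling is known exactly.  A session emulates a 60-min
sustained-attention experiment: three 20-min time-on-task blocks of
multichannel signal, target events placed throughout, and a per-block
coupling specification.  Under the *vigilance* condition the coupling
strengths weaken across blocks (default multipliers 1.0, 0.7, 0.4); under
the *enhancement* condition they stay high (1.0, 1.0, 0.95), mirroring
the decrement-versus-maintenance contrast the analysis is built to
detect.  Matched behavioral series (reaction time, accuracy, omission
and commission rates per 3-min bin) carry the corresponding linear
trends.

Ground-truth coupling is placed at lag 1 only, which keeps the implied
PDC analytically computable; innovations are i.i.d. Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import Recording
from .mvar_pdc import StabilityError, VARModel, spectral_radius

__all__ = [
    "CouplingSpec",
    "SessionRecording",
    "BehaviorSeries",
    "make_var_model",
    "simulate_var",
    "simulate_session",
    "simulate_behavior",
    "VIGILANCE_BLOCK_SCALES",
    "ENHANCEMENT_BLOCK_SCALES",
]

VIGILANCE_BLOCK_SCALES = (1.0, 0.7, 0.4)
ENHANCEMENT_BLOCK_SCALES = (1.0, 1.0, 0.95)

#: spectral-radius ceiling enforced by uniform shrinkage
STABILITY_RADIUS = 0.95


@dataclass
class CouplingSpec:
    """Ground-truth directed coupling for one synthetic subject.

    ``edges`` holds (source, target, strength) triples with strengths in
    (0, 1); ``self_coef`` is the per-channel AR(1) self term; and
    ``block_scale`` multiplies every edge strength in the corresponding
    time-on-task block.
    """

    n_channels: int
    edges: tuple[tuple[int, int, float], ...]
    self_coef: np.ndarray | float = 0.5
    block_scale: tuple[float, ...] = VIGILANCE_BLOCK_SCALES
    order: int = 1

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be positive")
        if self.order < 1:
            raise ValueError("order must be positive")
        self.self_coef = np.broadcast_to(
            np.asarray(self.self_coef, dtype=float), (self.n_channels,)
        ).copy()
        if np.any(np.abs(self.self_coef) >= 1):
            raise ValueError("self_coef entries must lie in (-1, 1)")
        edges = []
        for src, tgt, s in self.edges:
            if src == tgt:
                raise ValueError(f"self-loop edge ({src}, {tgt}) not allowed")
            if not (0 <= src < self.n_channels and 0 <= tgt < self.n_channels):
                raise ValueError(f"edge ({src}, {tgt}) outside channel range")
            if not np.isfinite(s):
                raise ValueError("edge strengths must be finite")
            edges.append((int(src), int(tgt), float(s)))
        self.edges = tuple(edges)
        if not all(np.isfinite(self.block_scale)):
            raise ValueError("block scales must be finite")

    @property
    def n_blocks(self) -> int:
        return len(self.block_scale)

    def scaled(self, factor: float) -> "CouplingSpec":
        """Copy with every edge strength multiplied by ``factor``."""
        return CouplingSpec(
            n_channels=self.n_channels,
            edges=tuple((s, t, w * factor) for s, t, w in self.edges),
            self_coef=self.self_coef.copy(),
            block_scale=self.block_scale,
            order=self.order,
        )


@dataclass
class SessionRecording(Recording):
    """Continuous synthetic session plus its generating ground truth."""

    events: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    block_bounds: tuple[tuple[int, int], ...] = ()
    truth: CouplingSpec | None = None
    #: realized per-block specs (includes session-variability jitter)
    truth_blocks: tuple[CouplingSpec, ...] = ()

    def __post_init__(self) -> None:
        super().__post_init__()
        self.events = np.asarray(self.events, dtype=int)
        if self.events.size and np.any(np.diff(self.events) <= 0):
            raise ValueError("events must be strictly increasing")

    def block_of_sample(self, sample: int) -> int:
        """1-based time-on-task block containing ``sample``."""
        for k, (lo, hi) in enumerate(self.block_bounds, start=1):
            if lo <= sample < hi:
                return k
        raise ValueError(f"sample {sample} outside all block bounds")


@dataclass
class BehaviorSeries:
    """Behavioral performance per time bin (default one bin per 3 min)."""

    bin_times: np.ndarray       # minutes, bin centers
    reaction_time: np.ndarray   # seconds
    accuracy: np.ndarray        # fraction in [0, 1]
    omission_rate: np.ndarray   # fraction in [0, 1]
    commission_rate: np.ndarray  # fraction in [0, 1]

    def __post_init__(self) -> None:
        for name in ("bin_times", "reaction_time", "accuracy", "omission_rate", "commission_rate"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.reaction_time <= 0):
            raise ValueError("reaction times must be positive")
        for name in ("accuracy", "omission_rate", "commission_rate"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")


def make_var_model(
    spec: CouplingSpec,
    block: int,
    noise_scale: float = 1.0,
) -> VARModel:
    """Ground-truth MVAR model of one time-on-task block.

    The lag-1 matrix carries ``self_coef`` on the diagonal and
    ``block_scale[block] * strength`` at (target, source) for every edge
    (row = receiver); higher lags are zero.  If the raw construction is
    unstable, all coefficients are shrunk uniformly until the companion
    spectral radius is at most 0.95 — deterministic and topology
    preserving.
    """
    if not 0 <= block < spec.n_blocks:
        raise ValueError(f"block {block} out of range for {spec.n_blocks} blocks")
    m = spec.n_channels
    A = np.zeros((spec.order, m, m))
    A[0][np.diag_indices(m)] = spec.self_coef
    scale = spec.block_scale[block]
    for src, tgt, s in spec.edges:
        A[0, tgt, src] = scale * s
    rho = spectral_radius(A)
    if rho > STABILITY_RADIUS:
        A *= STABILITY_RADIUS / rho  # exact for lag-1 structure
        # general-order safety: iterate the (rare) nonlinear case
        while spectral_radius(A) > STABILITY_RADIUS + 1e-12:
            A *= 0.99
    return VARModel(
        coeffs=A, noise_cov=noise_scale**2 * np.eye(m), order=spec.order
    )


def simulate_var(
    model: VARModel,
    n_samples: int,
    burn_in: int = 200,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate a stable MVAR process; returns (m, n_samples).

    Innovations are zero-mean Gaussian with the model's ``noise_cov``;
    the first ``burn_in`` samples are discarded so the output is
    (approximately) stationary.  The same seed yields the same output.
    """
    if not model.is_stable():
        raise StabilityError(
            f"model spectral radius {model.spectral_radius():.3f} >= 1"
        )
    if n_samples <= model.order:
        raise ValueError("n_samples must exceed the model order")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m, p = model.n_channels, model.order
    total = n_samples + burn_in
    chol = np.linalg.cholesky(model.noise_cov)
    innov = rng.standard_normal((total, m)) @ chol.T
    x = np.zeros((total, m))
    coeffs = model.coeffs
    for t in range(total):
        acc = innov[t].copy()
        for r in range(1, min(p, t) + 1):
            acc += coeffs[r - 1] @ x[t - r]
        x[t] = acc
    return x[burn_in:].T


def _subject_spec(
    spec: CouplingSpec,
    rng: np.random.Generator,
    subject_jitter: float,
) -> CouplingSpec:
    """Between-subject variation: one multiplicative strength jitter."""
    if subject_jitter <= 0:
        return spec
    factor = float(rng.uniform(1 - subject_jitter, 1 + subject_jitter))
    return spec.scaled(factor)


def simulate_session(
    vigilance: bool = True,
    spec: CouplingSpec | None = None,
    fs: float = 500.0,
    seed: int | np.random.Generator = 0,
    block_minutes: float = 20.0,
    epoch_ms: float = 1200.0,
    events_per_block: int | None = None,
    noise_scale_uv: float = 5.0,
    subject_jitter: float = 0.0,
    block_jitter: float = 0.1,
    channel_labels: list[str] | None = None,
) -> SessionRecording:
    """Simulate one subject's session: three concatenated blocks.

    Parameters
    ----------
    vigilance : bool
        True -> decreasing default block scales (1.0, 0.7, 0.4);
        False -> enhancement scales (1.0, 1.0, 0.95).  Ignored when
        ``spec`` carries its own ``block_scale``.
    spec : CouplingSpec, optional
        Ground-truth coupling; a small default network is used if None.
    block_minutes : float
        Length of each time-on-task block (study value 20; reduce for
        desk-scale runs).
    events_per_block : int, optional
        Target-onset count per block; default places one event every 3 s
        (>= 400 epochs of 1200 ms per 20-min block).
    noise_scale_uv : float
        Innovation standard deviation in microvolts.
    subject_jitter : float
        Between-subject fractional strength jitter (one draw per call).
    block_jitter : float
        Session-variability fractional strength jitter, drawn once per
        block (physiological state fluctuates between blocks beyond the
        time-on-task trend).
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec is None:
        spec = default_coupling_spec(vigilance=vigilance)
    elif spec.n_blocks != 3:
        raise ValueError("session simulation expects 3 block scales")
    spec = _subject_spec(spec, rng, subject_jitter)

    block_samples = int(round(block_minutes * 60 * fs))
    epoch_samples = int(round(epoch_ms / 1000 * fs))
    if events_per_block is None:
        spacing = int(round(3.0 * fs))  # one target every 3 s
        events_per_block = block_samples // spacing
    else:
        spacing = block_samples // events_per_block
    if spacing < epoch_samples:
        raise ValueError("events too dense for the epoch length")

    blocks, bounds, events = [], [], []
    truth_blocks = []
    offset = 0
    for b in range(3):
        block_spec = spec
        if block_jitter > 0:
            block_spec = spec.scaled(float(rng.uniform(1 - block_jitter, 1 + block_jitter)))
        truth_blocks.append(block_spec)
        model = make_var_model(block_spec, b, noise_scale=noise_scale_uv)
        blocks.append(simulate_var(model, block_samples, burn_in=200, seed=rng))
        bounds.append((offset, offset + block_samples))
        n_ev = min(events_per_block, (block_samples - epoch_samples) // spacing + 1)
        events.extend(offset + spacing * k for k in range(n_ev))
        offset += block_samples

    return SessionRecording(
        signal=np.concatenate(blocks, axis=1),
        fs=fs,
        channel_labels=channel_labels or [],
        events=np.asarray(events, dtype=int),
        block_bounds=tuple(bounds),
        truth=spec,
        truth_blocks=tuple(truth_blocks),
    )


def default_coupling_spec(
    vigilance: bool = True,
    n_channels: int = 16,
    n_edges: int | None = None,
    strength_range: tuple[float, float] = (0.35, 0.55),
    self_coef: float = 0.5,
    seed: int = 7,
) -> CouplingSpec:
    """Default ground-truth network: a fixed random directed graph with
    in-degree at most one.

    Each target channel receives at most one true edge (sources drawn at
    random), which keeps per-channel variance homogeneous — unconstrained
    placement creates receiving hubs whose variance blows up near the
    stability boundary.  Edge placement is drawn once from a fixed seed
    so the default truth is a constant of the package, not of the
    session seed.  Default edge count equals the channel count.
    """
    rng = np.random.default_rng(seed)
    if n_edges is None:
        n_edges = n_channels
    n_edges = min(n_edges, n_channels)
    targets = rng.permutation(n_channels)[:n_edges]
    lo, hi = strength_range
    edges = tuple(
        (
            int(rng.choice([c for c in range(n_channels) if c != t])),
            int(t),
            float(rng.uniform(lo, hi)),
        )
        for t in targets
    )
    return CouplingSpec(
        n_channels=n_channels,
        edges=edges,
        self_coef=self_coef,
        block_scale=VIGILANCE_BLOCK_SCALES if vigilance else ENHANCEMENT_BLOCK_SCALES,
    )


def simulate_behavior(
    group: str,
    n_bins: int = 20,
    seed: int | np.random.Generator = 0,
    session_minutes: float = 60.0,
    rt_base: float = 0.85,
    rt_trend: float | None = None,
    rt_noise: float = 0.04,
    acc_base: float = 0.95,
    acc_trend: float | None = None,
    acc_noise: float = 0.015,
) -> BehaviorSeries:
    """Behavioral series with the group's linear time-on-task trend.

    ``group`` is "vigilance" (reaction time rises, accuracy falls) or
    "enhancement" (reaction time falls, accuracy maintained).  Trends are
    total change over the session in seconds / fraction; defaults give a
    ~35% reaction-time slowdown under vigilance and a modest speed-up
    under enhancement.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if group not in ("vigilance", "enhancement"):
        raise ValueError("group must be 'vigilance' or 'enhancement'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vig = group == "vigilance"
    if rt_trend is None:
        rt_trend = 0.30 if vig else -0.12
    if acc_trend is None:
        acc_trend = -0.12 if vig else 0.0
    t = (np.arange(n_bins) + 0.5) * session_minutes / n_bins  # bin centers, min
    frac = np.arange(n_bins) / (n_bins - 1)
    rt = rt_base + rt_trend * frac + rt_noise * rng.standard_normal(n_bins)
    rt = np.clip(rt, 0.15, None)
    acc = acc_base + acc_trend * frac + acc_noise * rng.standard_normal(n_bins)
    acc = np.clip(acc, 0.0, 1.0)
    omission = np.clip(
        (0.02 if not vig else 0.02 + 0.06 * frac)
        + 0.005 * rng.standard_normal(n_bins),
        0.0,
        1.0,
    )
    commission = np.clip(
        (0.015 if not vig else 0.015 + 0.04 * frac)
        + 0.004 * rng.standard_normal(n_bins),
        0.0,
        1.0,
    )
    return BehaviorSeries(
        bin_times=t,
        reaction_time=rt,
        accuracy=acc,
        omission_rate=omission,
        commission_rate=commission,
    )
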