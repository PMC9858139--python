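"""Fast-linking modified spiking cortical model (FL-MSCM) tumor segmenter.

Each pixel is a spiking neuron with feeding input ``S`` (the intensity),
linking input ``L`` fed by neighbors' pulses, internal activity ``U``,
dynamic threshold ``E`` and pulse output ``Y``:

    L(n) = mL * (W * Y(n-1))                      (linking; * = correlation)
    U(n) = f * U(n-1) + S * (1 + beta * L(n))     (leaky modulation)
    Y(n) = 1  if U(n) > E(n) else 0               (pulse)
    E(n) = E(n-1) - Delta + h * Y(n)              (linear threshold decay)

The *modified* SCM decays the threshold linearly by ``Delta`` per iteration
(instead of the classical exponential decay), so brighter pixels fire at
earlier iterations and the first-fire map orders regions by intensity.
*Fast linking* re-runs the L/U/Y update inside one threshold step until the
firing map stops changing, so neurons with similar stimuli fire in one
synchronous wave.  All model constants can be derived automatically from the
image: the linking strength ``beta`` is a sigmoid of the local gradient
magnitude, ``h`` is large enough that no neuron can fire twice, and the
iteration budget ``N`` is set from Otsu's threshold so that exactly the
Otsu-foreground intensity range gets to fire.

Input images are expected on the [0, 1] scale (see
:func:`brainmr.core_io.rescale_range`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import correlate

from .core_io import BinaryMask, DegenerateInputError, Image2D

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Parameter derivation
# ---------------------------------------------------------------------------

def otsu_threshold(S: Image2D | np.ndarray) -> float:
    """Between-class-variance-maximizing threshold over a 256-bin histogram.

    Ties are broken toward the lower threshold.  Returns the bin-edge value
    separating the two classes (pixels ``>= TG`` form the upper class).
    """
    px = S.pixels if isinstance(S, Image2D) else np.asarray(S, dtype=np.float64)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        raise DegenerateInputError("Otsu threshold undefined on a constant image")
    counts, edges = np.histogram(px, bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    w0 = np.cumsum(counts)[:-1]                      # split after bin k -> bins 0..k
    w1 = total - w0
    mass = np.cumsum(counts * centers)[:-1]
    total_mass = (counts * centers).sum()
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(255)
    mu0 = np.divide(mass, w0, out=np.zeros(255), where=valid)
    mu1 = np.divide(total_mass - mass, w1, out=np.zeros(255), where=valid)
    sigma_b[valid] = (w0[valid] / total) * (w1[valid] / total) * (mu0[valid] - mu1[valid]) ** 2
    best = int(np.argmax(sigma_b))                   # argmax takes the lowest tie
    return float(edges[best + 1])


def make_weights(size: int = 7, sigma: float = 1.0) -> np.ndarray:
    """Sampled 2-D Gaussian linking kernel, normalized to sum 1.

    The center (self) weight is retained; with the single-fire guarantee of
    :func:`compute_h` the self-term only reinforces a neuron that already
    fired, which is harmless.
    """
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    return g / g.sum()


def compute_beta(S: Image2D | np.ndarray) -> np.ndarray:
    """Per-pixel linking strength: sigmoid of the gradient magnitude.

    Gradients are central differences on a replicate-padded image, so a unit
    step yields 0.5 at the step and ``beta = 1/(1+e^-0.5)`` there.
    """
    px = S.pixels if isinstance(S, Image2D) else np.asarray(S, dtype=np.float64)
    padded = np.pad(px, 1, mode="edge")
    gy = 0.5 * (padded[2:, 1:-1] - padded[:-2, 1:-1])
    gx = 0.5 * (padded[1:-1, 2:] - padded[1:-1, :-2])
    G = np.hypot(gx, gy)
    return 1.0 / (1.0 + np.exp(-G))


def compute_h(
    S: Image2D | np.ndarray,
    beta: np.ndarray,
    W: np.ndarray,
    f: float = 0.2,
    beta_reduce: str = "perpixel",
) -> np.ndarray:
    """Threshold magnitude ensuring each neuron fires at most once:

        h = (max(S) - min(S)) / (1 - f) + max(S) * (1 + beta * sum(W))

    ``beta`` enters per-pixel by default; ``beta_reduce`` in
    {"perpixel", "mean", "max"} selects alternative scalar readings.
    """
    px = S.pixels if isinstance(S, Image2D) else np.asarray(S, dtype=np.float64)
    if beta_reduce == "mean":
        b = float(np.mean(beta))
    elif beta_reduce == "max":
        b = float(np.max(beta))
    elif beta_reduce == "perpixel":
        b = beta
    else:
        raise ValueError(f"unknown beta_reduce {beta_reduce!r}")
    smax, smin = float(px.max()), float(px.min())
    h = (smax - smin) / (1.0 - f) + smax * (1.0 + b * W.sum())
    return np.broadcast_to(np.asarray(h, dtype=np.float64), px.shape).copy()


def compute_iterations(S: Image2D | np.ndarray, f: float = 0.2, delta: float = 0.02) -> int:
    """Iteration budget ``N = ceil((max(S) - TS)/Delta + 1)``, ``TS = TG/(1-f)``.

    ``TG`` is Otsu's threshold of S; pixels whose steady-state activity
    ``S/(1-f)`` exceeds ``TS`` — i.e. the Otsu foreground — fire within N.
    If ``TS >= max(S)`` a single iteration is used.
    """
    px = S.pixels if isinstance(S, Image2D) else np.asarray(S, dtype=np.float64)
    tg = otsu_threshold(px)
    ts = tg / (1.0 - f)
    smax = float(px.max())
    if ts >= smax:
        return 1
    return int(np.ceil((smax - ts) / delta + 1.0))


# ---------------------------------------------------------------------------
# Model state and dynamics
# ---------------------------------------------------------------------------

@dataclass
class MSCMParams:
    """Constants of the segmenter; ``from_image`` derives the automatic ones."""

    f: float = 0.2            # leak of the internal activity, 0 < f < 1
    mL: float = 1.0           # linking magnitude
    delta: float = 0.02       # linear threshold decay per iteration
    E0: float = 1.0           # initial threshold
    W: np.ndarray = field(default_factory=make_weights)
    beta: np.ndarray | None = None    # per-pixel linking strength
    h: np.ndarray | None = None       # per-pixel threshold magnitude
    N: int | None = None              # outer-iteration budget
    inner_cap: int = 64               # fast-linking safety cap
    beta_reduce: str = "perpixel"

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise ValueError("decay constant f must lie in (0, 1)")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if np.any(self.W < 0):
            raise ValueError("linking weights must be non-negative")
        if self.N is not None and self.N < 1:
            raise ValueError("N must be >= 1")

    @classmethod
    def from_image(cls, S: Image2D | np.ndarray, **overrides) -> "MSCMParams":
        """Derive beta, h and N from the image; ``overrides`` win."""
        p = cls(**{k: v for k, v in overrides.items() if k in cls.__dataclass_fields__})
        if p.beta is None:
            p.beta = compute_beta(S)
        if p.h is None:
            p.h = compute_h(S, p.beta, p.W, p.f, p.beta_reduce)
        if p.N is None:
            p.N = compute_iterations(S, p.f, p.delta)
        return p


@dataclass
class MSCMState:
    """Evolving neuron lattices; ``first_fire`` is 0 where never fired."""

    L: np.ndarray
    U: np.ndarray
    E: np.ndarray
    Y: np.ndarray
    n: int
    first_fire: np.ndarray

    @classmethod
    def initial(cls, shape: tuple[int, int], E0: float = 1.0) -> "MSCMState":
        z = np.zeros(shape, dtype=np.float64)
        return cls(
            L=z.copy(), U=z.copy(),
            E=np.full(shape, float(E0)),
            Y=np.zeros(shape, dtype=np.uint8),
            n=0,
            first_fire=np.zeros(shape, dtype=np.int32),
        )


@dataclass
class SegmentationResult:
    tumor_mask: BinaryMask
    first_fire: np.ndarray
    n_used: int
    params: MSCMParams


def _linking(Y: np.ndarray, W: np.ndarray, mL: float) -> np.ndarray:
    # zero padding: no neurons beyond the lattice
    return mL * correlate(Y.astype(np.float64), W, mode="constant", cval=0.0)


def step(state: MSCMState, S: np.ndarray, params: MSCMParams) -> MSCMState:
    """One outer iteration: threshold decay, then fast-linking to convergence.

    The linear decay ``-Delta`` is applied exactly once per outer iteration;
    within the inner loop only L, U, Y re-update (U always from the activity
    carried over from the previous iteration).  A neuron firing in any inner
    pass latches ``Y = 1`` for this iteration and immediately receives the
    ``+h`` threshold reinforcement, so the fired set grows monotonically and
    the loop terminates.
    """
    beta = params.beta
    h = params.h
    assert beta is not None and h is not None, "derive params via MSCMParams.from_image"
    n = state.n + 1
    E = state.E - params.delta
    U_prev = state.U
    Y_in = state.Y.astype(np.float64)     # pulses of iteration n-1 seed the linking
    fired = np.zeros(S.shape, dtype=bool)
    U = U_prev.copy()
    for inner in range(params.inner_cap):
        L = _linking(np.where(fired, 1.0, Y_in), params.W, params.mL)
        U = params.f * U_prev + S * (1.0 + beta * L)
        new = (U > E) & ~fired
        if not new.any():
            if inner == 0:
                L_last = L
            break
        fired |= new
        E = E + h * new                    # immediate single-fire reinforcement
        Y_in = np.zeros_like(Y_in)         # stale pulses consumed; linking now from `fired`
        L_last = L
    else:
        logger.warning("fast-linking inner loop hit inner_cap=%d at n=%d",
                       params.inner_cap, n)
        L_last = L
    first_fire = state.first_fire.copy()
    newly = fired & (first_fire == 0)
    first_fire[newly] = n
    return MSCMState(L=L_last, U=U, E=E, Y=fired.astype(np.uint8), n=n,
                     first_fire=first_fire)


def run_fl_mscm(S: Image2D, params: MSCMParams | None = None, *,
                strategy: str = "first-wave", k: int = 1) -> SegmentationResult:
    """Run the two-loop FL-MSCM on a [0,1]-scale image and extract the mask."""
    px = S.pixels
    needs_derivation = (params is None or params.beta is None
                        or params.h is None or params.N is None)
    if needs_derivation and float(px.max()) == float(px.min()):
        raise DegenerateInputError(
            "automatic parameter setting needs a non-constant image")
    if params is None:
        params = MSCMParams.from_image(S)
    elif needs_derivation:
        params = MSCMParams.from_image(
            S, **{f.name: getattr(params, f.name)
                  for f in params.__dataclass_fields__.values()})
    else:
        params = replace(params)
    state = MSCMState.initial(px.shape, params.E0)
    waves = 0
    for _ in range(int(params.N)):
        prev_fired = int((state.first_fire > 0).sum())
        state = step(state, px, params)
        if int((state.first_fire > 0).sum()) > prev_fired:
            waves += 1
    logger.info("fl-mscm n_used=%d waves=%d fired=%d/%d", state.n, waves,
                int((state.first_fire > 0).sum()), px.size)
    mask = extract_mask(state.first_fire, strategy=strategy, k=k)
    return SegmentationResult(tumor_mask=mask, first_fire=state.first_fire,
                              n_used=state.n, params=params)


def extract_mask(first_fire: np.ndarray, strategy: str = "first-wave",
                 k: int = 1) -> BinaryMask:
    """Turn a first-fire map into a region mask.

    first-wave: the pixels sharing the earliest positive firing iteration —
    with automatic parameters the brightest synchronized region, i.e. the
    hyperintense tumor on a skull-stripped T2 slice.  k-waves: the union of
    the k earliest distinct firing iterations.
    """
    fired = first_fire > 0
    if not fired.any():
        return BinaryMask(np.zeros(first_fire.shape, dtype=np.uint8))
    values = np.unique(first_fire[fired])
    if strategy == "first-wave":
        keep = values[:1]
    elif strategy == "k-waves":
        keep = values[: max(1, int(k))]
    else:
        raise ValueError(f"unknown extraction strategy {strategy!r}")
    return BinaryMask(np.isin(first_fire, keep).astype(np.uint8))
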