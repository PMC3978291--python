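"""Seeded generators for artificial processes and human-like surrogates.

Three artificial reference processes frame the analysis:

* ``AS`` — a strictly alternating up-down sequence (maximal regularity),
* ``AR`` — a uniform random walk confined to a 10 x 10 grid,
* ``AF`` — an i.i.d. process with prescribed first-order symbol
  frequencies (grid-unconstrained by construction).

Because no human recordings are distributed with the package, three
surrogate families emulate the drawing conditions at the symbol level:
repeated closed motifs with substitution noise (pattern-like, ``P``),
random concatenation of a small library of long stroke motifs
(letter-like, ``L``), and random concatenation of a large repertoire of
short motor-primitive fragments (random-like, ``R1``); Markov walks with
analytic entropy rates serve as validation sources.  Every generator is a
pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .encoding import GridSpec, OutOfBoundsError, Trajectory
from .sequences import ALPHABET, INVERSE, MOVES, EmptyInputError, SymbolSequence

#: Per-trial transition count and trials per condition of the reference
#: experimental design (50 trials x 200 transitions -> n = 10,000).
TRANSITIONS_PER_TRIAL = 200
TRIALS_PER_CONDITION = 50
DEFAULT_N = TRANSITIONS_PER_TRIAL * TRIALS_PER_CONDITION

_TRIAL_BOUNDARIES = tuple(
    range(TRANSITIONS_PER_TRIAL, DEFAULT_N, TRANSITIONS_PER_TRIAL)
)


def _boundaries(n: int) -> tuple[int, ...]:
    if n == DEFAULT_N:
        return _TRIAL_BOUNDARIES
    return ()


def gen_rhythmic(n: int, label: str = "AS") -> SymbolSequence:
    """Strictly alternating ``ududud...`` sequence of length n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return SymbolSequence(
        ("ud" * ((n + 1) // 2))[:n], trial_boundaries=_boundaries(n), label=label
    )


def gen_grid_random_walk(
    grid: GridSpec | None = None,
    n: int = DEFAULT_N,
    seed: int = 0,
    start: tuple[int, int] | None = None,
    label: str = "AR",
) -> SymbolSequence:
    """Uniform random walk among admissible moves of a bounded grid.

    The walk starts at the grid center (matching a central start position)
    and at each step chooses uniformly among the in-bounds unit moves.
    """
    if grid is None:
        grid = GridSpec(10, 10, 1.0)
    if grid.width_cells * grid.height_cells < 2:
        raise ValueError("the walk needs at least 2 cells")
    rng = np.random.default_rng(seed)
    i, j = start if start is not None else (grid.width_cells // 2, grid.height_cells // 2)
    out = []
    W, H = grid.width_cells, grid.height_cells
    for _ in range(n):
        moves = [
            c
            for c, (dx, dy) in MOVES.items()
            if 0 <= i + dx < W and 0 <= j + dy < H
        ]
        c = moves[rng.integers(len(moves))]
        dx, dy = MOVES[c]
        i, j = i + dx, j + dy
        out.append(c)
    return SymbolSequence("".join(out), trial_boundaries=_boundaries(n), label=label)


def gen_iid_frequencies(
    freqs, n: int = DEFAULT_N, seed: int = 0, label: str = "AF"
) -> SymbolSequence:
    """i.i.d. draws with the given (p_l, p_r, p_u, p_d), grid-unconstrained."""
    p = np.asarray(freqs, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be 4 non-negative numbers summing to 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(4, size=n, p=p / p.sum())
    return SymbolSequence(
        "".join(ALPHABET[i] for i in draws),
        trial_boundaries=_boundaries(n),
        label=label,
    )


def markov_entropy_rate(T: np.ndarray, k: int = 4) -> float:
    """Analytic entropy rate of an order-1 chain in base-k units."""
    T = np.asarray(T, dtype=float)
    evals, evecs = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, idx])
    pi = pi / pi.sum()
    if np.any(pi < -1e-9):
        raise ValueError("chain has no valid stationary distribution")
    pi = np.clip(pi, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(T > 0, np.log(T), 0.0)
    return float(-(pi[:, None] * T * logs).sum() / math.log(k))


def gen_markov(
    transition_matrix,
    n: int = DEFAULT_N,
    seed: int = 0,
    start: int | None = None,
    label: str = "R1",
) -> SymbolSequence:
    """Order-1 Markov chain over the four transition symbols.

    Row i of the 4 x 4 row-stochastic matrix gives the distribution of the
    next symbol after symbol i (alphabet order ``l r u d``).  Its analytic
    entropy rate is available via :func:`markov_entropy_rate`.
    """
    T = np.asarray(transition_matrix, dtype=float)
    if T.shape != (4, 4) or np.any(T < 0) or np.any(np.abs(T.sum(axis=1) - 1) > 1e-9):
        raise ValueError("transition matrix must be 4x4 row-stochastic")
    rng = np.random.default_rng(seed)
    state = int(rng.integers(4)) if start is None else int(start)
    out = []
    cum = np.cumsum(T, axis=1)
    u = rng.random(n)
    for t in range(n):
        out.append(ALPHABET[state])
        state = int(np.searchsorted(cum[state], u[t], side="right"))
        state = min(state, 3)
    return SymbolSequence("".join(out), trial_boundaries=_boundaries(n), label=label)


# ---------------------------------------------------------------------------
# Motif machinery for the pattern-like and letter-like surrogates.
# ---------------------------------------------------------------------------


def _motif_displacement(motif: str) -> tuple[int, int]:
    dx = dy = 0
    for c in motif:
        mx, my = MOVES[c]
        dx, dy = dx + mx, dy + my
    return dx, dy


def _motif_bbox(motif: str) -> tuple[int, int, int, int]:
    """(min_dx, max_dx, min_dy, max_dy) of the running position from 0."""
    x = y = 0
    xs, ys = [0], [0]
    for c in motif:
        mx, my = MOVES[c]
        x, y = x + mx, y + my
        xs.append(x)
        ys.append(y)
    return min(xs), max(xs), min(ys), max(ys)


def random_closed_motif(rng: np.random.Generator, min_len: int = 6,
                        max_len: int = 20) -> str:
    """Sample a closed loop (zero net displacement) on the grid.

    Loops are rectangles or staircase diamonds in a random orientation,
    the shapes a repetitive drawing gesture traces.
    """
    for _ in range(200):
        if rng.random() < 0.7:  # rectangle a x b
            a = int(rng.integers(1, 6))
            b = int(rng.integers(1, 6))
            length = 2 * (a + b)
            h, v = ("r", "l") if rng.random() < 0.5 else ("l", "r")
            up, dn = ("u", "d") if rng.random() < 0.5 else ("d", "u")
            motif = h * a + up * b + v * a + dn * b
            if rng.random() < 0.5:  # vertical-first variant
                motif = up * b + h * a + dn * b + v * a
        else:  # staircase diamond of s steps per side
            s = int(rng.integers(1, 4))
            h, v = ("r", "l") if rng.random() < 0.5 else ("l", "r")
            up, dn = ("u", "d") if rng.random() < 0.5 else ("d", "u")
            motif = (h + up) * s + (v + up) * s + (v + dn) * s + (h + dn) * s
            length = len(motif)
        if min_len <= length <= max_len:
            return motif
    raise ValueError(f"no closed motif with length in [{min_len}, {max_len}]")


def _fit_start(motif: str, grid: GridSpec, rng: np.random.Generator,
               at: tuple[int, int] | None = None) -> tuple[int, int] | None:
    """A start cell from which the motif's bounding box stays in bounds."""
    minx, maxx, miny, maxy = _motif_bbox(motif)
    lo_x, hi_x = -minx, grid.width_cells - 1 - maxx
    lo_y, hi_y = -miny, grid.height_cells - 1 - maxy
    if lo_x > hi_x or lo_y > hi_y:
        return None
    if at is not None:
        i, j = at
        if lo_x <= i <= hi_x and lo_y <= j <= hi_y:
            return at
        return None
    return int(rng.integers(lo_x, hi_x + 1)), int(rng.integers(lo_y, hi_y + 1))


def gen_motif_pattern(
    motif: str | None = None,
    n: int = DEFAULT_N,
    switch_prob: float = 0.02,
    noise_prob: float = 0.005,
    seed: int = 0,
    grid: GridSpec | None = None,
    motif_len: tuple[int, int] = (8, 20),
    label: str = "P",
) -> SymbolSequence:
    """Pattern-like surrogate: a repeated closed motif with rare deviations.

    The motif must be a closed loop (zero net displacement) so indefinite
    repetition stays in bounds.  With probability ``noise_prob`` per symbol
    an admissible random move is substituted and immediately undone
    (returning to the motif path); with probability ``switch_prob`` per
    completed cycle the drawing switches to a freshly sampled closed motif,
    emulating a subject changing the repeated pattern between trials.
    """
    if grid is None:
        grid = GridSpec(10, 10, 1.0)
    rng = np.random.default_rng(seed)
    if motif is None:
        motif = random_closed_motif(rng, *motif_len)
    if _motif_displacement(motif) != (0, 0):
        raise ValueError("motif must be a closed loop (zero net displacement)")
    start = _fit_start(motif, grid, rng)
    if start is None:
        raise ValueError("motif does not fit inside the grid")
    i, j = start
    W, H = grid.width_cells, grid.height_cells
    out: list[str] = []
    while len(out) < n:
        for c in motif:
            if rng.random() < noise_prob:
                moves = [
                    m
                    for m, (dx, dy) in MOVES.items()
                    if 0 <= i + dx < W and 0 <= j + dy < H
                ]
                noise = moves[rng.integers(len(moves))]
                out.append(noise)
                out.append(INVERSE[noise])  # return to the motif path
            dx, dy = MOVES[c]
            i, j = i + dx, j + dy
            out.append(c)
            if len(out) >= n:
                break
        else:
            if rng.random() < switch_prob:
                for _ in range(50):
                    cand = random_closed_motif(rng, *motif_len)
                    if _fit_start(cand, grid, rng, at=(i, j)) is not None:
                        motif = cand
                        break
    return SymbolSequence(
        "".join(out[:n]), trial_boundaries=_boundaries(n), label=label
    )


def random_stroke_motif(rng: np.random.Generator, min_len: int = 10,
                        max_len: int = 20) -> str:
    """A stroke-like open motif: a walk that never immediately reverses."""
    length = int(rng.integers(min_len, max_len + 1))
    out = [ALPHABET[rng.integers(4)]]
    for _ in range(length - 1):
        options = [c for c in ALPHABET if c != INVERSE[out[-1]]]
        out.append(options[rng.integers(len(options))])
    return "".join(out)


def gen_motif_library(
    motifs: list[str] | None = None,
    n: int = DEFAULT_N,
    seed: int = 0,
    library_size: int = 10,
    motif_len: tuple[int, int] = (10, 20),
    label: str = "L",
) -> SymbolSequence:
    """Letter-like surrogate: uniform random concatenation of fixed motifs.

    Emulates copying letters drawn in random order: each motif is a fixed
    stroke pattern, the order of motifs carries the randomness.
    """
    rng = np.random.default_rng(seed)
    if motifs is None:
        motifs = [random_stroke_motif(rng, *motif_len) for _ in range(library_size)]
    if len(motifs) < 1 or any(not m for m in motifs):
        raise ValueError("motif library must contain non-empty motifs")
    out: list[str] = []
    while len(out) < n:
        out.extend(motifs[rng.integers(len(motifs))])
    return SymbolSequence(
        "".join(out[:n]), trial_boundaries=_boundaries(n), label=label
    )


def persistent_walk_matrix(
    p_repeat: float = 0.55, p_reverse: float = 0.05
) -> np.ndarray:
    """Transition matrix of a directionally persistent walk.

    A drawing hand in "random" mode keeps its direction more often than it
    backtracks; the two orthogonal turns share the remaining mass.
    """
    p_turn = (1.0 - p_repeat - p_reverse) / 2.0
    if p_turn < 0:
        raise ValueError("p_repeat + p_reverse must be <= 1")
    T = np.zeros((4, 4))
    for idx, c in enumerate(ALPHABET):
        for jdx, c2 in enumerate(ALPHABET):
            if c2 == c:
                T[idx, jdx] = p_repeat
            elif c2 == INVERSE[c]:
                T[idx, jdx] = p_reverse
            else:
                T[idx, jdx] = p_turn
    return T


def gen_regime_walk(
    n: int = DEFAULT_N,
    seed: int = 0,
    p_sweep_stay: float = 0.9,
    p_jitter_stay: float = 0.955,
    sweep_persistence: float = 0.92,
    grid: GridSpec | None = None,
    label: str = "R1",
) -> SymbolSequence:
    """Random-like surrogate: a two-mode persistent walk on the grid.

    Self-paced "random" drawing alternates between deliberate sweeps
    (long runs in one direction) and local jitter.  The composite state
    (mode, last direction) is an order-1 Markov chain; the emitted symbols
    are its projection, so conditional entropies decay gradually over
    several orders — the slow decay typical of human random motion — while
    one-step predictability stays modest.

    In ``sweep`` mode the previous direction repeats with probability
    ``sweep_persistence`` (remainder uniform over the other admissible
    moves); in ``jitter`` mode moves are uniform over all admissible
    moves.  Mode dwell times are geometric with the given stay
    probabilities.  Boundary cells truncate the admissible set, as a
    spring-walled workspace would.
    """
    if grid is None:
        grid = GridSpec(10, 10, 1.0)
    rng = np.random.default_rng(seed)
    W, H = grid.width_cells, grid.height_cells
    i, j = W // 2, H // 2
    mode_sweep = True
    prev: str | None = None
    out: list[str] = []
    for _ in range(n):
        stay = p_sweep_stay if mode_sweep else p_jitter_stay
        if rng.random() > stay:
            mode_sweep = not mode_sweep
        admissible = [
            c for c, (dx, dy) in MOVES.items()
            if 0 <= i + dx < W and 0 <= j + dy < H
        ]
        if mode_sweep and prev in admissible and rng.random() < sweep_persistence:
            c = prev
        else:
            pool = (
                [c for c in admissible if c != prev]
                if mode_sweep and prev in admissible
                else admissible
            )
            c = pool[rng.integers(len(pool))]
        dx, dy = MOVES[c]
        i, j = i + dx, j + dy
        out.append(c)
        prev = c
    return SymbolSequence("".join(out), trial_boundaries=_boundaries(n), label=label)


# ---------------------------------------------------------------------------
# Continuous test trajectories for the encoding layer.
# ---------------------------------------------------------------------------


def gen_trajectory(
    kind: str,
    duration_s: float,
    rate_hz: float = 1000.0,
    workspace: tuple[float, float] = (10.0, 10.0),
    seed: int = 0,
    **params,
) -> Trajectory:
    """Continuous synthetic trajectories: ``circle``, ``lissajous``, ``brownian``.

    Circle: ``radius`` (cm), ``period_s``; Lissajous: ``ax, ay`` amplitudes
    and ``fx, fy`` frequencies (Hz) with optional ``phase``; Brownian:
    ``step_cm`` per-sample standard deviation, reflective boundaries.
    """
    if duration_s <= 0:
        raise EmptyInputError("trajectory duration must be positive")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    W, Hh = workspace
    cx, cy = W / 2.0, Hh / 2.0
    if kind == "circle":
        radius = params.get("radius", 3.0)
        period = params.get("period_s", 2.0)
        if radius >= min(cx, cy):
            raise OutOfBoundsError("circle radius exceeds workspace")
        x = cx + radius * np.cos(2 * np.pi * t / period)
        y = cy + radius * np.sin(2 * np.pi * t / period)
    elif kind == "lissajous":
        ax_, ay_ = params.get("ax", 4.0), params.get("ay", 3.0)
        fx, fy = params.get("fx", 0.7), params.get("fy", 1.1)
        phase = params.get("phase", np.pi / 4)
        if ax_ >= cx or ay_ >= cy:
            raise OutOfBoundsError("lissajous amplitude exceeds workspace")
        x = cx + ax_ * np.sin(2 * np.pi * fx * t + phase)
        y = cy + ay_ * np.sin(2 * np.pi * fy * t)
    elif kind == "brownian":
        rng = np.random.default_rng(seed)
        step = params.get("step_cm", 0.05)
        steps = rng.normal(0.0, step, size=(n, 2))
        pos = np.cumsum(steps, axis=0) + np.array([cx, cy])
        # reflect into [0, W] x [0, H]
        x = np.abs(np.mod(pos[:, 0], 2 * W) - W)
        x = W - x
        y = np.abs(np.mod(pos[:, 1], 2 * Hh) - Hh)
        y = Hh - y
    elif kind == "smooth_random":
        # Ornstein-Uhlenbeck velocity: a differentiable random scribble with
        # hand-movement-like speed and curvature statistics.
        rng = np.random.default_rng(seed)
        tau = params.get("tau_s", 0.3)          # velocity correlation time
        speed = params.get("speed_cm_s", 4.0)   # per-axis RMS velocity
        dt = 1.0 / rate_hz
        sigma_eta = speed * math.sqrt(2.0 * dt / tau)
        v = np.zeros(2)
        pos = np.array([cx, cy])
        xs = np.empty(n)
        ys = np.empty(n)
        for idx in range(n):
            xs[idx], ys[idx] = pos
            v += -(dt / tau) * v + sigma_eta * rng.normal(size=2)
            pos = pos + v * dt
            for axis, lim in ((0, W), (1, Hh)):
                if pos[axis] < 0:
                    pos[axis] = -pos[axis]
                    v[axis] = -v[axis]
                elif pos[axis] > lim:
                    pos[axis] = 2 * lim - pos[axis]
                    v[axis] = -v[axis]
        x, y = xs, ys
    else:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    samples = np.column_stack([t * 1000.0, x, y])
    return Trajectory(samples, sampling_rate=rate_hz)


# ---------------------------------------------------------------------------
# The condition suite.
# ---------------------------------------------------------------------------

#: Condition labels of the reference design: three artificial processes and
#: three human-like surrogates.
CONDITIONS = ("AS", "P", "L", "R1", "AR", "AF")


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one generator call."""

    kind: str
    n: int = DEFAULT_N
    seed: int = 0
    params: dict = field(default_factory=dict)

    def generate(self) -> SymbolSequence:
        fns = {
            "rhythmic": lambda: gen_rhythmic(self.n, **self.params),
            "grid_random_walk": lambda: gen_grid_random_walk(
                n=self.n, seed=self.seed, **self.params
            ),
            "iid_frequencies": lambda: gen_iid_frequencies(
                n=self.n, seed=self.seed, **self.params
            ),
            "markov": lambda: gen_markov(n=self.n, seed=self.seed, **self.params),
            "motif_pattern": lambda: gen_motif_pattern(
                n=self.n, seed=self.seed, **self.params
            ),
            "motif_library": lambda: gen_motif_library(
                n=self.n, seed=self.seed, **self.params
            ),
        }
        if self.kind not in fns:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        return fns[self.kind]()


def generate_condition(label: str, seed: int = 0, n: int = DEFAULT_N) -> SymbolSequence:
    """One simulated subject-condition sequence with study-default parameters.

    ``AF`` matches the first-order frequencies of the same seed's
    pattern-like sequence, as the artificial frequency-matched process is
    defined relative to the pattern condition.
    """
    if label == "AS":
        return gen_rhythmic(n)
    if label == "AR":
        return gen_grid_random_walk(n=n, seed=seed)
    if label == "P":
        return gen_motif_pattern(n=n, seed=seed)
    if label == "L":
        return gen_motif_library(n=n, seed=seed, library_size=12, motif_len=(8, 16))
    if label == "R1":
        return gen_motif_library(
            n=n, seed=seed, library_size=32, motif_len=(6, 9), label="R1"
        )
    if label == "AF":
        pattern = gen_motif_pattern(n=n, seed=seed)
        counts = np.array([pattern.symbols.count(c) for c in ALPHABET], dtype=float)
        freqs = counts / counts.sum()
        return gen_iid_frequencies(freqs, n=n, seed=seed)
    raise ValueError(f"unknown condition label {label!r}")


def generate_suite(seed: int = 0, n: int = DEFAULT_N,
                   labels=CONDITIONS) -> dict[str, SymbolSequence]:
    """All conditions for one simulated subject (seeded reproducibly)."""
    return {lab: generate_condition(lab, seed=seed, n=n) for lab in labels}
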