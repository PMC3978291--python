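"""Per-condition measure panels, pairwise statistics, the pursuit game,
and the grid-size sweep.

The panel bundles the seven measures reported per subject-condition:
predictability, LZ and CTW compressibility, approximate entropy at m = 1
and m = 2, LZ-76 complexity, and effective measure complexity.  Pairwise
condition contrasts use the two-sided Mann-Whitney-Wilcoxon test with
Bonferroni-Holm step-down correction within each measure.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import ctw as _ctw
from . import entropy as _entropy
from . import regularity as _reg
from .encoding import GridSpec, Trajectory, discretize, regrid
from .sequences import ALPHABET, MOVES, SymbolSequence

logger = logging.getLogger("symcomplex")

#: Panel measure columns in reporting order.
MEASURES = (
    "predictability",
    "eta_lz",
    "eta_ctw",
    "apen_m1",
    "apen_m2",
    "lz_complexity",
    "emc",
)

#: Measures for which larger values mean more irregularity.
IRREGULARITY_MEASURES = ("eta_lz", "eta_ctw", "apen_m1", "apen_m2", "lz_complexity")


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the per-sequence analysis."""

    ctw_depth: int = 8
    apen_r_factor: float = 0.2
    emc_L_max_emp: int = 4
    emc_L_trunc: int = 64
    reset_per_trial: bool = False


@dataclass(frozen=True)
class MeasurePanel:
    """The seven per-sequence measures for one subject-condition."""

    label: str
    subject: int
    predictability: float
    eta_lz: float
    eta_ctw: float
    apen_m1: float
    apen_m2: float
    lz_complexity: int
    lz_complexity_normalized: float
    emc: float
    h_rate: float
    alpha: float | None
    partial: bool = False


def compute_panel(
    seq: SymbolSequence,
    config: AnalysisConfig | None = None,
    subject: int = 0,
) -> MeasurePanel:
    """All seven measures for one sequence."""
    cfg = config or AnalysisConfig()
    label = seq.label or "?"
    logger.debug("panel: label=%s subject=%d n=%d", label, subject, len(seq))
    ana = _ctw.ctw_analyze(seq, depth=cfg.ctw_depth, reset_per_trial=cfg.reset_per_trial)
    parse = _reg.lz76_parse(seq)
    try:
        emc_est = _entropy.estimate_emc(
            seq, L_max_emp=cfg.emc_L_max_emp, L_trunc=cfg.emc_L_trunc
        )
        emc_fields = dict(emc=emc_est.emc, h_rate=emc_est.h_rate, alpha=emc_est.alpha)
        partial = False
    except (_entropy.UnreliableOrderError, _entropy.InsufficientDataError) as exc:
        logger.warning("EMC unavailable for %s (n=%d): %s", label, len(seq), exc)
        emc_fields = dict(emc=float("nan"), h_rate=float("nan"), alpha=None)
        partial = True
    return MeasurePanel(
        label=label,
        subject=subject,
        predictability=ana.predictability.gamma,
        eta_lz=_reg.lz_compress(seq).eta,
        eta_ctw=ana.compression.eta,
        apen_m1=_reg.apen(seq, m=1, r_factor=cfg.apen_r_factor),
        apen_m2=_reg.apen(seq, m=2, r_factor=cfg.apen_r_factor),
        lz_complexity=parse.c,
        lz_complexity_normalized=_reg.lz_entropy_rate(seq),
        partial=partial,
        **emc_fields,
    )


def analyze_condition(
    seqs: list[SymbolSequence],
    config: AnalysisConfig | None = None,
) -> list[MeasurePanel]:
    """One panel per subject for a list of same-condition sequences."""
    if not seqs:
        raise ValueError("need at least one sequence")
    return [compute_panel(s, config, subject=i) for i, s in enumerate(seqs)]


def panels_to_frame(panels: list[MeasurePanel]) -> pd.DataFrame:
    """Panels as a tidy DataFrame, one row per subject-condition."""
    return pd.DataFrame([asdict(p) for p in panels])


@dataclass(frozen=True)
class ComparisonTable:
    """Pairwise Mann-Whitney-Wilcoxon contrasts for one measure."""

    measure: str
    pairs: tuple[tuple[str, str], ...]
    raw_p: tuple[float, ...]
    adj_p: tuple[float, ...]
    stars: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": [f"{a}-{b}" for a, b in self.pairs],
                "raw_p": self.raw_p,
                "adj_p": self.adj_p,
                "stars": self.stars,
            }
        )


def omnibus_effect(panels: list[MeasurePanel] | pd.DataFrame, measure: str) -> float:
    """Kruskal-Wallis p-value for an overall effect across all conditions.

    An omnibus companion to the pairwise contrasts (an extension beyond
    the rank-sum pairs; reported in the "effect across conditions" slot).
    """
    df = panels if isinstance(panels, pd.DataFrame) else panels_to_frame(panels)
    groups = [g[measure].to_numpy(float) for _, g in df.groupby("label", sort=False)]
    if len(groups) < 2:
        raise ValueError("need at least two conditions")
    return float(stats.kruskal(*groups).pvalue)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "-"


def compare_conditions(
    panels: list[MeasurePanel] | pd.DataFrame,
    measure: str,
    pairs: list[tuple[str, str]] | None = None,
) -> ComparisonTable:
    """Two-sided MWW tests with Holm correction across the pair family.

    The correction family is the set of pairwise contrasts within this one
    measure.  Identical (all-tied) groups yield p = 1 with a warning.
    """
    df = panels if isinstance(panels, pd.DataFrame) else panels_to_frame(panels)
    if measure not in df.columns:
        raise KeyError(f"unknown measure {measure!r}")
    labels = list(dict.fromkeys(df["label"]))
    if len(labels) < 2:
        raise ValueError("need at least two conditions to compare")
    if pairs is None:
        pairs = list(combinations(labels, 2))
    raw = []
    for a, b in pairs:
        xa = df.loc[df["label"] == a, measure].to_numpy(float)
        xb = df.loc[df["label"] == b, measure].to_numpy(float)
        if min(len(xa), len(xb)) < 3:
            raise ValueError("need >= 3 subjects per condition")
        if np.ptp(np.concatenate([xa, xb])) == 0:
            logger.warning("all observations tied for %s-%s; p = 1", a, b)
            raw.append(1.0)
            continue
        raw.append(float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue))
    adj = multipletests(raw, method="holm")[1]
    return ComparisonTable(
        measure=measure,
        pairs=tuple(pairs),
        raw_p=tuple(raw),
        adj_p=tuple(float(p) for p in adj),
        stars=tuple(significance_stars(p) for p in adj),
    )


# ---------------------------------------------------------------------------
# Pursuit game
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PursuitConfig:
    """Closed-loop prediction game configuration.

    An online CTW predictor forecasts each grid move of an evader policy;
    in ``online`` feedback mode the policy learns each hit immediately, in
    ``offline`` mode only the end-of-trial hit fraction.
    """

    evader_policy: str = "uniform"  # uniform | anti_map | softmax_evasive
    n_trials: int = 50
    transitions_per_trial: int = 200
    feedback: str = "offline"  # online | offline
    depth: int = 8
    softmax_beta: float = 10.0
    grid: GridSpec = field(default_factory=GridSpec)


@dataclass(frozen=True)
class PursuitResult:
    """Per-trial predictability trace plus the full emitted sequence."""

    per_trial_gamma: tuple[float, ...]
    sequence: SymbolSequence

    @property
    def gamma(self) -> float:
        return float(np.mean(self.per_trial_gamma))

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trial": np.arange(1, len(self.per_trial_gamma) + 1),
             "gamma": self.per_trial_gamma}
        )


def pursuit_simulate(cfg: PursuitConfig, seed: int = 0,
                     evader_sequence: SymbolSequence | None = None) -> PursuitResult:
    """Run the pursuit game: evader emits moves, a persistent CTW model
    predicts each one before seeing it.

    The context trees learn online across trials through the whole
    session.  ``evader_sequence`` replaces the policy with a scripted
    move source (e.g. a deterministic repetition) for testing.
    """
    rng = np.random.default_rng(seed)
    model = _ctw.ContextTreeModel(depth=cfg.depth)
    grid = cfg.grid
    W, H = grid.width_cells, grid.height_cells
    i, j = W // 2, H // 2
    scripted = iter(evader_sequence.symbols) if evader_sequence is not None else None
    gammas = []
    all_syms: list[str] = []
    last_hit: bool | None = None  # online feedback to the policy
    trial_fraction = 0.0  # offline feedback to the policy
    for _ in range(cfg.n_trials):
        hits = 0
        for _ in range(cfg.transitions_per_trial):
            admissible = [
                c for c, (dx, dy) in MOVES.items()
                if 0 <= i + dx < W and 0 <= j + dy < H
            ]
            pred, dist = model.predict_symbol()
            if scripted is not None:
                move = next(scripted)
            elif cfg.evader_policy == "uniform":
                move = admissible[rng.integers(len(admissible))]
            elif cfg.evader_policy == "anti_map":
                move = min(admissible, key=lambda c: dist[c])
            elif cfg.evader_policy == "softmax_evasive":
                # Feedback-modulated evasion: press away from the predictor
                # harder while being caught.
                beta = cfg.softmax_beta
                if cfg.feedback == "online" and last_hit is not None:
                    beta *= 1.5 if last_hit else 0.75
                elif cfg.feedback == "offline":
                    beta *= 0.5 + trial_fraction
                w = np.array([np.exp(-beta * dist[c]) for c in admissible])
                move = admissible[rng.choice(len(admissible), p=w / w.sum())]
            else:
                raise ValueError(f"unknown evader policy {cfg.evader_policy!r}")
            hit = pred == move
            hits += hit
            if cfg.feedback == "online":
                last_hit = hit
            model.update(move)
            dx, dy = MOVES[move]
            i, j = i + dx, j + dy
            all_syms.append(move)
        gammas.append(hits / cfg.transitions_per_trial)
        trial_fraction = gammas[-1]
    n = len(all_syms)
    seq = SymbolSequence(
        "".join(all_syms),
        trial_boundaries=tuple(
            range(cfg.transitions_per_trial, n, cfg.transitions_per_trial)
        ),
        label="R2" if cfg.feedback == "offline" else "RF",
    )
    return PursuitResult(per_trial_gamma=tuple(gammas), sequence=seq)


# ---------------------------------------------------------------------------
# Grid-size sweep
# ---------------------------------------------------------------------------


def grid_size_sweep(
    trajs: dict[str, Trajectory],
    sizes: list[float],
    config: AnalysisConfig | None = None,
    workspace: tuple[float, float] = (10.0, 10.0),
) -> pd.DataFrame:
    """Measure panels per (condition, cell size) after re-discretization.

    For smooth trajectories the finer the grid, the higher the regularity
    and the larger the unnormalized LZ complexity; the relative condition
    ordering is preserved across sizes.
    """
    rows = []
    for label, traj in trajs.items():
        seqs = regrid(traj, sizes, workspace=workspace)
        for size, seq in seqs.items():
            if len(seq) < 10:
                logger.warning(
                    "label=%s size=%s yields only %d transitions; skipped",
                    label, size, len(seq),
                )
                continue
            panel = compute_panel(seq.with_label(label), config)
            row = asdict(panel)
            row["cell_size"] = size
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------


def write_panels_tsv(path, panels: list[MeasurePanel]) -> None:
    panels_to_frame(panels).to_csv(path, sep="\t", index=False)


def read_panels_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def provenance_block(config, seed: int) -> dict:
    """Run metadata written next to every report."""
    from . import __version__

    cfg_json = json.dumps(asdict(config) if hasattr(config, "__dataclass_fields__")
                          else dict(config), sort_keys=True, default=str)
    return {
        "config_sha1": hashlib.sha1(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
    }
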