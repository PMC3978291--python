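"""Statsmodels-style front end: one model object per sequence.

``SequenceComplexity`` wraps the full measure battery behind a familiar
``model.fit() -> results`` interface; the results object carries the seven
measures, the entropy profile behind the EMC estimate, and a printable
summary table.
"""

from __future__ import annotations

import numpy as np

from .entropy import ExcessEntropyModel, ExcessEntropyResults
from .pipeline import AnalysisConfig, MeasurePanel, compute_panel
from .sequences import SymbolSequence


class SequenceComplexity:
    """Randomness/complexity analysis of one symbol sequence.

    Parameters
    ----------
    seq : SymbolSequence or str
        The symbolized trajectory to analyze.
    config : AnalysisConfig, optional
        CTW depth, ApEn tolerance factor, and EMC orders.

    Examples
    --------
    >>> from symcomplex.synthetic import gen_rhythmic
    >>> res = SequenceComplexity(gen_rhythmic(10000)).fit()
    >>> res.panel.predictability > 0.99
    True
    """

    def __init__(self, seq: SymbolSequence | str, config: AnalysisConfig | None = None):
        self.seq = seq if isinstance(seq, SymbolSequence) else SymbolSequence(seq)
        self.config = config or AnalysisConfig()

    def fit(self) -> "SequenceComplexityResults":
        panel = compute_panel(self.seq, self.config)
        entropy_res = ExcessEntropyModel(
            self.seq,
            L_max_emp=self.config.emc_L_max_emp,
            L_trunc=self.config.emc_L_trunc,
        ).fit()
        return SequenceComplexityResults(self, panel, entropy_res)


class SequenceComplexityResults:
    """Measure panel plus the entropy profile for one sequence."""

    def __init__(self, model: SequenceComplexity, panel: MeasurePanel,
                 entropy: ExcessEntropyResults):
        self.model = model
        self.panel = panel
        self.entropy = entropy

    def __getattr__(self, name):
        # expose panel fields (predictability, eta_lz, ..., emc) directly
        try:
            return getattr(self.__dict__["panel"], name)
        except (KeyError, AttributeError):
            raise AttributeError(name)

    def summary(self) -> str:
        p = self.panel
        rows = [
            ("Predictability gamma", f"{p.predictability:.4f}"),
            ("LZ compressibility eta", f"{p.eta_lz:.4f}"),
            ("CTW compressibility eta", f"{p.eta_ctw:.4f}"),
            ("ApEn (m=1)", f"{p.apen_m1:.4f}"),
            ("ApEn (m=2)", f"{p.apen_m2:.4f}"),
            ("LZ-76 complexity c", f"{p.lz_complexity}"),
            ("  normalized (entropy rate)", f"{p.lz_complexity_normalized:.4f}"),
            ("Effective measure complexity", f"{p.emc:.4f}"),
            ("  entropy-rate asymptote", f"{p.h_rate:.4f}"),
            ("  decay exponent alpha",
             f"{p.alpha:.4f}" if p.alpha is not None else "degenerate"),
        ]
        width = max(len(r[0]) for r in rows) + 2
        lines = [
            "Symbol-Sequence Complexity",
            "=" * (width + 10),
            f"{'label':<{width}}{p.label}",
            f"{'N':<{width}}{len(self.model.seq)}",
            "-" * (width + 10),
        ]
        lines += [f"{name:<{width}}{val}" for name, val in rows]
        return "\n".join(lines)

    def plot_entropy_profile(self, ax=None):
        return self.entropy.plot(ax=ax)
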