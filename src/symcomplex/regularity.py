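"""Model-free regularity measures: approximate entropy, LZ-76 complexity,
normalized-LZ entropy-rate estimation, and dictionary (LZW) compression.

Approximate entropy (ApEn) compares how often length-m templates recur
within tolerance r against how often their length-(m+1) extensions do;
larger values mean more irregularity.  LZ-76 complexity counts the minimal
number of distinct phrases in the exhaustive-history segmentation of a
string; normalized by log_k(N)/N it is a consistent estimator of the
entropy rate of a stationary ergodic source.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .ctw import CompressionResult
from .sequences import EmptyInputError, SymbolSequence

R_FACTORS = (0.1, 0.15, 0.2, 0.25)


@dataclass(frozen=True)
class ApEnParams:
    """Approximate-entropy parameters.

    m is the template (run) length and r = r_factor * SD of the numeric
    sequence is the match tolerance.  For the four-symbol integer coding
    (l→1, r→2, u→3, d→4) every r_factor in {0.1, 0.15, 0.2, 0.25} yields
    r < 1, so matching reduces to exact template equality and the value is
    independent of r_factor.
    """

    m: int = 1
    r_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r_factor > 0:
            raise ValueError("r_factor must be positive")


def _phi_exact(x: np.ndarray, m: int) -> float:
    """phi_m for tolerance below the minimal nonzero gap (exact matching)."""
    n_vec = len(x) - m + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, m)
    _, inverse, counts = np.unique(
        windows, axis=0, return_inverse=True, return_counts=True
    )
    c_i = counts[inverse] / n_vec
    return float(np.mean(np.log(c_i)))


def _phi_general(x: np.ndarray, m: int, r: float) -> float:
    """phi_m by direct pairwise Chebyshev comparison (chunked O(N^2))."""
    n_vec = len(x) - m + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, m).astype(float)
    counts = np.zeros(n_vec, dtype=np.int64)
    chunk = max(1, int(2e7) // max(1, n_vec))
    for start in range(0, n_vec, chunk):
        block = windows[start : start + chunk]
        d = np.abs(block[:, None, :] - windows[None, :, :]).max(axis=2)
        counts[start : start + chunk] = (d < r).sum(axis=1)
    return float(np.mean(np.log(counts / n_vec)))


def apen(
    seq: SymbolSequence | np.ndarray,
    params: ApEnParams | None = None,
    m: int | None = None,
    r_factor: float | None = None,
) -> float:
    """Approximate entropy ApEn(m, r) of an integer-coded sequence.

    Implements the classic Pincus procedure: embedding vectors X_i of
    length m, Chebyshev distance, match counts with d < r (strict) that
    include the self-match, phi = mean natural log of the match fractions,
    and ApEn = phi_m - phi_{m+1}.

    A constant sequence has SD = 0, hence r = 0; it is maximally regular
    and returns 0 with a warning.
    """
    if params is None:
        params = ApEnParams(
            m=1 if m is None else m,
            r_factor=0.2 if r_factor is None else r_factor,
        )
    x = seq.numeric() if isinstance(seq, SymbolSequence) else np.asarray(seq)
    if len(x) <= params.m + 1:
        raise ValueError("sequence too short for the chosen m")
    sigma = float(np.std(x))
    if sigma == 0.0:
        warnings.warn("constant sequence: SD = 0, returning ApEn = 0", stacklevel=2)
        return 0.0
    r = params.r_factor * sigma
    is_integral = np.allclose(x, np.round(x))
    if is_integral and r < 1.0:
        xi = np.round(x).astype(np.int64)
        phi_m = _phi_exact(xi, params.m)
        phi_m1 = _phi_exact(xi, params.m + 1)
    else:
        phi_m = _phi_general(x, params.m, r)
        phi_m1 = _phi_general(x, params.m + 1, r)
    return phi_m - phi_m1


@dataclass(frozen=True)
class LZ76Parse:
    """Exhaustive-history Lempel-Ziv (1976) segmentation of a string."""

    phrases: tuple[str, ...]

    @property
    def c(self) -> int:
        """Phrase count (the LZ-76 complexity)."""
        return len(self.phrases)

    def __post_init__(self) -> None:
        object.__setattr__(self, "phrases", tuple(self.phrases))


def lz76_parse(seq: SymbolSequence | str) -> LZ76Parse:
    """LZ-76 exhaustive-history parsing.

    Each new phrase is the shortest prefix of the remaining text that
    cannot be reproduced by copying from previously seen text (self-overlap
    allowed); the final, possibly reproducible, fragment counts as one
    phrase.  The binary string ``01001101010111001001`` parses into
    ``0|1|00|11|0101|0111|0010|01``, complexity 8.
    """
    s = seq.symbols if isinstance(seq, SymbolSequence) else seq
    if not s:
        raise EmptyInputError("cannot parse an empty string")
    n = len(s)
    phrases: list[str] = []
    i = 0
    while i < n:
        length = 1
        # Grow the candidate while it is a substring of the text that
        # precedes its last character (reproducibility with overlap).
        while i + length <= n and s.find(s[i : i + length], 0, i + length - 1) != -1:
            length += 1
        phrases.append(s[i : min(i + length, n)])
        i += length
    return LZ76Parse(tuple(phrases))


def lz_entropy_rate(seq: SymbolSequence | str, k: int | None = None) -> float:
    """Entropy-rate estimate from the normalized LZ-76 complexity.

    h = c(N) * log_k(N) / N, clipped to [0, 1], in base-k units per
    symbol.  Consistent for stationary ergodic sources; convergence is
    slow, so sequences shorter than ~100 symbols trigger a warning.
    """
    s = seq.symbols if isinstance(seq, SymbolSequence) else seq
    if k is None:
        k = seq.k if isinstance(seq, SymbolSequence) else max(2, len(set(s)))
    n = len(s)
    if n < 100:
        warnings.warn(
            "normalized LZ complexity is unreliable below ~100 symbols",
            stacklevel=2,
        )
    c = lz76_parse(s).c
    h = c * math.log(n, k) / n
    return min(max(h, 0.0), 1.0)


def lzw_tokens(s: str, alphabet: tuple[str, ...]) -> list[int]:
    table = {ch: i for i, ch in enumerate(alphabet)}
    tokens: list[int] = []
    w = s[0]
    for ch in s[1:]:
        if w + ch in table:
            w += ch
        else:
            tokens.append(table[w])
            table[w + ch] = len(table)
            w = ch
    tokens.append(table[w])
    return tokens


def lz_compress(seq: SymbolSequence | str) -> CompressionResult:
    """Dictionary (LZW) compression with growing code width.

    The dictionary starts with the single symbols of the alphabet; each
    emitted token is charged ceil(log2(dictionary size at emission)) bits.
    The original length is counted at 8 bits per symbol (byte coding), so
    eta = (N - N_comp)/N is directly comparable with the CTW coder.
    """
    s = seq.symbols if isinstance(seq, SymbolSequence) else seq
    if not s:
        raise EmptyInputError("cannot compress an empty string")
    alphabet = (
        tuple(seq.alphabet) if isinstance(seq, SymbolSequence) else tuple(sorted(set(s)))
    )
    n_bits = 0
    # Re-run the tokenizer while tracking the table size at each emission.
    table = {ch: i for i, ch in enumerate(alphabet)}
    w = s[0]
    for ch in s[1:]:
        if w + ch in table:
            w += ch
        else:
            n_bits += max(1, math.ceil(math.log2(len(table))))
            table[w + ch] = len(table)
            w = ch
    n_bits += max(1, math.ceil(math.log2(len(table))))
    return CompressionResult(N=8 * len(s), N_comp=n_bits)


def lzw_decompress(tokens: list[int], alphabet: tuple[str, ...]) -> str:
    """Decode an LZW token stream produced by :func:`lzw_tokens`."""
    if not tokens:
        return ""
    table = list(alphabet)
    prev = table[tokens[0]]
    out = [prev]
    for code in tokens[1:]:
        if code < len(table):
            entry = table[code]
        elif code == len(table):  # the cScSc corner case
            entry = prev + prev[0]
        else:
            raise ValueError("corrupt LZW stream")
        out.append(entry)
        table.append(prev + entry[0])
        prev = entry
    return "".join(out)
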