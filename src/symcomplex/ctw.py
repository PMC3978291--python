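"""Context-Tree Weighting prediction and compression.

CTW is an online Bayesian mixture over all binary tree sources up to a
fixed depth D.  Each node of a binary suffix tree carries zero/one counts
and predicts with the Krichevsky-Trofimov (KT) add-1/2 estimator

    P(next = 0 | a zeros, b ones) = (a + 1/2) / (a + b + 1).

The weighted probability of a node mixes "this node is a leaf of the true
source tree" with "the source splits on one more context bit":

    P_w(n) = P_kt(n)                         if n is at maximal depth,
    P_w(n) = 1/2 P_kt(n) + 1/2 P_w(n0) P_w(n1)  otherwise.

To handle the 4-symbol transition alphabet, each symbol is expanded into
the 8 bits of its ASCII code and eight context trees run in parallel, one
per bit position; tree i conditions on the history of its own bit stream
up to depth D bits (= D past transitions).  A symbol's predictive
probability is the product of its eight per-bit probabilities,
renormalized over the four valid symbols.

All probability arithmetic is carried out in the log domain so that
length-10,000 sequences (total probabilities around 2^-20000) are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .sequences import ALPHABET, AlphabetError, SymbolSequence

LOG_HALF = math.log(0.5)

# Node layout: [a, b, log_kt, log_w], stored per tree in a dict keyed by a
# "marked" context integer (1 << depth) | prefix_bits (most recent bit in
# the lowest position), which is unique across depths.


@dataclass(frozen=True)
class KTCounts:
    """Zero/one counts at a context node."""

    a: int = 0
    b: int = 0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("counts must be non-negative")


def kt_probability(counts: KTCounts, next_bit: int) -> float:
    """KT predictive probability of the next bit given past counts."""
    p0 = (counts.a + 0.5) / (counts.a + counts.b + 1.0)
    return p0 if next_bit == 0 else 1.0 - p0


def kt_log_prob_sequence(bits) -> float:
    """Natural-log KT probability of a whole bit string (chain rule)."""
    a = b = 0
    lp = 0.0
    for bit in bits:
        if bit == 0:
            lp += math.log((a + 0.5) / (a + b + 1.0))
            a += 1
        else:
            lp += math.log((b + 0.5) / (a + b + 1.0))
            b += 1
    return lp


class ContextTree:
    """One binary CTW suffix tree of fixed depth over its own bit stream."""

    __slots__ = ("depth", "nodes", "context", "_mask")

    def __init__(self, depth: int):
        if depth < 0:
            raise ValueError("depth must be >= 0")
        self.depth = depth
        self.nodes: dict[int, list] = {}
        # Past bits, most recent in the lowest position; zero-padded start.
        self.context = 0
        self._mask = (1 << depth) - 1 if depth else 0

    def _node(self, key: int) -> list:
        node = self.nodes.get(key)
        if node is None:
            node = [0, 0, 0.0, 0.0]
            self.nodes[key] = node
        return node

    @property
    def root_log_w(self) -> float:
        node = self.nodes.get(1)
        return node[3] if node is not None else 0.0

    def _path_keys(self) -> list[int]:
        ctx = self.context
        return [(1 << d) | (ctx & ((1 << d) - 1)) for d in range(self.depth + 1)]

    def _trial_root_log_w(self, keys: list[int], bit: int) -> float:
        """Root log P_w if ``bit`` were appended in the current context."""
        D = self.depth
        nodes = self.nodes
        lw_child = 0.0
        for d in range(D, -1, -1):
            node = nodes.get(keys[d])
            a, b, log_kt = (node[0], node[1], node[2]) if node else (0, 0, 0.0)
            if bit == 0:
                lkt_new = log_kt + math.log((a + 0.5) / (a + b + 1.0))
            else:
                lkt_new = log_kt + math.log((b + 0.5) / (a + b + 1.0))
            if d == D:
                lw = lkt_new
            else:
                # keys[d+1] encodes the on-path child; flipping bit d gives
                # the sibling.
                sib = nodes.get(keys[d + 1] ^ (1 << d))
                lw_off = sib[3] if sib else 0.0
                lw = _log_add(LOG_HALF + lkt_new, LOG_HALF + lw_child + lw_off)
            lw_child = lw
        return lw_child

    def predictive(self) -> tuple[float, float]:
        """(P(0), P(1)) for the next bit in the current context."""
        keys = self._path_keys()
        root = self.root_log_w
        p0 = math.exp(self._trial_root_log_w(keys, 0) - root)
        p1 = math.exp(self._trial_root_log_w(keys, 1) - root)
        return p0, p1

    def update(self, bit: int) -> tuple[float, float]:
        """Observe one bit; return (P(0), P(1)) assigned before the update."""
        keys = self._path_keys()
        root = self.root_log_w
        lw0 = self._trial_root_log_w(keys, 0)
        lw1 = self._trial_root_log_w(keys, 1)
        p = (math.exp(lw0 - root), math.exp(lw1 - root))
        # Commit: recompute the path bottom-up for the realized bit.
        D = self.depth
        ctx = self.context
        lw_child = 0.0
        for d in range(D, -1, -1):
            node = self._node(keys[d])
            a, b = node[0], node[1]
            if bit == 0:
                node[2] += math.log((a + 0.5) / (a + b + 1.0))
                node[0] = a + 1
            else:
                node[2] += math.log((b + 0.5) / (a + b + 1.0))
                node[1] = b + 1
            if d == D:
                node[3] = node[2]
            else:
                sib = self.nodes.get(keys[d + 1] ^ (1 << d))
                lw_off = sib[3] if sib else 0.0
                node[3] = _log_add(LOG_HALF + node[2], LOG_HALF + lw_child + lw_off)
            lw_child = node[3]
        if D:
            self.context = ((ctx << 1) | bit) & self._mask
        return p

    def reset_context(self) -> None:
        """Zero the sliding context (counts are kept)."""
        self.context = 0


def _log_add(x: float, y: float) -> float:
    if x < y:
        x, y = y, x
    return x + math.log1p(math.exp(y - x))


@dataclass(frozen=True)
class PredictabilityResult:
    """Outcome of online one-step-ahead prediction over a sequence."""

    n_m: int
    N: int

    @property
    def gamma(self) -> float:
        return self.n_m / self.N


@dataclass(frozen=True)
class CompressionResult:
    """Ideal code length of a sequence under a model or compressor."""

    N: int        # original length in bits
    N_comp: int   # compressed length in bits

    @property
    def eta(self) -> float:
        return (self.N - self.N_comp) / self.N


class ContextTreeModel:
    """Eight parallel binary context trees over byte-decomposed symbols.

    Parameters
    ----------
    depth : int
        Maximum context length in bits per tree; with one bit per symbol
        per tree this equals the number of past transitions conditioned on.
    alphabet : str
        Symbol alphabet; byte codes are the 8-bit ASCII codes.
    """

    def __init__(self, depth: int = 8, alphabet: str = ALPHABET):
        if len(alphabet) > 256:
            raise AlphabetError("byte decomposition supports at most 256 symbols")
        self.depth = depth
        self.alphabet = alphabet
        self.byte_map = {c: ord(c) for c in alphabet}
        if len(set(self.byte_map.values())) != len(alphabet):
            raise AlphabetError("byte map must be injective over the alphabet")
        self.trees = [ContextTree(depth) for _ in range(8)]
        # Precomputed bit patterns, most significant bit = tree 0.
        self._bits = {
            c: tuple((code >> (7 - i)) & 1 for i in range(8))
            for c, code in self.byte_map.items()
        }

    def predict_distribution(self) -> dict[str, float]:
        """Predictive distribution over the alphabet in the current state."""
        per_tree = [t.predictive() for t in self.trees]
        weights = {}
        for c, bits in self._bits.items():
            w = 1.0
            for i in range(8):
                w *= per_tree[i][bits[i]]
            weights[c] = w
        total = sum(weights.values())
        return {c: w / total for c, w in weights.items()}

    def predict_symbol(self) -> tuple[str, dict[str, float]]:
        """MAP next symbol (ties broken by alphabet order) and distribution."""
        dist = self.predict_distribution()
        best = max(self.alphabet, key=lambda c: dist[c])  # max is stable: first wins ties
        # Python's max keeps the first of equal keys, i.e. alphabet order.
        return best, dist

    def update(self, symbol: str) -> float:
        """Observe one symbol; return the joint 8-bit probability it was
        assigned before the update (unnormalized over the alphabet — this is
        the coding probability of its byte)."""
        bits = self._bits.get(symbol)
        if bits is None:
            raise AlphabetError(f"symbol {symbol!r} not in alphabet")
        p = 1.0
        for i, tree in enumerate(self.trees):
            probs = tree.update(bits[i])
            p *= probs[bits[i]]
        return p

    def reset_context(self) -> None:
        for t in self.trees:
            t.reset_context()


@dataclass(frozen=True)
class CTWAnalysis:
    """Joint result of one online CTW pass over a sequence."""

    predictability: PredictabilityResult
    compression: CompressionResult
    log2_prob: float  # total byte-stream log2 probability


def ctw_analyze(
    seq: SymbolSequence,
    depth: int = 8,
    reset_per_trial: bool = False,
) -> CTWAnalysis:
    """One online pass computing predictability and ideal code length.

    The model predicts each symbol one step ahead, is scored, and is then
    updated with the realized symbol.  Counts persist across trial
    boundaries by default; with ``reset_per_trial`` the sliding context
    (not the counts) is zeroed at each boundary.
    """
    if len(seq) == 0:
        raise ValueError("cannot analyze an empty sequence")
    model = ContextTreeModel(depth=depth, alphabet=seq.alphabet)
    boundaries = set(seq.trial_boundaries) if reset_per_trial else ()
    n_m = 0
    log2_total = 0.0
    for idx, sym in enumerate(seq.symbols):
        if idx in boundaries and idx > 0:
            model.reset_context()
        pred, _ = model.predict_symbol()
        if pred == sym:
            n_m += 1
        p = model.update(sym)
        log2_total += math.log2(p)
    n_bits = 8 * len(seq)
    n_comp = math.ceil(-log2_total) + 2  # ideal arithmetic-coder bound
    return CTWAnalysis(
        predictability=PredictabilityResult(n_m=n_m, N=len(seq)),
        compression=CompressionResult(N=n_bits, N_comp=n_comp),
        log2_prob=log2_total,
    )


def predictability(seq: SymbolSequence, depth: int = 8, **kw) -> PredictabilityResult:
    """Fraction of transitions predicted correctly one step ahead (gamma)."""
    if len(seq) < 2:
        raise ValueError("predictability needs a sequence of length >= 2")
    return ctw_analyze(seq, depth=depth, **kw).predictability


def ctw_code_length(seq: SymbolSequence, depth: int = 8, **kw) -> CompressionResult:
    """Ideal arithmetic-coding length under the CTW coding distribution."""
    return ctw_analyze(seq, depth=depth, **kw).compression
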