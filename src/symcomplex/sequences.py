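"""Symbol sequences over the four-letter cell-transition alphabet.

A trajectory through a planar grid is reduced to the sequence of cell
transitions it makes: ``l``, ``r``, ``u``, ``d`` for left/right/up/down.
:class:`SymbolSequence` is the universal currency of the package: every
regularity and complexity measure consumes one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical alphabet in its fixed order.  The order matters only for
#: maximum-a-posteriori tie-breaking in prediction.
ALPHABET = "lrud"

#: Unit grid moves for each symbol (dx, dy), y pointing upward.
MOVES = {"l": (-1, 0), "r": (1, 0), "u": (0, 1), "d": (0, -1)}

#: Opposite move of each symbol.
INVERSE = {"l": "r", "r": "l", "u": "d", "d": "u"}

#: Numeric representation used by approximate entropy.
NUMERIC_MAP = {"l": 1, "r": 2, "u": 3, "d": 4}


class AlphabetError(ValueError):
    """A symbol outside the declared alphabet was encountered."""


class EmptyInputError(ValueError):
    """An operation that needs data received an empty input."""


@dataclass(frozen=True)
class SymbolSequence:
    """A finite string over a k-ary alphabet with trial-boundary metadata.

    Parameters
    ----------
    symbols : str
        The sequence itself, e.g. ``"rruudd"``.
    trial_boundaries : tuple of int
        Sorted split indices in ``[0, len]`` marking junctions where
        independently recorded trials were concatenated.
    label : str or None
        Free-text condition tag (``P``, ``L``, ``R1``, ``AS`` ...).
    alphabet : str
        Ordered alphabet; every character of ``symbols`` must be in it.
    """

    symbols: str
    trial_boundaries: tuple[int, ...] = ()
    label: str | None = None
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        extra = set(self.symbols) - set(self.alphabet)
        if extra:
            raise AlphabetError(
                f"symbols {sorted(extra)} not in alphabet {self.alphabet!r}"
            )
        if len(set(self.alphabet)) != len(self.alphabet):
            raise AlphabetError("alphabet contains duplicate symbols")
        bounds = tuple(self.trial_boundaries)
        if any(b < 0 or b > len(self.symbols) for b in bounds):
            raise ValueError("trial boundaries must lie in [0, length]")
        if list(bounds) != sorted(bounds):
            raise ValueError("trial boundaries must be sorted")
        object.__setattr__(self, "trial_boundaries", bounds)

    @property
    def k(self) -> int:
        """Alphabet size."""
        return len(self.alphabet)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def numeric(self) -> np.ndarray:
        """Integer representation (l→1, r→2, u→3, d→4 for the default alphabet)."""
        mapping = (
            NUMERIC_MAP
            if self.alphabet == ALPHABET
            else {c: i + 1 for i, c in enumerate(self.alphabet)}
        )
        return np.array([mapping[c] for c in self.symbols], dtype=np.int64)

    def relabel(self, permutation: dict[str, str]) -> "SymbolSequence":
        """Apply a permutation of the symbol labels (alphabet order kept)."""
        if sorted(permutation) != sorted(self.alphabet) or sorted(
            permutation.values()
        ) != sorted(self.alphabet):
            raise AlphabetError("permutation must be a bijection of the alphabet")
        return replace(
            self, symbols="".join(permutation[c] for c in self.symbols)
        )

    def with_label(self, label: str) -> "SymbolSequence":
        return replace(self, label=label)


def concat_trials(seqs: list[SymbolSequence]) -> SymbolSequence:
    """Merge per-trial sequences into one long sequence.

    Trials recorded separately for one condition are concatenated with no
    separator symbol; the junction indices are kept as trial boundaries so
    downstream consumers may optionally reset model state there.

    Raises
    ------
    AlphabetError
        If the inputs do not share a single alphabet.
    """
    if not seqs:
        return SymbolSequence("")
    alphabet = seqs[0].alphabet
    if any(s.alphabet != alphabet for s in seqs):
        raise AlphabetError("cannot concatenate sequences over different alphabets")
    parts: list[str] = []
    boundaries: list[int] = []
    offset = 0
    for i, s in enumerate(seqs):
        boundaries.extend(offset + b for b in s.trial_boundaries if 0 < b < len(s))
        if i > 0:
            boundaries.append(offset)
        parts.append(s.symbols)
        offset += len(s)
    labels = {s.label for s in seqs if s.label is not None}
    label = labels.pop() if len(labels) == 1 else None
    return SymbolSequence(
        "".join(parts),
        trial_boundaries=tuple(sorted(set(boundaries))),
        label=label,
        alphabet=alphabet,
    )


def write_sequences(path, seqs: list[SymbolSequence]) -> None:
    """Write sequences to a plain-text file, one per line.

    ``#``-prefixed metadata lines (label, trial boundaries) precede each
    sequence line.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for s in seqs:
            if s.label is not None:
                fh.write(f"# label={s.label}\n")
            if s.trial_boundaries:
                fh.write(
                    "# trial_boundaries="
                    + ",".join(str(b) for b in s.trial_boundaries)
                    + "\n"
                )
            fh.write(s.symbols + "\n")


def read_sequences(path) -> list[SymbolSequence]:
    """Read sequences written by :func:`write_sequences`."""
    seqs: list[SymbolSequence] = []
    label: str | None = None
    boundaries: tuple[int, ...] = ()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                meta = line[1:].strip()
                if meta.startswith("label="):
                    label = meta[len("label="):]
                elif meta.startswith("trial_boundaries="):
                    raw = meta[len("trial_boundaries="):]
                    boundaries = tuple(int(x) for x in raw.split(",") if x)
                continue
            seqs.append(
                SymbolSequence(line, trial_boundaries=boundaries, label=label)
            )
            label, boundaries = None, ()
    return seqs
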