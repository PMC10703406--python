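"""Fixed residue alphabet shared by every model component.

The model treats an aligned protein sequence as categorical data over 21
symbols: the 20 canonical amino acids plus the alignment gap ``-``, which
participates in probabilities, distances and statistics as an ordinary
symbol.  The symbol order is fixed (alphabetical one-letter codes, gap
last) so that every tensor in the package indexes residues identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical symbol order: 20 amino acids alphabetically, gap last.
PROTEIN_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY-"

#: Non-canonical residue codes silently collapsed onto the gap symbol.
AMBIGUOUS_RESIDUES = frozenset("BZXJUO.")


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet with encode/decode maps.

    Parameters
    ----------
    symbols:
        Ordered string of distinct symbols; the default is the 21-letter
        protein alphabet with the gap character last.
    """

    symbols: str = PROTEIN_SYMBOLS
    index_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")
        object.__setattr__(
            self, "index_of", {s: i for i, s in enumerate(self.symbols)}
        )

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def gap_index(self) -> int:
        return self.index_of["-"]

    def encode(self, sequence: str) -> np.ndarray:
        """Encode a residue string to integer codes.

        Raises ``KeyError`` for symbols outside the alphabet; callers that
        want the gap-mapping policy for ambiguous residues should go
        through :func:`generalist.msa.read_fasta`.
        """
        return np.array([self.index_of[s] for s in sequence], dtype=np.int8)

    def decode(self, codes: np.ndarray) -> str:
        """Decode integer codes back to a residue string."""
        return "".join(self.symbols[int(c)] for c in np.asarray(codes).ravel())


#: Module-level default instance; all public APIs use it unless told otherwise.
PROTEIN_ALPHABET = Alphabet()
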