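"""Aligned-FASTA input/output and integer/one-hot encodings of an MSA.

An :class:`EncodedMSA` is the package's canonical in-memory container: an
``N x L`` integer matrix over the 21-symbol alphabet plus the record ids.
All downstream modules (model fitting, distance statistics, ensemble
statistics) operate on this container, never on raw strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMBIGUOUS_RESIDUES, PROTEIN_ALPHABET, Alphabet

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Raised when records do not form a fixed-width alignment."""


@dataclass
class EncodedMSA:
    """Integer-coded multiple sequence alignment.

    Attributes
    ----------
    ids:
        Record identifiers in file order.
    codes:
        ``N x L`` integer matrix with entries in ``[0, alphabet.size)``.
    alphabet:
        The residue alphabet the codes index into.
    """

    ids: list[str]
    codes: np.ndarray
    alphabet: Alphabet = field(default_factory=lambda: PROTEIN_ALPHABET)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] < 1 or self.codes.shape[1] < 1:
            raise AlignmentError("codes must be a non-empty N x L matrix")
        if len(self.ids) != self.codes.shape[0]:
            raise AlignmentError("one id per sequence required")
        if self.codes.min() < 0 or self.codes.max() >= self.alphabet.size:
            raise AlignmentError("codes contain invalid alphabet indices")

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def sequence(self, n: int) -> str:
        return self.alphabet.decode(self.codes[n])

    def subset(self, rows: np.ndarray) -> "EncodedMSA":
        rows = np.asarray(rows)
        return EncodedMSA(
            ids=[self.ids[int(i)] for i in rows],
            codes=self.codes[rows],
            alphabet=self.alphabet,
        )


def read_fasta(path, alphabet: Alphabet = PROTEIN_ALPHABET) -> EncodedMSA:
    """Read an aligned FASTA file into an :class:`EncodedMSA`.

    All records must have identical length.  Lowercase residues are
    uppercased; ambiguous residue codes (B, Z, X, J, U, O and ``.``) are
    mapped to the gap symbol with a logged per-file count.  A2M-style
    insert columns are not treated specially — the input must already be
    a fixed-width alignment.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")

    length = len(records[0].seq)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    n_mapped = 0
    for rec in records:
        seq = str(rec.seq).upper()
        if len(seq) != length:
            raise AlignmentError(
                f"record {rec.id!r} has length {len(seq)}, expected {length}"
            )
        cleaned = []
        for s in seq:
            if s in AMBIGUOUS_RESIDUES:
                n_mapped += 1
                cleaned.append("-")
            elif s in alphabet.index_of:
                cleaned.append(s)
            else:
                raise AlignmentError(
                    f"record {rec.id!r} contains unsupported symbol {s!r}"
                )
        ids.append(rec.id)
        rows.append(alphabet.encode("".join(cleaned)))
    if n_mapped:
        logger.warning(
            "%s: mapped %d non-canonical residues to the gap symbol", path, n_mapped
        )
    return EncodedMSA(ids=ids, codes=np.vstack(rows), alphabet=alphabet)


def write_fasta(msa: EncodedMSA, path) -> None:
    """Write an :class:`EncodedMSA` as aligned FASTA (gap ``-``, 80-column wrap)."""
    records = []
    for n in range(msa.n_sequences):
        rec_id = msa.ids[n] or f"seq_{n}"
        records.append(
            SeqRecord(Seq(msa.sequence(n)), id=rec_id, description="")
        )
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(records, fh, "fasta")


def one_hot(msa: EncodedMSA) -> np.ndarray:
    """One-hot encode an alignment as an ``N x A x L`` indicator tensor.

    ``out[n, a, l] == 1`` iff sequence ``n`` carries symbol ``a`` at
    position ``l``; the symbol axis sums to one at every ``(n, l)``.
    """
    n, length = msa.codes.shape
    a = msa.alphabet.size
    out = np.zeros((n, a, length), dtype=np.float64)
    out[np.arange(n)[:, None], msa.codes, np.arange(length)[None, :]] = 1.0
    return out
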