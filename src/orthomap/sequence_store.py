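"""Gene-linked sequence storage in ranked categories.

The ortholog cascade consults sequences in a fixed preference order —
canonical protein first, then curated mRNA, curated ncRNA, and finally their
predicted counterparts.  This module provides a local-FASTA-backed store with
exactly that contract; it replaces live Uniprot/NCBI retrieval so that runs
are reproducible offline.  A remote backend implementing the same
``get_sequence`` contract can be swapped in, but nothing here requires one.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .errors import ParseError

_AA_CHARS = frozenset("ABCDEFGHIKLMNPQRSTUVWXYZ*")
_NT_CHARS = frozenset("ACGTUNRYSWKMBDHV")


class Alphabet(str, enum.Enum):
    AMINO_ACID = "amino_acid"
    NUCLEOTIDE = "nucleotide"


class SequenceCategory(str, enum.Enum):
    """Ranked sequence tiers, best-annotated first."""

    PROTEIN_CANONICAL = "protein_canonical"
    MRNA_CURATED = "mrna_curated"
    NCRNA_CURATED = "ncrna_curated"
    MRNA_PREDICTED = "mrna_predicted"
    NCRNA_PREDICTED = "ncrna_predicted"

    @property
    def alphabet(self) -> Alphabet:
        if self is SequenceCategory.PROTEIN_CANONICAL:
            return Alphabet.AMINO_ACID
        return Alphabet.NUCLEOTIDE


#: Full consultation order: protein first, then nucleotide tiers.
DEFAULT_CATEGORY_ORDER: tuple[SequenceCategory, ...] = tuple(SequenceCategory)

#: Nucleotide fall-through order used when no canonical protein exists.
NUCLEOTIDE_CATEGORY_ORDER: tuple[SequenceCategory, ...] = (
    SequenceCategory.MRNA_CURATED,
    SequenceCategory.NCRNA_CURATED,
    SequenceCategory.MRNA_PREDICTED,
    SequenceCategory.NCRNA_PREDICTED,
)


@dataclass(frozen=True)
class SequenceRecord:
    gene_id: str
    category: SequenceCategory
    sequence: str


def _gene_id_from_header(record) -> str:
    # a "gene=XYZ" tag anywhere in the description wins; otherwise the first
    # whitespace-delimited token (SeqIO's record.id)
    for token in record.description.split():
        if token.startswith("gene="):
            return token[5:]
    return record.id


@dataclass
class SequenceStore:
    """Sequences indexed by ``(gene_id, category)``; isoforms all retained."""

    _data: dict[tuple[str, SequenceCategory], list[str]] = field(default_factory=dict)

    def add(self, gene_id: str, category: SequenceCategory, sequence: str) -> None:
        seq = sequence.upper()
        valid = _AA_CHARS if category.alphabet is Alphabet.AMINO_ACID else _NT_CHARS
        bad = set(seq) - valid
        if bad:
            raise ParseError(
                f"invalid {category.alphabet.value} symbol(s) "
                f"{sorted(bad)} in sequence for gene {gene_id!r}"
            )
        bucket = self._data.setdefault((gene_id, category), [])
        if seq in bucket:
            warnings.warn(
                f"duplicate {category.value} record for gene {gene_id!r}; deduplicated",
                stacklevel=2,
            )
            return
        bucket.append(seq)

    def isoforms(self, gene_id: str, category: SequenceCategory) -> list[str]:
        return list(self._data.get((gene_id, category), []))

    def has(self, gene_id: str, category: SequenceCategory) -> bool:
        return bool(self._data.get((gene_id, category)))

    def __len__(self) -> int:
        return sum(len(v) for v in self._data.values())


def load_fasta(
    path: str | Path,
    category: SequenceCategory,
    store: SequenceStore | None = None,
) -> SequenceStore:
    """Load a FASTA file into *store* under *category* (new store if None).

    Headers must carry a gene id as the first whitespace-delimited field or a
    ``gene=`` tag.  Sequences are uppercased on ingestion; exact duplicate
    records for a gene are dropped with a warning.
    """
    store = store if store is not None else SequenceStore()
    for record in SeqIO.parse(str(path), "fasta"):
        store.add(_gene_id_from_header(record), category, str(record.seq))
    return store


def get_sequence(
    store: SequenceStore,
    gene_id: str,
    category_order: Sequence[SequenceCategory] = DEFAULT_CATEGORY_ORDER,
) -> SequenceRecord | None:
    """First-available sequence for *gene_id* along *category_order*.

    Within a category, the longest isoform is treated as canonical; length
    ties are broken by lexicographically smallest sequence.  Returns ``None``
    when no consulted category holds an entry — absence is a value here, not
    an error.
    """
    if not category_order:
        raise ValueError("category_order must be non-empty")
    for category in category_order:
        isoforms = store.isoforms(gene_id, category)
        if isoforms:
            best = min(isoforms, key=lambda s: (-len(s), s))
            return SequenceRecord(gene_id=gene_id, category=category, sequence=best)
    return None
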