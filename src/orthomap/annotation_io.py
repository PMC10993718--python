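"""Gene-annotation input: Ensembl-dialect GTF parsing and predicted-gene filtering.

A :class:`GeneUniverse` is the per-species catalogue of genes the ortholog
cascade operates on.  Only features of type ``gene`` are kept; transcript and
exon lines are ignored.  Gene symbols fall back to the stable gene id when the
annotation carries no ``gene_name``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ConfigurationError, IntegrityError, ParseError

#: Symbol patterns treated as predicted/poorly-annotated genes in mouse-style
#: nomenclature (Ensembl "Gm" models and Riken cDNA clones).  Human-style
#: universes conventionally use an empty list.
DEFAULT_PREDICTED_PATTERNS: tuple[str, ...] = (r"^Gm[0-9]+$", r"Rik$")

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class GeneRecord:
    """One gene of one species."""

    gene_id: str
    symbol: str
    biotype: str = "unknown"
    species: str = ""
    predicted: bool = False

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise IntegrityError("gene_id must be non-empty")
        if not self.symbol:
            object.__setattr__(self, "symbol", self.gene_id)


@dataclass
class GeneUniverse:
    """Ordered, id-unique collection of :class:`GeneRecord` for one species."""

    species: str
    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id: dict[str, GeneRecord] = {}
        self._symbol_index: dict[str, set[str]] = {}
        for rec in self.records:
            self._index(rec)

    def _index(self, rec: GeneRecord) -> None:
        if rec.gene_id in self._by_id:
            raise IntegrityError(
                f"duplicate gene_id {rec.gene_id!r} in universe {self.species!r}"
            )
        self._by_id[rec.gene_id] = rec
        self._symbol_index.setdefault(rec.symbol, set()).add(rec.gene_id)

    @property
    def symbol_index(self) -> Mapping[str, set[str]]:
        return self._symbol_index

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __iter__(self):
        return iter(self.records)

    def get(self, gene_id: str) -> GeneRecord | None:
        return self._by_id.get(gene_id)

    def lookup_symbol(self, symbol: str) -> set[str]:
        return set(self._symbol_index.get(symbol, set()))

    def lookup_symbol_casefold(self, symbol: str) -> set[str]:
        """Gene ids whose symbol equals *symbol* case-insensitively."""
        want = symbol.casefold()
        out: set[str] = set()
        for sym, ids in self._symbol_index.items():
            if sym.casefold() == want:
                out |= ids
        return out


def parse_gtf(path: str | Path, species: str) -> GeneUniverse:
    """Parse an Ensembl-dialect GTF into a :class:`GeneUniverse`.

    One record is produced per feature of type ``gene``; ``gene_name`` supplies
    the symbol (falling back to ``gene_id``) and ``gene_biotype`` (or the
    GENCODE synonym ``gene_type``) the biotype.  A gene is flagged predicted
    when its source column mentions prediction.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            if cols[2] != "gene":
                continue
            attrs = dict(_ATTR_RE.findall(cols[8]))
            gene_id = attrs.get("gene_id", "")
            if not gene_id:
                raise ParseError(f"{path.name}:{lineno}: missing gene_id attribute")
            symbol = attrs.get("gene_name") or gene_id
            biotype = attrs.get("gene_biotype") or attrs.get("gene_type") or "unknown"
            predicted = "predict" in cols[1].lower()
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    symbol=symbol,
                    biotype=biotype,
                    species=species,
                    predicted=predicted,
                )
            )
    return GeneUniverse(species=species, records=records)


def filter_predicted(
    universe: GeneUniverse, patterns: Iterable[str] = DEFAULT_PREDICTED_PATTERNS
) -> GeneUniverse:
    """Return a new universe without predicted genes.

    A record is dropped when its ``predicted`` flag is set or its symbol
    matches any of the given regular expressions (``re.search`` semantics).
    The input universe is left untouched.
    """
    compiled = []
    for pat in patterns:
        try:
            compiled.append(re.compile(pat))
        except re.error as exc:
            raise ConfigurationError(f"invalid predicted-gene pattern {pat!r}: {exc}")
    kept = [
        rec
        for rec in universe.records
        if not rec.predicted and not any(c.search(rec.symbol) for c in compiled)
    ]
    return GeneUniverse(species=universe.species, records=kept)


def write_universe_tsv(universe: GeneUniverse, path: str | Path) -> None:
    """Dump the universe as a TSV for inspection."""
    with open(path, "wt") as fh:
        fh.write("gene_id\tsymbol\tbiotype\tspecies\tpredicted\n")
        for rec in universe.records:
            fh.write(
                f"{rec.gene_id}\t{rec.symbol}\t{rec.biotype}\t{rec.species}\t"
                f"{int(rec.predicted)}\n"
            )
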