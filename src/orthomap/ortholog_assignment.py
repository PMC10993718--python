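"""Hierarchical 1-to-1 ortholog assignment.

Each source-species gene is resolved to at most one target-species gene by a
tiered cascade over a table of database candidates:

1. ``unique_db``       — exactly one candidate: taken as-is.
2. ``protein_align``   — several candidates: Needleman–Wunsch over canonical
   protein sequences (BLOSUM50); highest score wins.
3. ``nucleotide_align``— no usable protein: nucleotide alignment, falling
   through curated mRNA → curated ncRNA → predicted mRNA → predicted ncRNA
   (the same category on both sides).
4. ``levenshtein``     — no sequences at all: smallest symbol edit distance.
5. ``lowercase``       — no candidates: case-insensitive exact symbol match
   against the target universe (how e.g. mouse *Malat1* finds human *MALAT1*).

A greedy, score-ranked conflict-resolution pass then enforces a globally
bijective table: when several sources claim one target, the best-ranked
claimant keeps it and the displaced sources are re-resolved against their
remaining candidates until the table is stable.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .alignment_core import (
    SubstitutionMatrix,
    blosum50,
    global_align,
    iupac_nucleotide_matrix,
    levenshtein,
    normalized_similarity,
)
from .annotation_io import GeneRecord, GeneUniverse
from .errors import ConfigurationError, IntegrityError, ParseError
from .sequence_store import (
    NUCLEOTIDE_CATEGORY_ORDER,
    SequenceCategory,
    SequenceStore,
    get_sequence,
)

METHOD_UNIQUE = "unique_db"
METHOD_PROTEIN = "protein_align"
METHOD_NUCLEOTIDE = "nucleotide_align"
METHOD_LEVENSHTEIN = "levenshtein"
METHOD_LOWERCASE = "lowercase"
METHOD_UNASSIGNED = "unassigned"

METHODS = (
    METHOD_UNIQUE,
    METHOD_PROTEIN,
    METHOD_NUCLEOTIDE,
    METHOD_LEVENSHTEIN,
    METHOD_LOWERCASE,
    METHOD_UNASSIGNED,
)

#: Conflict-resolution precedence: unique database hits outrank every scored
#: tier, then tiers in cascade order.
_METHOD_RANK = {
    METHOD_UNIQUE: 0,
    METHOD_PROTEIN: 1,
    METHOD_NUCLEOTIDE: 2,
    METHOD_LEVENSHTEIN: 3,
    METHOD_LOWERCASE: 4,
}


@dataclass(frozen=True)
class CascadeConfig:
    """Tunable knobs of the assignment cascade."""

    gap_open: float = 10.0
    gap_extend: float = 4.0
    nt_match: float = 1.0
    nt_mismatch: float = -1.0
    normalize_scores: bool = False
    levenshtein_max: int | None = None
    #: restrict the lowercase tier to these biotypes (None = all biotypes)
    lowercase_biotypes: tuple[str, ...] | None = None
    nucleotide_order: tuple[SequenceCategory, ...] = NUCLEOTIDE_CATEGORY_ORDER

    def nucleotide_matrix(self) -> SubstitutionMatrix:
        return iupac_nucleotide_matrix(self.nt_match, self.nt_mismatch)


@dataclass(frozen=True)
class OrthologAssignment:
    source_id: str
    target_id: str | None
    method: str
    score: float | None = None
    n_candidates: int = 0
    source_symbol: str = ""
    target_symbol: str = ""

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise IntegrityError(f"unknown assignment method {self.method!r}")
        if (self.method == METHOD_UNASSIGNED) != (self.target_id is None):
            raise IntegrityError(
                "method is 'unassigned' exactly when target_id is absent"
            )
        if self.method == METHOD_UNIQUE and self.n_candidates != 1:
            raise IntegrityError("unique_db implies exactly one candidate")

    @property
    def assigned(self) -> bool:
        return self.target_id is not None


@dataclass
class CandidateSource:
    """Source gene id → ordered candidate target gene ids (possibly empty)."""

    mapping: dict[str, list[str]] = field(default_factory=dict)

    def candidates_for(self, source_id: str) -> list[str]:
        return list(self.mapping.get(source_id, []))

    def validate(
        self, source_universe: GeneUniverse, target_universe: GeneUniverse
    ) -> None:
        for src, targets in self.mapping.items():
            if src not in source_universe:
                raise IntegrityError(
                    f"candidate table references unknown source gene {src!r}"
                )
            for tgt in targets:
                if tgt not in target_universe:
                    raise IntegrityError(
                        f"candidate table references unknown target gene {tgt!r}"
                    )


def read_candidates(path: str | Path) -> CandidateSource:
    """Read a two-column (source_id, target_id) TSV; header row optional."""
    mapping: dict[str, list[str]] = defaultdict(list)
    path = Path(path)
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 2 columns, got {len(cols)}"
                )
            if lineno == 1 and cols == ["source_id", "target_id"]:
                continue
            src, tgt = cols
            if tgt and tgt not in mapping[src]:
                mapping[src].append(tgt)
            else:
                mapping.setdefault(src, mapping[src])
    return CandidateSource(mapping=dict(mapping))


@dataclass
class OrthologTable:
    """Bijective source→target gene map with per-pair provenance."""

    species_pair: tuple[str, str]
    pairs: list[OrthologAssignment]
    unassigned: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen_src: set[str] = set()
        seen_tgt: set[str] = set()
        for pair in self.pairs:
            if not pair.assigned:
                raise IntegrityError("unassigned record placed among pairs")
            if pair.source_id in seen_src:
                raise IntegrityError(f"duplicate source_id {pair.source_id!r}")
            if pair.target_id in seen_tgt:
                raise IntegrityError(f"duplicate target_id {pair.target_id!r}")
            seen_src.add(pair.source_id)
            seen_tgt.add(pair.target_id)

    @property
    def method_counts(self) -> dict[str, int]:
        counts = Counter(p.method for p in self.pairs)
        out = {m: counts.get(m, 0) for m in METHODS[:-1]}
        out[METHOD_UNASSIGNED] = len(self.unassigned)
        return out

    def as_mapping(self) -> dict[str, str]:
        return {p.source_id: p.target_id for p in self.pairs}

    def summary(self) -> dict:
        return {
            "species_pair": list(self.species_pair),
            "n_pairs": len(self.pairs),
            "n_unassigned": len(self.unassigned),
            "method_counts": self.method_counts,
        }


# ---------------------------------------------------------------------------
# per-gene resolution


def _tie_key(source: GeneRecord, cand: GeneRecord) -> tuple[int, str]:
    return (levenshtein(source.symbol, cand.symbol), cand.gene_id)


def _score_candidates(
    source: GeneRecord,
    candidates: Sequence[GeneRecord],
    src_seq: str,
    tgt_seqs: Mapping[str, str],
    matrix: SubstitutionMatrix,
    cfg: CascadeConfig,
) -> tuple[GeneRecord, float]:
    best: tuple[float, tuple[int, str], GeneRecord] | None = None
    for cand in candidates:
        seq = tgt_seqs.get(cand.gene_id)
        if seq is None:
            continue
        result = global_align(src_seq, seq, matrix, cfg.gap_open, cfg.gap_extend)
        score = (
            normalized_similarity(result) if cfg.normalize_scores else result.score
        )
        key = _tie_key(source, cand)
        if best is None or score > best[0] or (score == best[0] and key < best[1]):
            best = (score, key, cand)
    assert best is not None
    return best[2], best[0]


def resolve_gene(
    source: GeneRecord,
    candidates: Sequence[GeneRecord],
    source_store: SequenceStore,
    target_store: SequenceStore,
    target_universe: GeneUniverse,
    cfg: CascadeConfig = CascadeConfig(),
    *,
    n_candidates: int | None = None,
    allow_lowercase: bool = True,
) -> OrthologAssignment:
    """Resolve one source gene through the tiered cascade.

    ``n_candidates`` records the original candidate count when re-resolving a
    displaced gene against a reduced candidate list.
    """
    n_orig = len(candidates) if n_candidates is None else n_candidates

    def _make(cand: GeneRecord, method: str, score: float | None) -> OrthologAssignment:
        return OrthologAssignment(
            source_id=source.gene_id,
            target_id=cand.gene_id,
            method=method,
            score=score,
            n_candidates=n_orig,
            source_symbol=source.symbol,
            target_symbol=cand.symbol,
        )

    unassigned = OrthologAssignment(
        source_id=source.gene_id,
        target_id=None,
        method=METHOD_UNASSIGNED,
        n_candidates=n_orig,
        source_symbol=source.symbol,
    )

    if not candidates:
        if not allow_lowercase:
            return unassigned
        hits = target_universe.lookup_symbol_casefold(source.symbol)
        if cfg.lowercase_biotypes is not None:
            hits = {
                gid
                for gid in hits
                if target_universe.get(gid).biotype in cfg.lowercase_biotypes
            }
        if not hits:
            return unassigned
        cand = min(
            (target_universe.get(gid) for gid in hits),
            key=lambda c: _tie_key(source, c),
        )
        return _make(cand, METHOD_LOWERCASE, None)

    if n_orig == 1 and len(candidates) == 1:
        return _make(candidates[0], METHOD_UNIQUE, None)

    # scored tiers -----------------------------------------------------
    protein_cat = SequenceCategory.PROTEIN_CANONICAL
    src_prot = get_sequence(source_store, source.gene_id, [protein_cat])
    if src_prot is not None:
        tgt_prots = {
            c.gene_id: rec.sequence
            for c in candidates
            if (rec := get_sequence(target_store, c.gene_id, [protein_cat]))
            is not None
        }
        if tgt_prots:
            cand, score = _score_candidates(
                source, candidates, src_prot.sequence, tgt_prots, blosum50(), cfg
            )
            return _make(cand, METHOD_PROTEIN, score)

    nt_matrix = cfg.nucleotide_matrix()
    for category in cfg.nucleotide_order:
        src_nt = get_sequence(source_store, source.gene_id, [category])
        if src_nt is None:
            continue
        tgt_nts = {
            c.gene_id: rec.sequence
            for c in candidates
            if (rec := get_sequence(target_store, c.gene_id, [category])) is not None
        }
        if not tgt_nts:
            continue
        cand, score = _score_candidates(
            source, candidates, src_nt.sequence, tgt_nts, nt_matrix, cfg
        )
        return _make(cand, METHOD_NUCLEOTIDE, score)

    # symbol edit distance --------------------------------------------
    best = min(
        candidates,
        key=lambda c: (levenshtein(source.symbol, c.symbol), c.gene_id),
    )
    dist = levenshtein(source.symbol, best.symbol)
    if cfg.levenshtein_max is not None and dist > cfg.levenshtein_max:
        return unassigned
    return _make(best, METHOD_LEVENSHTEIN, float(dist))


# ---------------------------------------------------------------------------
# global bijectivity


def _claim_rank(a: OrthologAssignment) -> tuple[int, float, str]:
    """Sort key under which the *smallest* claimant keeps a contested target."""
    rank = _METHOD_RANK[a.method]
    if a.method in (METHOD_PROTEIN, METHOD_NUCLEOTIDE):
        score_key = -(a.score if a.score is not None else float("-inf"))
    elif a.method == METHOD_LEVENSHTEIN:
        score_key = a.score if a.score is not None else float("inf")
    else:
        score_key = 0.0
    return (rank, score_key, a.source_id)


Resolver = Callable[[str, set[str]], OrthologAssignment]


def enforce_uniqueness(
    assignments: Iterable[OrthologAssignment],
    species_pair: tuple[str, str] = ("", ""),
    resolver: Resolver | None = None,
) -> OrthologTable:
    """Greedy score-ranked conflict resolution to a strict 1-to-1 table.

    When several sources claim one target the best claimant (unique database
    hit first, then tier precedence, then score, then lexicographic
    source id) keeps it; each displaced source is re-resolved via *resolver*
    (excluding every target it has lost) and the pass repeats until stable.
    Without a resolver displaced sources become unassigned.  Termination is
    guaranteed because a source's exclusion set strictly grows on every
    displacement.
    """
    current: dict[str, OrthologAssignment] = {}
    for a in assignments:
        if a.source_id in current:
            raise IntegrityError(f"duplicate assignment for source {a.source_id!r}")
        current[a.source_id] = a
    exclusions: dict[str, set[str]] = defaultdict(set)

    changed = True
    while changed:
        changed = False
        by_target: dict[str, list[OrthologAssignment]] = defaultdict(list)
        for a in current.values():
            if a.assigned:
                by_target[a.target_id].append(a)
        for target in sorted(by_target):
            group = by_target[target]
            if len(group) < 2:
                continue
            group.sort(key=_claim_rank)
            for loser in group[1:]:
                exclusions[loser.source_id].add(target)
                if resolver is not None:
                    current[loser.source_id] = resolver(
                        loser.source_id, set(exclusions[loser.source_id])
                    )
                else:
                    current[loser.source_id] = replace(
                        loser, target_id=None, method=METHOD_UNASSIGNED, score=None,
                        target_symbol="",
                    )
                changed = True
            break  # re-group after each mutation for determinism

    pairs = [a for _, a in sorted(current.items()) if a.assigned]
    unassigned = sorted(s for s, a in current.items() if not a.assigned)
    return OrthologTable(species_pair=species_pair, pairs=pairs, unassigned=unassigned)


def build_table(
    source_universe: GeneUniverse,
    target_universe: GeneUniverse,
    candidates: CandidateSource,
    source_store: SequenceStore,
    target_store: SequenceStore,
    cfg: CascadeConfig = CascadeConfig(),
) -> OrthologTable:
    """Run the cascade over every source gene and enforce bijectivity."""
    if source_universe.species == target_universe.species:
        raise ConfigurationError(
            f"source and target universes share the species tag "
            f"{source_universe.species!r}"
        )
    candidates.validate(source_universe, target_universe)

    initial: list[OrthologAssignment] = []
    orig_candidates: dict[str, list[str]] = {}
    for source in sorted(source_universe.records, key=lambda r: r.gene_id):
        cand_ids = candidates.candidates_for(source.gene_id)
        orig_candidates[source.gene_id] = cand_ids
        cand_records = [target_universe.get(cid) for cid in cand_ids]
        initial.append(
            resolve_gene(
                source, cand_records, source_store, target_store,
                target_universe, cfg,
            )
        )

    def resolver(source_id: str, excluded: set[str]) -> OrthologAssignment:
        source = source_universe.get(source_id)
        cand_ids = [c for c in orig_candidates[source_id] if c not in excluded]
        cand_records = [target_universe.get(cid) for cid in cand_ids]
        if not orig_candidates[source_id]:
            # lowercase-tier gene: retry the symbol search minus lost targets
            a = resolve_gene(
                source, [], source_store, target_store, target_universe, cfg,
                n_candidates=0,
            )
            if a.assigned and a.target_id in excluded:
                hits = target_universe.lookup_symbol_casefold(source.symbol)
                hits -= excluded
                if not hits:
                    return replace(
                        a, target_id=None, method=METHOD_UNASSIGNED,
                        target_symbol="",
                    )
                cand = min(
                    (target_universe.get(g) for g in hits),
                    key=lambda c: _tie_key(source, c),
                )
                return replace(
                    a, target_id=cand.gene_id, target_symbol=cand.symbol
                )
            return a
        if not cand_records:
            return OrthologAssignment(
                source_id=source_id,
                target_id=None,
                method=METHOD_UNASSIGNED,
                n_candidates=len(orig_candidates[source_id]),
                source_symbol=source.symbol,
            )
        return resolve_gene(
            source, cand_records, source_store, target_store, target_universe,
            cfg, n_candidates=len(orig_candidates[source_id]),
            allow_lowercase=False,
        )

    return enforce_uniqueness(
        initial,
        species_pair=(source_universe.species, target_universe.species),
        resolver=resolver,
    )


# ---------------------------------------------------------------------------
# table I/O

_COLUMNS = (
    "source_id",
    "source_symbol",
    "target_id",
    "target_symbol",
    "method",
    "score",
    "n_candidates",
)


def write_table(table: OrthologTable, path: str | Path) -> None:
    """Write the table (assigned pairs then unassigned sources) as TSV."""
    with open(path, "wt") as fh:
        fh.write(
            f"# source_species={table.species_pair[0]}\t"
            f"target_species={table.species_pair[1]}\n"
        )
        fh.write("\t".join(_COLUMNS) + "\n")
        for p in table.pairs:
            score = "" if p.score is None else repr(p.score)
            fh.write(
                f"{p.source_id}\t{p.source_symbol}\t{p.target_id}\t"
                f"{p.target_symbol}\t{p.method}\t{score}\t{p.n_candidates}\n"
            )
        for src in table.unassigned:
            fh.write(f"{src}\t\t\t\t{METHOD_UNASSIGNED}\t\t0\n")


def read_table(path: str | Path) -> OrthologTable:
    """Read a TSV written by :func:`write_table`; validates bijectivity."""
    path = Path(path)
    species_pair = ("", "")
    pairs: list[OrthologAssignment] = []
    unassigned: list[str] = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                fields = dict(
                    kv.split("=", 1) for kv in line[1:].strip().split("\t") if "=" in kv
                )
                species_pair = (
                    fields.get("source_species", ""),
                    fields.get("target_species", ""),
                )
                continue
            cols = line.split("\t")
            if cols == list(_COLUMNS):
                continue
            if len(cols) != len(_COLUMNS):
                raise ParseError(
                    f"{path.name}:{lineno}: expected {len(_COLUMNS)} columns, "
                    f"got {len(cols)}"
                )
            src, src_sym, tgt, tgt_sym, method, score, n_cand = cols
            if method == METHOD_UNASSIGNED:
                unassigned.append(src)
                continue
            pairs.append(
                OrthologAssignment(
                    source_id=src,
                    target_id=tgt,
                    method=method,
                    score=None if score == "" else float(score),
                    n_candidates=int(n_cand),
                    source_symbol=src_sym,
                    target_symbol=tgt_sym,
                )
            )
    return OrthologTable(
        species_pair=species_pair, pairs=pairs, unassigned=sorted(unassigned)
    )


def write_summary(table: OrthologTable, path: str | Path) -> None:
    with open(path, "wt") as fh:
        json.dump(table.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
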