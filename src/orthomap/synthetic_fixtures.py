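"""Two-species synthetic test worlds.

The generator emits everything the pipeline consumes — GTF annotations,
category-ranked FASTA sequence files, an ortholog-candidate table with
planted ambiguity, and negative-binomial count matrices with shared
cell-type programs — together with the ground truth needed to score
recovery.  The construction guarantees that the truth map is decodable:

* species A carries uppercase symbols, species B the title-case variant of
  the same root (mitochondrial genes follow the ``MT-``/``mt-`` convention);
* each true ortholog pair descends from a random ancestor mutated at
  ``seq_divergence`` while decoy candidates are mutated at the strictly
  larger ``decoy_divergence``, so sequence alignment separates them;
* scheduled subsets of the ambiguous genes have their protein (or all)
  sequences withheld, forcing resolution through the nucleotide and
  Levenshtein tiers; genes without any candidate are resolvable only by
  case-insensitive symbol matching.

Counts are Gamma–Poisson (negative binomial) draws around per-cell-type
programs shared across species, modulated by per-species per-gene offsets
and a continuous cell-cycle covariate; a configurable number of cells is
planted to violate exactly one QC gate each.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError
from .expression_harmonization import CellMatrix, QCThresholds, write_matrix_dir
from .ortholog_assignment import (
    METHOD_LEVENSHTEIN,
    METHOD_LOWERCASE,
    METHOD_NUCLEOTIDE,
    METHOD_PROTEIN,
    METHOD_UNIQUE,
    OrthologTable,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions of the synthetic two-species world."""

    n_genes: int = 200
    n_ambiguous: int = 40
    n_no_candidate: int = 10
    #: of the ambiguous genes, how many are forced down to the nucleotide /
    #: Levenshtein tiers by withholding sequences
    n_force_nucleotide: int = 8
    n_force_levenshtein: int = 8
    n_decoys: int = 2
    n_mito_genes: int = 5
    n_predicted_b: int = 5
    protein_len: int = 120
    mrna_len: int = 240
    seq_divergence: float = 0.05
    decoy_divergence: float = 0.5
    n_cell_types: int = 3
    cells_per_type_per_species: int = 100
    nb_mean: float = 3.0
    nb_dispersion: float = 2.0
    species_offset_sd: float = 0.3
    n_markers_per_type: int = 12
    marker_fold: float = 6.0
    cc_frac: float = 0.1
    cc_effect: float = 1.0
    planted_qc_violations: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.seq_divergence < 1.0:
            raise ConfigurationError("seq_divergence must be in [0, 1)")
        if not self.decoy_divergence > self.seq_divergence:
            raise ConfigurationError(
                "decoy_divergence must exceed seq_divergence so that the "
                "truth map is decodable from sequences"
            )
        if self.n_ambiguous + self.n_no_candidate > self.n_genes:
            raise ConfigurationError(
                "n_ambiguous + n_no_candidate must not exceed n_genes"
            )
        if self.n_force_nucleotide + self.n_force_levenshtein > self.n_ambiguous:
            raise ConfigurationError(
                "tier quotas (nucleotide + levenshtein) exceed n_ambiguous"
            )
        if self.n_mito_genes > self.n_plain:
            raise ConfigurationError("n_mito_genes exceeds the unambiguous genes")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ConfigurationError("nb_mean and nb_dispersion must be positive")

    @property
    def n_plain(self) -> int:
        return self.n_genes - self.n_ambiguous - self.n_no_candidate

    @classmethod
    def from_tier_quotas(
        cls,
        unique_db: int,
        protein_align: int,
        nucleotide_align: int,
        levenshtein: int,
        lowercase: int,
        **kwargs,
    ) -> "FixtureConfig":
        """Config whose intended per-tier gene counts equal the quotas."""
        return cls(
            n_genes=unique_db + protein_align + nucleotide_align + levenshtein + lowercase,
            n_ambiguous=protein_align + nucleotide_align + levenshtein,
            n_no_candidate=lowercase,
            n_force_nucleotide=nucleotide_align,
            n_force_levenshtein=levenshtein,
            n_mito_genes=min(5, unique_db),
            **kwargs,
        )


@dataclass(frozen=True)
class TruthPair:
    target_id: str
    tier: str


@dataclass
class FixtureBundle:
    """File paths plus in-memory conveniences for one simulated world."""

    config: FixtureConfig
    gtf_a: Path
    gtf_b: Path
    fastas: dict[tuple[str, str], Path]  # (species, category) -> path
    candidates_path: Path
    truth_path: Path
    matrix_dir_a: Path
    matrix_dir_b: Path
    truth: dict[str, TruthPair]
    qc_thresholds: QCThresholds
    matrix_a: CellMatrix
    matrix_b: CellMatrix
    planted_violations: dict[str, list[str]]
    species: tuple[str, str] = ("human_like", "mouse_like")


# ---------------------------------------------------------------------------
# helpers


def _random_root(rng: np.random.Generator, i: int) -> str:
    letters = "".join(rng.choice(list(string.ascii_uppercase), size=4))
    return f"{letters}{i}"


def _random_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(rng.choice(list(alphabet), size=length))

def _mutate(rng: np.random.Generator, seq: str, rate: float, alphabet: str) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = [c for c in alphabet if c != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _lev(a: str, b: str) -> int:
    from .alignment_core import levenshtein

    return levenshtein(a, b)


@dataclass
class _Gene:
    idx: int
    tier: str
    a_id: str
    b_id: str
    a_symbol: str
    b_symbol: str
    biotype: str
    decoys: list[tuple[str, str]] = field(default_factory=list)  # (id, symbol)


# ---------------------------------------------------------------------------
# generator


def simulate_fixture(cfg: FixtureConfig, out_dir: str | Path) -> FixtureBundle:
    """Generate a complete, fully seeded two-species fixture under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    sp_a, sp_b = "human_like", "mouse_like"

    genes = _design_genes(cfg, rng)
    seqs = _assign_sequences(cfg, rng, genes)
    gtf_a, gtf_b = _write_gtfs(out, genes, cfg, rng)
    fastas = _write_fastas(out, seqs)
    candidates_path = _write_candidates(out, genes, rng)

    truth = {
        g.a_id: TruthPair(target_id=g.b_id, tier=g.tier) for g in genes
    }
    truth_path = out / "truth.tsv"
    with open(truth_path, "wt") as fh:
        fh.write("source_id\ttarget_id\ttier\n")
        for g in genes:
            fh.write(f"{g.a_id}\t{g.b_id}\t{g.tier}\n")

    matrix_a, matrix_b, thresholds, planted = _simulate_expression(cfg, rng, genes)
    matrix_dir_a = out / "matrix_a"
    matrix_dir_b = out / "matrix_b"
    write_matrix_dir(matrix_a, matrix_dir_a)
    write_matrix_dir(matrix_b, matrix_dir_b)

    with open(out / "fixture.json", "wt") as fh:
        json.dump(
            {
                "seed": cfg.seed,
                "n_genes": cfg.n_genes,
                "species": [sp_a, sp_b],
                "qc_thresholds": {
                    "min_genes": thresholds.min_genes,
                    "max_genes": thresholds.max_genes,
                    "min_counts": thresholds.min_counts,
                    "max_counts": thresholds.max_counts,
                    "max_mito_pct": thresholds.max_mito_pct,
                },
                "planted_violations": planted,
                "intended_tiers": {
                    t: sum(1 for g in genes if g.tier == t)
                    for t in (
                        METHOD_UNIQUE,
                        METHOD_PROTEIN,
                        METHOD_NUCLEOTIDE,
                        METHOD_LEVENSHTEIN,
                        METHOD_LOWERCASE,
                    )
                },
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")

    return FixtureBundle(
        config=cfg,
        gtf_a=gtf_a,
        gtf_b=gtf_b,
        fastas=fastas,
        candidates_path=candidates_path,
        truth_path=truth_path,
        matrix_dir_a=matrix_dir_a,
        matrix_dir_b=matrix_dir_b,
        truth=truth,
        qc_thresholds=thresholds,
        matrix_a=matrix_a,
        matrix_b=matrix_b,
        planted_violations=planted,
        species=(sp_a, sp_b),
    )


def _design_genes(cfg: FixtureConfig, rng: np.random.Generator) -> list[_Gene]:
    n_prot_amb = cfg.n_ambiguous - cfg.n_force_nucleotide - cfg.n_force_levenshtein
    tiers = (
        [METHOD_UNIQUE] * cfg.n_plain
        + [METHOD_PROTEIN] * n_prot_amb
        + [METHOD_NUCLEOTIDE] * cfg.n_force_nucleotide
        + [METHOD_LEVENSHTEIN] * cfg.n_force_levenshtein
        + [METHOD_LOWERCASE] * cfg.n_no_candidate
    )
    genes: list[_Gene] = []
    used_roots: set[str] = set()
    for i, tier in enumerate(tiers):
        root = _random_root(rng, i)
        while root in used_roots:  # pragma: no cover - 4-letter clash is rare
            root = _random_root(rng, i)
        used_roots.add(root)
        if tier == METHOD_UNIQUE and i < cfg.n_mito_genes:
            a_sym = f"MT-{root}"
            b_sym = f"mt-{root.title()}"
            biotype = "protein_coding"
        else:
            a_sym = root
            b_sym = root.title()
            biotype = "lncRNA" if tier == METHOD_LOWERCASE else "protein_coding"
        gene = _Gene(
            idx=i,
            tier=tier,
            a_id=f"GA{i:05d}",
            b_id=f"GB{i:05d}",
            a_symbol=a_sym,
            b_symbol=b_sym,
            biotype=biotype,
        )
        if tier in (METHOD_PROTEIN, METHOD_NUCLEOTIDE, METHOD_LEVENSHTEIN):
            for j in range(cfg.n_decoys):
                d_root = _random_root(rng, 1000 + i * 10 + j)
                d_sym = d_root.title()
                if tier == METHOD_LEVENSHTEIN:
                    # the symbol distance must exceed the true pair's
                    while _lev(a_sym, d_sym) <= _lev(a_sym, b_sym):
                        d_root = _random_root(rng, 1000 + i * 10 + j)
                        d_sym = d_root.title()
                gene.decoys.append((f"GBD{i:05d}_{j}", d_sym))
        genes.append(gene)
    return genes


def _assign_sequences(
    cfg: FixtureConfig, rng: np.random.Generator, genes: list[_Gene]
) -> dict[tuple[str, str], list[tuple[str, str]]]:
    """(species, category) -> list of (gene_id, sequence)."""
    out: dict[tuple[str, str], list[tuple[str, str]]] = {}

    def put(species: str, category: str, gene_id: str, seq: str) -> None:
        out.setdefault((species, category), []).append((gene_id, seq))

    first_nt_forced = True
    for g in genes:
        anc_prot = _random_seq(rng, _AA, cfg.protein_len)
        anc_nt = _random_seq(rng, _NT, cfg.mrna_len)
        a_prot = anc_prot
        b_prot = _mutate(rng, anc_prot, cfg.seq_divergence, _AA)
        a_nt = anc_nt
        b_nt = _mutate(rng, anc_nt, cfg.seq_divergence, _NT)
        decoy_prots = [
            _mutate(rng, anc_prot, cfg.decoy_divergence, _AA) for _ in g.decoys
        ]
        decoy_nts = [
            _mutate(rng, anc_nt, cfg.decoy_divergence, _NT) for _ in g.decoys
        ]

        if g.tier == METHOD_LEVENSHTEIN:
            continue  # no sequences at all on the source side
        if g.tier == METHOD_LOWERCASE:
            put("a", "ncrna_curated", g.a_id, a_nt)
            put("b", "ncrna_curated", g.b_id, b_nt)
            continue
        if g.tier == METHOD_NUCLEOTIDE:
            # protein withheld; the first such gene also lacks curated mRNA so
            # resolution falls through to the predicted-mRNA category
            if first_nt_forced:
                put("a", "mrna_predicted", g.a_id, a_nt)
                put("b", "mrna_predicted", g.b_id, b_nt)
                for (d_id, _), d_nt in zip(g.decoys, decoy_nts):
                    put("b", "mrna_predicted", d_id, d_nt)
                first_nt_forced = False
            else:
                put("a", "mrna_curated", g.a_id, a_nt)
                put("b", "mrna_curated", g.b_id, b_nt)
                for (d_id, _), d_nt in zip(g.decoys, decoy_nts):
                    put("b", "mrna_curated", d_id, d_nt)
            continue
        # unique_db and protein-tier genes carry full sequence sets
        put("a", "protein_canonical", g.a_id, a_prot)
        put("b", "protein_canonical", g.b_id, b_prot)
        put("a", "mrna_curated", g.a_id, a_nt)
        put("b", "mrna_curated", g.b_id, b_nt)
        for (d_id, _), d_prot, d_nt in zip(g.decoys, decoy_prots, decoy_nts):
            put("b", "protein_canonical", d_id, d_prot)
            put("b", "mrna_curated", d_id, d_nt)
    # a second, shorter protein isoform for the first gene exercises the
    # longest-isoform canonical rule
    if genes and genes[0].tier == METHOD_UNIQUE:
        full = out[("a", "protein_canonical")][0][1]
        put("a", "protein_canonical", genes[0].a_id, full[: len(full) // 2])
    return out


def _write_gtfs(
    out: Path, genes: list[_Gene], cfg: FixtureConfig, rng: np.random.Generator
) -> tuple[Path, Path]:
    def gene_line(
        gene_id: str, symbol: str, biotype: str, start: int, source: str = "simulated"
    ) -> str:
        attrs = (
            f'gene_id "{gene_id}"; gene_name "{symbol}"; '
            f'gene_biotype "{biotype}";'
        )
        return (
            f"chr1\t{source}\tgene\t{start}\t{start + 999}\t.\t+\t.\t{attrs}\n"
        )

    def exon_line(gene_id: str, start: int) -> str:
        return (
            f"chr1\tsimulated\texon\t{start}\t{start + 99}\t.\t+\t.\t"
            f'gene_id "{gene_id}";\n'
        )

    gtf_a = out / "annotation_a.gtf"
    with open(gtf_a, "wt") as fh:
        fh.write("#!genome-build synthetic-A\n")
        for i, g in enumerate(genes):
            start = 1000 + 2000 * i
            fh.write(gene_line(g.a_id, g.a_symbol, g.biotype, start))
            fh.write(exon_line(g.a_id, start))

    gtf_b = out / "annotation_b.gtf"
    with open(gtf_b, "wt") as fh:
        fh.write("#!genome-build synthetic-B\n")
        pos = 0
        for g in genes:
            start = 1000 + 2000 * pos
            fh.write(gene_line(g.b_id, g.b_symbol, g.biotype, start))
            pos += 1
            for d_id, d_sym in g.decoys:
                fh.write(gene_line(d_id, d_sym, "protein_coding", 1000 + 2000 * pos))
                pos += 1
        for j in range(cfg.n_predicted_b):
            sym = f"Gm{9000 + j}" if j % 2 == 0 else f"{1700000 + j}A{j:02d}Rik"
            fh.write(
                gene_line(
                    f"GBP{j:05d}", sym, "protein_coding", 1000 + 2000 * pos,
                    source="simulated_predicted",
                )
            )
            pos += 1
    return gtf_a, gtf_b


def _write_fastas(
    out: Path, seqs: dict[tuple[str, str], list[tuple[str, str]]]
) -> dict[tuple[str, str], Path]:
    paths: dict[tuple[str, str], Path] = {}
    for (species, category), records in sorted(seqs.items()):
        path = out / f"{category}_{species}.fasta"
        with open(path, "wt") as fh:
            for gene_id, seq in records:
                fh.write(f">{gene_id} gene={gene_id}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        paths[(species, category)] = path
    return paths


def _write_candidates(
    out: Path, genes: list[_Gene], rng: np.random.Generator
) -> Path:
    path = out / "candidates.tsv"
    with open(path, "wt") as fh:
        fh.write("source_id\ttarget_id\n")
        for g in genes:
            if g.tier == METHOD_LOWERCASE:
                continue
            entries = [g.b_id] + [d_id for d_id, _ in g.decoys]
            order = rng.permutation(len(entries))
            for i in order:
                fh.write(f"{g.a_id}\t{entries[i]}\n")
    return path


# ---------------------------------------------------------------------------
# expression simulation


def _simulate_expression(
    cfg: FixtureConfig, rng: np.random.Generator, genes: list[_Gene]
) -> tuple[CellMatrix, CellMatrix, QCThresholds, dict[str, list[str]]]:
    n = cfg.n_genes
    base = np.full(n, cfg.nb_mean)
    mito_idx = np.array(
        [g.idx for g in genes if g.a_symbol.startswith("MT-")], dtype=int
    )
    base[mito_idx] = 0.3  # keep baseline mitochondrial content far below the gate

    # disjoint marker blocks per cell type, then a cell-cycle-driven block
    avail = [i for i in range(n) if i not in set(mito_idx)]
    per_type = min(cfg.n_markers_per_type, len(avail) // (cfg.n_cell_types + 1))
    marker_sets = [
        np.array(avail[t * per_type : (t + 1) * per_type], dtype=int)
        for t in range(cfg.n_cell_types)
    ]
    cc_start = cfg.n_cell_types * per_type
    n_cc = min(int(round(cfg.cc_frac * n)), len(avail) - cc_start)
    cc_idx = np.array(avail[cc_start : cc_start + n_cc], dtype=int)

    species_factor = {
        s: np.exp(rng.normal(0.0, cfg.species_offset_sd, size=n)) for s in ("a", "b")
    }

    r = cfg.nb_dispersion
    expected_genes: list[float] = []
    expected_totals: list[float] = []

    def type_means(species: str, cell_type: int) -> np.ndarray:
        mu = base.copy()
        mu[marker_sets[cell_type]] *= cfg.marker_fold
        return mu * species_factor[species]

    for s in ("a", "b"):
        for t in range(cfg.n_cell_types):
            mu = type_means(s, t)
            p_zero = (r / (r + mu)) ** r
            expected_genes.append(float(np.sum(1.0 - p_zero)))
            expected_totals.append(float(mu.sum()))

    thresholds = QCThresholds(
        min_genes=max(2, int(0.5 * min(expected_genes))),
        max_genes=min(n - 1, int(np.ceil(1.3 * max(expected_genes)))),
        min_counts=max(10, int(0.3 * min(expected_totals))),
        max_counts=int(np.ceil(3.0 * max(expected_totals))),
        max_mito_pct=5.0,
    )

    def sample_species(species: str):
        cols: list[np.ndarray] = []
        cell_ids: list[str] = []
        meta_rows: list[dict] = []
        idx = 0
        for t in range(cfg.n_cell_types):
            mu_t = type_means(species, t)
            for _ in range(cfg.cells_per_type_per_species):
                cc = float(rng.random())
                mu = mu_t.copy()
                mu[cc_idx] *= 1.0 + cfg.cc_effect * cc
                lam = rng.gamma(shape=r, scale=mu / r)
                cols.append(rng.poisson(lam))
                cell_ids.append(f"{species}_c{idx:04d}")
                meta_rows.append(
                    {
                        "sample": f"{species}1",
                        "species": "human_like" if species == "a" else "mouse_like",
                        "condition": "na",
                        "cell_type": f"type{t}",
                        "cc_score": cc,
                    }
                )
                idx += 1
        return cols, cell_ids, meta_rows

    cols_a, ids_a, meta_a = sample_species("a")
    cols_b, ids_b, meta_b = sample_species("b")

    # species B matrix additionally carries decoy and predicted genes at very
    # low expression; they are dropped at harmonisation
    extra_b: list[str] = []
    for g in genes:
        extra_b.extend(sym for _, sym in g.decoys)
    for j in range(cfg.n_predicted_b):
        extra_b.append(f"Gm{9000 + j}" if j % 2 == 0 else f"{1700000 + j}A{j:02d}Rik")
    n_extra = len(extra_b)
    if n_extra:
        extra_counts = rng.poisson(0.05, size=(n_extra, len(cols_b)))
        cols_b = [
            np.concatenate([c, extra_counts[:, i]]) for i, c in enumerate(cols_b)
        ]

    planted: dict[str, list[str]] = {"a": [], "b": []}
    viol_kinds = ("low_genes", "high_genes", "low_counts", "high_counts", "high_mito")
    for v in range(cfg.planted_qc_violations):
        species = "a" if v % 2 == 0 else "b"
        kind = viol_kinds[v % len(viol_kinds)]
        size = n if species == "a" else n + n_extra
        col = _violation_column(kind, thresholds, size, n, mito_idx, cfg)
        cid = f"{species}_viol{v:02d}"
        if species == "a":
            cols_a.append(col)
            ids_a.append(cid)
            meta_a.append(
                {
                    "sample": "a1",
                    "species": "human_like",
                    "condition": "na",
                    "cell_type": "type0",
                    "cc_score": 0.0,
                }
            )
        else:
            cols_b.append(col)
            ids_b.append(cid)
            meta_b.append(
                {
                    "sample": "b1",
                    "species": "mouse_like",
                    "condition": "na",
                    "cell_type": "type0",
                    "cc_score": 0.0,
                }
            )
        planted[species].append(cid)

    a_symbols = [g.a_symbol for g in genes]
    b_symbols = [g.b_symbol for g in genes] + extra_b

    def build(cols, ids, meta_rows, symbols) -> CellMatrix:
        counts = sp.csr_matrix(np.column_stack(cols).astype(np.int64))
        meta = pd.DataFrame(meta_rows, index=pd.Index(ids, name="cell_id"))
        return CellMatrix(
            counts=counts, gene_ids=symbols, cell_ids=ids, cell_meta=meta
        )

    return (
        build(cols_a, ids_a, meta_a, a_symbols),
        build(cols_b, ids_b, meta_b, b_symbols),
        thresholds,
        planted,
    )


def _violation_column(
    kind: str,
    t: QCThresholds,
    size: int,
    n_true: int,
    mito_idx: np.ndarray,
    cfg: FixtureConfig,
) -> np.ndarray:
    """A count column violating exactly the named QC gate."""
    col = np.zeros(size, dtype=np.int64)
    non_mito = np.array(
        [i for i in range(n_true) if i not in set(mito_idx)], dtype=int
    )

    def spread(total: int, n_spread: int, pool: np.ndarray) -> None:
        n_spread = min(n_spread, len(pool), total)
        q, rem = divmod(total, n_spread)
        col[pool[:n_spread]] = q
        col[pool[:rem]] += 1

    if kind == "low_genes":
        n_low = max(1, (2 * t.min_genes) // 3)
        total = 2 * t.min_counts
        spread(total, n_low, non_mito)
    elif kind == "high_genes":
        c = max(3, int(round(cfg.nb_mean)))
        col[non_mito] = c
        col[mito_idx] = 1
        if size > n_true:
            col[n_true:] = 1  # decoy/predicted rows count as genes too
    elif kind == "low_counts":
        total = max(1, t.min_counts // 2)
        n_spread = min(t.max_genes, max(t.min_genes, total))
        spread(total, n_spread, non_mito)
    elif kind == "high_counts":
        n_spread = (t.min_genes + t.max_genes) // 2
        total = int(np.ceil(1.5 * t.max_counts))
        spread(total, n_spread, non_mito)
    elif kind == "high_mito":
        total = 2 * t.min_counts
        mito_total = max(1, int(np.ceil(0.15 * total)))
        non_total = total - mito_total
        n_spread = min(
            max(t.min_genes, non_total // 2), t.max_genes - len(mito_idx)
        )
        spread(non_total, n_spread, non_mito)
        q, rem = divmod(mito_total, len(mito_idx))
        col[mito_idx] = q
        col[mito_idx[:rem]] += 1
    else:  # pragma: no cover
        raise ValueError(kind)
    return col


# ---------------------------------------------------------------------------
# running the cascade on a bundle


def cascade_inputs(bundle: FixtureBundle):
    """Parse a bundle's files into cascade-ready inputs.

    Returns ``(universe_a, universe_b, candidates, store_a, store_b)`` with
    species B filtered through the default predicted-gene patterns.
    """
    from .annotation_io import (
        DEFAULT_PREDICTED_PATTERNS,
        filter_predicted,
        parse_gtf,
    )
    from .ortholog_assignment import read_candidates
    from .sequence_store import SequenceCategory, SequenceStore, load_fasta

    uni_a = parse_gtf(bundle.gtf_a, bundle.species[0])
    uni_b = filter_predicted(
        parse_gtf(bundle.gtf_b, bundle.species[1]), DEFAULT_PREDICTED_PATTERNS
    )
    stores = {"a": SequenceStore(), "b": SequenceStore()}
    for (species, category), path in sorted(bundle.fastas.items()):
        load_fasta(path, SequenceCategory(category), stores[species])
    candidates = read_candidates(bundle.candidates_path)
    return uni_a, uni_b, candidates, stores["a"], stores["b"]


def build_bundle_table(bundle: FixtureBundle, cfg=None) -> OrthologTable:
    """Run the full assignment cascade on a bundle's files."""
    from .ortholog_assignment import CascadeConfig, build_table

    uni_a, uni_b, candidates, store_a, store_b = cascade_inputs(bundle)
    return build_table(
        uni_a, uni_b, candidates, store_a, store_b, cfg or CascadeConfig()
    )


# ---------------------------------------------------------------------------
# scoring against the truth


def truth_recovery_report(
    table: OrthologTable, truth: dict[str, TruthPair]
) -> dict:
    """Fraction of truth pairs recovered, overall and per intended tier."""
    mapping = table.as_mapping()
    tiers = sorted({tp.tier for tp in truth.values()})
    per_tier = {}
    for tier in tiers:
        items = [(s, tp) for s, tp in truth.items() if tp.tier == tier]
        hit = sum(1 for s, tp in items if mapping.get(s) == tp.target_id)
        per_tier[tier] = hit / len(items) if items else 1.0
    overall = (
        sum(1 for s, tp in truth.items() if mapping.get(s) == tp.target_id)
        / len(truth)
        if truth
        else 1.0
    )
    return {"overall": overall, "per_tier": per_tier, "n_truth": len(truth)}
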