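"""Seeded synthetic fixture bundles in every source dialect.

The generator emulates the inputs the pipeline integrates — an Orphanet-style
XML, an OMIM genemap TSV, a DisGeNet TSV with its UMLS→OMIM map, an HGNC
alias table and a GMT pathway collection — with controlled structure:

* cross-source disease overlap: a configurable fraction of orphan diseases
  are cross-referenced to OMIM (every other one of those also appears in
  DisGeNet), and a fraction of complex diseases are duplicated into
  DisGeNet, so every Venn region the integrator reports is exercised;
* ambiguous UMLS CUIs: a fraction of the DisGeNet-duplicated diseases get a
  CUI that maps to two OMIM identifiers and must be discarded at ingest;
* alias noise: gene mentions are emitted under an HGNC alias or with
  mangled case at a configurable rate; symbol normalization must make the
  noise invisible downstream;
* planted pathway enrichment: selected diseases draw exactly k* of their
  genes from inside a target pathway (exact set construction, not
  rejection sampling), so the enrichment stage has known positives.

Alongside the files, a :class:`FixtureTruth` ledger records the expected
association pairs per source, merged pair count, Venn region counts,
diseasome edges at each configured sharing threshold, and the planted
(disease, pathway, k*) triples — everything downstream tests compare
against.  A fixed seed yields a byte-identical bundle; every file type
draws from its own substream of the master seed, so adding noise to one
dialect never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .ingest import Association, Source
from .integrate import Category

__all__ = [
    "FixtureConfig",
    "FixtureTruth",
    "FixtureBundle",
    "DiseaseSpec",
    "FixtureModel",
    "build_model",
    "generate_fixture",
    "null_fixture",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic study.

    The default scale (200 genes, 30 orphan diseases, 60 complex diseases,
    20 pathways) keeps a full pipeline run well under a second while still
    producing non-trivial overlap structure.  ``planted_pairs`` entries are
    ``(disease_index, pathway_index, k*)`` with diseases indexed orphan
    first, then complex, then DisGeNet-only.
    """

    seed: int = 0
    n_genes: int = 200
    n_od: int = 30
    n_cd: int = 60
    n_disgenet_only: int = 5
    od_gene_count_range: tuple[int, int] = (3, 15)
    cd_gene_count_range: tuple[int, int] = (10, 60)
    cross_source_overlap_fraction: float = 0.5
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 40)
    planted_pairs: tuple[tuple[int, int, int], ...] = ()
    alias_noise_fraction: float = 0.1
    ambiguous_cui_fraction: float = 0.1
    min_shared_grid: tuple[int, ...] = (1, 2, 10)

    def validate(self) -> None:
        for name in ("cross_source_overlap_fraction", "alias_noise_fraction",
                     "ambiguous_cui_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_genes", "n_od", "n_cd", "n_disgenet_only", "n_pathways"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("od_gene_count_range", "cd_gene_count_range",
                     "pathway_size_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 1 <= lo <= hi, got {(lo, hi)}")
        n_diseases = self.n_od + self.n_cd + self.n_disgenet_only
        for d, p, k in self.planted_pairs:
            if not (0 <= d < n_diseases):
                raise ValueError(f"planted disease index {d} out of range")
            if not (0 <= p < self.n_pathways):
                raise ValueError(f"planted pathway index {p} out of range")
            if k < 1:
                raise ValueError(f"planted overlap k*={k} must be >= 1")


@dataclass
class DiseaseSpec:
    """One synthetic disease: identities across sources and its gene set."""

    index: int
    canonical_id: str
    name: str
    genes: list[str]
    category: Category
    sources: frozenset[Source]
    orpha_id: str | None = None
    omim_id: str | None = None
    cui: str | None = None
    ambiguous_cui: bool = False


@dataclass
class FixtureTruth:
    """Ground-truth ledger for one generated bundle."""

    seed: int
    pairs_per_source: dict[str, int]
    disgenet_rows_total: int  # including rows later discarded as ambiguous
    ambiguous_cui_rows: int
    omim_decoy_rows: int
    merged_pairs: int
    venn: dict[str, int]
    n_od_genes: int
    n_cd_genes: int
    n_shared_genes: int
    categories: dict[str, str]
    diseasome_edges: dict[str, list[list]]  # min_shared -> [[a, b, weight, genes]]
    planted: list[list]  # [disease_id, pathway_id, k*]
    n_universe: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class FixtureModel:
    """In-memory fixture: everything needed to emit files or test directly."""

    cfg: FixtureConfig
    genes: list[str]
    alias_of: dict[str, str]  # official -> alias
    pathways: list[tuple[str, str, list[str]]]  # (id, name, members)
    diseases: list[DiseaseSpec]
    truth: FixtureTruth


@dataclass
class FixtureBundle:
    """Paths of one emitted bundle."""

    root: Path
    orphanet: Path
    omim: Path
    disgenet: Path
    umls_map: Path
    aliases: Path
    gmt: Path
    truth: Path


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def build_model(cfg: FixtureConfig) -> FixtureModel:
    """Draw the full fixture in memory; raises before any file is written.

    Substreams: 1 — pathway sizes and membership; 2 — disease gene sets.
    (Stream 3, alias emission, is consumed only at file-writing time.)
    """
    cfg.validate()
    genes = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    alias_of = {g: f"ALT{i:04d}" for i, g in enumerate(genes)}

    # --- pathways: every gene is covered, then sets are topped up ---------
    rng_pw = _rng(cfg.seed, 1)
    pathways: list[tuple[str, str, list[str]]] = []
    members: list[set[str]] = [set() for _ in range(cfg.n_pathways)]
    if cfg.n_pathways > 0:
        order = rng_pw.permutation(cfg.n_genes)
        for j, gi in enumerate(order):
            members[j % cfg.n_pathways].add(genes[gi])
        lo, hi = cfg.pathway_size_range
        for p in range(cfg.n_pathways):
            target = int(rng_pw.integers(lo, hi + 1))
            pool = sorted(set(genes) - members[p])
            extra = target - len(members[p])
            if extra > 0 and pool:
                picks = rng_pw.choice(len(pool), size=min(extra, len(pool)),
                                      replace=False)
                members[p].update(pool[i] for i in picks)
            pathways.append(
                (f"hsa{p + 1:05d}", f"Pathway {p + 1}", sorted(members[p]))
            )
    universe = set().union(*(set(m) for _, _, m in pathways)) if pathways else set()

    planted_by_disease = {d: (p, k) for d, p, k in cfg.planted_pairs}
    if len(planted_by_disease) != len(cfg.planted_pairs):
        raise ValueError("at most one planted pathway per disease")
    for d, p, k in cfg.planted_pairs:
        if k > len(pathways[p][2]):
            raise ValueError(
                f"planted overlap k*={k} exceeds pathway size {len(pathways[p][2])}"
            )

    # --- diseases ---------------------------------------------------------
    rng_d = _rng(cfg.seed, 2)
    n_od_omim = round(cfg.cross_source_overlap_fraction * cfg.n_od)
    n_cd_dg = round(cfg.cross_source_overlap_fraction * cfg.n_cd)
    n_cd_ambig = round(cfg.ambiguous_cui_fraction * n_cd_dg)

    def draw_genes(index: int, count_range: tuple[int, int]) -> list[str]:
        lo, hi = count_range
        n = int(rng_d.integers(lo, hi + 1))
        if index in planted_by_disease:
            p, k = planted_by_disease[index]
            inside = pathways[p][2]
            outside = sorted(set(genes) - set(inside))
            if k > n:
                raise ValueError(
                    f"planted overlap k*={k} exceeds disease gene count {n}"
                )
            if n - k > len(outside):
                raise ValueError("not enough genes outside the planted pathway")
            chosen = [inside[i] for i in rng_d.choice(len(inside), k, replace=False)]
            chosen += [outside[i]
                       for i in rng_d.choice(len(outside), n - k, replace=False)]
            return chosen
        return [genes[i] for i in rng_d.choice(cfg.n_genes, min(n, cfg.n_genes),
                                               replace=False)]

    diseases: list[DiseaseSpec] = []
    for i in range(cfg.n_od):
        cross = i < n_od_omim
        in_dg = cross and (i % 2 == 0)
        sources = {Source.ORPHANET}
        omim_id = None
        cui = None
        if cross:
            sources.add(Source.OMIM)
            omim_id = f"OMIM:{500000 + i}"
        if in_dg:
            sources.add(Source.DISGENET)
            cui = f"C{5000000 + i}"
        diseases.append(DiseaseSpec(
            index=i,
            canonical_id=omim_id or f"ORPHA:{1000 + i}",
            name=f"Orphan disease {i + 1}",
            genes=draw_genes(i, cfg.od_gene_count_range),
            category=Category.BOTH if cross else Category.OD,
            sources=frozenset(sources),
            orpha_id=f"ORPHA:{1000 + i}",
            omim_id=omim_id,
            cui=cui,
        ))
    for j in range(cfg.n_cd):
        index = cfg.n_od + j
        in_dg = j < n_cd_dg
        ambiguous = in_dg and j < n_cd_ambig
        sources = {Source.OMIM}
        if in_dg and not ambiguous:
            sources.add(Source.DISGENET)
        diseases.append(DiseaseSpec(
            index=index,
            canonical_id=f"OMIM:{600000 + j}",
            name=f"Complex disease {j + 1}",
            genes=draw_genes(index, cfg.cd_gene_count_range),
            category=Category.CD,
            sources=frozenset(sources),
            omim_id=f"OMIM:{600000 + j}",
            cui=f"C{6000000 + j}" if in_dg else None,
            ambiguous_cui=ambiguous,
        ))
    for d in range(cfg.n_disgenet_only):
        index = cfg.n_od + cfg.n_cd + d
        diseases.append(DiseaseSpec(
            index=index,
            canonical_id=f"OMIM:{700000 + d}",
            name=f"DisGeNet disease {d + 1}",
            genes=draw_genes(index, cfg.cd_gene_count_range),
            category=Category.CD,
            sources=frozenset({Source.DISGENET}),
            cui=f"C{7000000 + d}",
        ))

    truth = _compute_truth(cfg, diseases, pathways, universe)
    return FixtureModel(cfg, genes, alias_of, pathways, diseases, truth)


def _compute_truth(cfg, diseases, pathways, universe) -> FixtureTruth:
    pairs = {s.value: 0 for s in Source}
    dg_total = 0
    ambiguous_rows = 0
    for d in diseases:
        n = len(d.genes)
        if Source.ORPHANET in d.sources:
            pairs[Source.ORPHANET.value] += n
        if Source.OMIM in d.sources:
            pairs[Source.OMIM.value] += n
        if d.cui is not None:
            dg_total += n
            if d.ambiguous_cui:
                ambiguous_rows += n
            else:
                pairs[Source.DISGENET.value] += n

    venn = {
        "orphanet_only": 0, "omim_only": 0, "disgenet_only": 0,
        "orphanet_omim": 0, "orphanet_disgenet": 0, "omim_disgenet": 0,
        "orphanet_omim_disgenet": 0,
    }
    for d in diseases:
        key = [name for name, src in (
            ("orphanet", Source.ORPHANET),
            ("omim", Source.OMIM),
            ("disgenet", Source.DISGENET),
        ) if src in d.sources]
        venn["_".join(key) + ("_only" if len(key) == 1 else "")] += 1

    od_genes: set[str] = set()
    cd_genes: set[str] = set()
    for d in diseases:
        if d.category in (Category.OD, Category.BOTH):
            od_genes.update(d.genes)
        if d.category in (Category.CD, Category.BOTH):
            cd_genes.update(d.genes)

    edges: dict[str, list[list]] = {}
    gene_sets = {d.canonical_id: set(d.genes) for d in diseases}
    ids = sorted(gene_sets)
    for min_shared in cfg.min_shared_grid:
        found = []
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                common = gene_sets[a] & gene_sets[b]
                if len(common) >= min_shared:
                    found.append([a, b, len(common), sorted(common)])
        edges[str(min_shared)] = found

    by_index = {d.index: d for d in diseases}
    planted = [
        [by_index[di].canonical_id, pathways[pi][0], k]
        for di, pi, k in cfg.planted_pairs
    ]

    return FixtureTruth(
        seed=cfg.seed,
        pairs_per_source=pairs,
        disgenet_rows_total=dg_total,
        ambiguous_cui_rows=ambiguous_rows,
        omim_decoy_rows=2,
        merged_pairs=sum(len(d.genes) for d in diseases),
        venn=venn,
        n_od_genes=len(od_genes),
        n_cd_genes=len(cd_genes),
        n_shared_genes=len(od_genes & cd_genes),
        categories={d.canonical_id: d.category.value for d in diseases},
        diseasome_edges=edges,
        planted=planted,
        n_universe=len(universe),
    )


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def _noisy(symbol: str, alias_of: dict[str, str], fraction: float,
           rng: np.random.Generator) -> str:
    """Emit a gene mention under an alias or with mangled case at rate ``fraction``."""
    if fraction > 0 and rng.random() < fraction:
        return alias_of[symbol] if rng.random() < 0.5 else symbol.lower()
    return symbol


def generate_fixture(cfg: FixtureConfig, out_dir: str | Path) -> tuple[FixtureBundle, FixtureTruth]:
    """Emit the full bundle into ``out_dir`` and return paths plus truth.

    The same config always yields byte-identical files.  Infeasible configs
    (e.g. a planted overlap larger than its pathway) raise ``ValueError``
    before any file is written.
    """
    model = build_model(cfg)
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rng_alias = _rng(cfg.seed, 3)
    noise = cfg.alias_noise_fraction

    from . import ingest  # writers for the XML dialect

    # Orphanet XML
    orphanet_rows: list[Association] = []
    xref: dict[str, str] = {}
    for d in model.diseases:
        if Source.ORPHANET not in d.sources:
            continue
        if d.omim_id:
            xref[d.orpha_id] = d.omim_id
        for g in d.genes:
            raw = _noisy(g, model.alias_of, noise, rng_alias)
            orphanet_rows.append(
                Association(Source.ORPHANET, d.orpha_id, d.name, raw, raw)
            )
    orphanet_path = root / "orphanet.xml"
    ingest.write_orphanet_xml(orphanet_rows, orphanet_path, omim_xref=xref)

    # OMIM genemap (with decoy rows carrying non-3 mapping keys)
    omim_path = root / "omim_genemap.tsv"
    with open(omim_path, "w", newline="") as fh:
        fh.write("# omim_id\tphenotype_name\tmapping_key\tgene_symbols\n")
        for d in model.diseases:
            if Source.OMIM not in d.sources:
                continue
            raws = [_noisy(g, model.alias_of, noise, rng_alias) for g in d.genes]
            fh.write(f"{d.omim_id.split(':')[1]}\t{d.name}\t(3)\t{', '.join(raws)}\n")
        fh.write("999001\tDecoy susceptibility locus\t(2)\tGENE0001\n")
        fh.write("999002\tDecoy cytogenetic locus\t(1)\tGENE0002\n")

    # DisGeNet TSV (ambiguous-CUI diseases included; ingest must drop them)
    disgenet_path = root / "disgenet.tsv"
    with open(disgenet_path, "w", newline="") as fh:
        for d in model.diseases:
            if d.cui is None:
                continue
            for g in d.genes:
                raw = _noisy(g, model.alias_of, noise, rng_alias)
                fh.write(f"{d.cui}\t{d.name}\t{raw}\n")

    # UMLS map (ambiguous CUIs map to two OMIM ids)
    umls_path = root / "umls_map.tsv"
    with open(umls_path, "w", newline="") as fh:
        for d in model.diseases:
            if d.cui is None:
                continue
            target = (d.omim_id or d.canonical_id).split(":")[1]
            fh.write(f"{d.cui}\t{target}\n")
            if d.ambiguous_cui:
                fh.write(f"{d.cui}\t{900000 + d.index}\n")

    # alias table
    alias_path = root / "aliases.tsv"
    with open(alias_path, "w", newline="") as fh:
        fh.write("# alias\tofficial\n")
        for g in model.genes:
            fh.write(f"{model.alias_of[g]}\t{g}\n")

    # GMT
    gmt_path = root / "pathways.gmt"
    with open(gmt_path, "w", newline="") as fh:
        for pid, name, members in model.pathways:
            fh.write("\t".join([pid, name, *members]) + "\n")

    truth_path = root / "truth.json"
    model.truth.to_json(truth_path)

    bundle = FixtureBundle(root, orphanet_path, omim_path, disgenet_path,
                           umls_path, alias_path, gmt_path, truth_path)
    return bundle, model.truth


def null_fixture(cfg: FixtureConfig, out_dir: str | Path) -> tuple[FixtureBundle, FixtureTruth]:
    """A bundle with no planted enrichment, for type-I-error calibration."""
    if cfg.planted_pairs:
        raise ValueError("null_fixture requires an empty planted_pairs")
    return generate_fixture(cfg, out_dir)
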