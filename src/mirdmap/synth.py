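"""Synthetic miRNA→gene and gene→disease mapping generator.

Every analysis in this package is testable without downloading the curated
source databases: the generator draws two random bipartite layers with
independent Bernoulli edges at stated densities, then overlays planted
structures — a hub miRNA targeting a stated fraction of genes, a disease
wired to the target genes of a designated query miRNA set (so that after
the merge the disease's miRNA set contains the whole query, the ``Inf``
odds-ratio situation), and blocks of miRNAs with near-identical
association sets that should surface as cliques in the overlap-enrichment
network. Planting only adds edges, so the densities are lower bounds.

Generation is a pure function of the spec: the same :class:`FixtureSpec`
always yields byte-identical mappings. Names mimic real entities
(``hsa-miR-<k>-5p/3p``, ``GENE<k>``, ``Disease <k>``) so regex-query tests
exercise realistic patterns, including the -5p/-3p arm suffixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mapping import AssociationMap

__all__ = ["FixtureSpec", "GroundTruth", "generate", "mirna_name"]


def mirna_name(k: int) -> str:
    arm = "5p" if k % 2 == 0 else "3p"
    return f"hsa-miR-{k}-{arm}"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic two-layer mapping.

    Defaults give a sparse desk-scale instance: 80 miRNAs × 120 genes ×
    60 diseases at 3% Bernoulli density per layer, which after the merge
    yields a miRNA–disease density of roughly 10% — sparse enough that
    planted structure is clearly separated from background.
    """

    n_mirnas: int = 80
    n_genes: int = 120
    n_diseases: int = 60
    mirna_gene_density: float = 0.03
    gene_disease_density: float = 0.03
    hub_fraction: float | None = None
    enriched_query_size: int | None = None
    clique_sizes: Sequence[int] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_genes, self.n_diseases) < 1:
            raise ValueError("entity counts must be positive")
        for dens in (self.mirna_gene_density, self.gene_disease_density):
            if not 0.0 < dens <= 1.0 or dens != dens:
                raise ValueError(f"density {dens} outside (0, 1]")
        if self.hub_fraction is not None and not 0.0 < self.hub_fraction <= 1.0:
            raise ValueError("hub_fraction must lie in (0, 1]")
        if self.enriched_query_size is not None and not (
            1 <= self.enriched_query_size <= self.n_mirnas
        ):
            raise ValueError("enriched_query_size out of range")
        if any(s < 2 for s in self.clique_sizes):
            raise ValueError("clique sizes must be >= 2")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: hub miRNA, enriched disease + its query, clique blocks."""

    hub: str | None
    enriched_disease: str | None
    enriched_query: tuple[str, ...]
    cliques: tuple[tuple[str, ...], ...]


def generate(spec: FixtureSpec) -> tuple[AssociationMap, AssociationMap, GroundTruth]:
    """Draw the two mapping layers and overlay the planted structures.

    Returns (miRNA→gene map, gene→disease map, ground truth). Raises if the
    drawn spec yields an empty layer (possible only at tiny sizes).
    """
    rng = np.random.default_rng(spec.seed)
    mirnas = [mirna_name(k) for k in range(1, spec.n_mirnas + 1)]
    genes = [f"GENE{k}" for k in range(1, spec.n_genes + 1)]
    diseases = [f"Disease {k}" for k in range(1, spec.n_diseases + 1)]

    mg = rng.random((spec.n_mirnas, spec.n_genes)) < spec.mirna_gene_density
    gd = rng.random((spec.n_genes, spec.n_diseases)) < spec.gene_disease_density

    hub = None
    if spec.hub_fraction is not None:
        # hub targets the first ceil(fraction * n_genes) genes
        hub = mirnas[0]
        k = max(1, int(np.ceil(spec.hub_fraction * spec.n_genes)))
        mg[0, :k] = True

    cliques: list[tuple[str, ...]] = []
    extra_genes: list[str] = []
    extra_mg_rows: dict[str, set[str]] = {}
    extra_gd: dict[str, set[str]] = {}
    if spec.clique_sizes:
        # each block shares a private battery of genes mapping to private
        # diseases, giving near-identical disease sets after the merge
        start = 0
        for ci, size in enumerate(spec.clique_sizes, start=1):
            members = mirnas[start : start + size]
            if len(members) < size:
                raise ValueError("clique sizes exceed n_mirnas")
            start += size
            battery = [f"GENE_C{ci}_{j}" for j in range(1, 11)]
            block_dis = [f"Clique disease {ci}-{j}" for j in range(1, 17)]
            extra_genes.extend(battery)
            for m in members:
                extra_mg_rows.setdefault(m, set()).update(battery)
            for g in battery:
                extra_gd[g] = set(block_dis)
            cliques.append(tuple(members))

    enriched_disease = None
    enriched_query: tuple[str, ...] = ()
    if spec.enriched_query_size:
        # the planted disease attaches to a covering subset of the query's
        # target genes — one least-shared target gene per query miRNA, so
        # containment of the whole query is guaranteed while bystander
        # pickup stays minimal; members without targets get a marker gene
        q_idx = rng.choice(spec.n_mirnas, size=spec.enriched_query_size, replace=False)
        q_idx.sort()
        enriched_query = tuple(mirnas[i] for i in q_idx)
        enriched_disease = "Planted enriched disease"
        target_counts = mg.sum(axis=0)
        cover: set[str] = set()
        for i in q_idx:
            row = np.flatnonzero(mg[i])
            if len(row) == 0:
                marker = f"GENE_Q{i + 1}"
                extra_genes.append(marker)
                extra_mg_rows.setdefault(mirnas[i], set()).add(marker)
                cover.add(marker)
            else:
                j = row[np.argmin(target_counts[row])]
                cover.add(genes[j])
        for g in cover:
            extra_gd.setdefault(g, set()).add(enriched_disease)

    mg_map = AssociationMap.from_pairs(
        [(mirnas[i], genes[j]) for i, j in zip(*np.nonzero(mg))]
    )
    for m, gs in extra_mg_rows.items():
        mg_map.entries.setdefault(m, set()).update(gs)
    gd_map = AssociationMap.from_pairs(
        [(genes[i], diseases[j]) for i, j in zip(*np.nonzero(gd))]
    )
    for g, ds in extra_gd.items():
        gd_map.entries.setdefault(g, set()).update(ds)

    if len(mg_map) == 0 or len(gd_map) == 0:
        raise ValueError(f"spec produced an empty mapping layer: {spec}")

    truth = GroundTruth(
        hub=hub,
        enriched_disease=enriched_disease,
        enriched_query=enriched_query,
        cliques=tuple(cliques),
    )
    return mg_map, gd_map, truth
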