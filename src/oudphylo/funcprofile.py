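"""Gene-content partition, hypergeometric pathway enrichment, BH correction
and KEGG-style module completeness classification.

These are the functional-profiling computations that accompany the
alignment-free phylogeny: which ortholog groups (KOs) are exclusive to a
trophic group versus shared by all groups, whether a gene set is enriched
for a pathway (hypergeometric upper tail), and whether an essential module
is operational in a strain given its detected gene set.

Pathway and module definitions are user-supplied TSVs; no external database
is queried.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneMembershipTable",
    "PathwayDefinition",
    "ModuleDefinition",
    "ModuleStatus",
    "EnrichmentResult",
    "GeneContentPartition",
    "gene_content_partition",
    "hypergeom_pathway_enrichment",
    "bh_adjust",
    "module_completeness",
    "read_membership_table",
    "read_pathway_definitions",
    "read_module_definitions",
]


class GeneMembershipTable:
    """Strain x gene presence table (which ortholog IDs each strain expressed)."""

    def __init__(self, present: pd.DataFrame):
        if present.index.duplicated().any():
            raise ValueError("duplicate strain IDs")
        if present.columns.duplicated().any():
            raise ValueError("duplicate gene IDs")
        self.present = present.astype(bool)

    @property
    def strains(self) -> list[str]:
        return list(self.present.index)

    @property
    def genes(self) -> list[str]:
        return list(self.present.columns)

    def genes_of(self, strain: str) -> set[str]:
        row = self.present.loc[strain]
        return set(row.index[row])

    def shared_genes(self) -> set[str]:
        """Genes present in every strain."""
        return set(self.present.columns[self.present.all(axis=0)])

    @classmethod
    def from_long(cls, rows: Iterable[tuple[str, str]]) -> "GeneMembershipTable":
        """Build from (strain, gene_id) pairs."""
        df = pd.DataFrame(rows, columns=["strain", "gene_id"])
        wide = pd.crosstab(df["strain"], df["gene_id"]).astype(bool)
        wide = wide.sort_index(axis=0).sort_index(axis=1)
        return cls(wide)

    def to_long_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("strain\tgene_id\n")
            for strain in self.present.index:
                row = self.present.loc[strain]
                for gene in row.index[row]:
                    fh.write(f"{strain}\t{gene}\n")


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")


class ModuleStatus(enum.Enum):
    COMPLETE = "complete"
    PARTIAL = "partial"
    MISSING = "missing"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class ModuleDefinition:
    """A pathway module (required enzymes + core subset) or a structural
    complex (a list of constituent pathway modules)."""

    module_id: str
    kind: str  # "pathway_module" | "structural_complex"
    required: frozenset[str] = frozenset()
    core: frozenset[str] = frozenset()
    constituents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "pathway_module":
            if not self.required:
                raise ValueError(f"module {self.module_id!r}: empty required set")
            if not self.core <= self.required:
                raise ValueError(f"module {self.module_id!r}: core must be a subset of required")
        elif self.kind == "structural_complex":
            if not self.constituents:
                raise ValueError(f"complex {self.module_id!r}: no constituent modules")
        else:
            raise ValueError(f"unknown module kind {self.kind!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    overlap: int       # x: selected genes in the pathway
    selected: int      # n: size of the selected set
    pathway_size: int  # K: pathway members within the universe
    universe: int      # N_u
    p_value: float     # hypergeometric upper tail P(X >= x)
    bh_adjusted: float
    significant: bool


@dataclass(frozen=True)
class GeneContentPartition:
    exclusive: dict  # group -> count of genes present only in that group
    core: int        # genes present in every group
    total: int       # genes present in >= 1 strain


def gene_content_partition(
    tbl: GeneMembershipTable, groups: Mapping[str, str]
) -> GeneContentPartition:
    """Partition detected genes by group presence.

    A gene is present in a group iff >= 1 strain of that group carries it;
    exclusive genes occur in exactly one group, core genes in all groups.
    """
    missing = set(tbl.strains) - set(groups)
    if missing:
        raise ValueError(f"strains without group assignment: {sorted(missing)}")
    group_names = sorted(set(groups[s] for s in tbl.strains))
    present_in_group = {
        g: tbl.present.loc[[s for s in tbl.strains if groups[s] == g]].any(axis=0)
        for g in group_names
    }
    flags = pd.DataFrame(present_in_group)  # genes x groups
    detected = flags.any(axis=1)
    n_groups_per_gene = flags.sum(axis=1)
    exclusive = {
        g: int((flags[g] & (n_groups_per_gene == 1)).sum()) for g in group_names
    }
    return GeneContentPartition(
        exclusive=exclusive,
        core=int((n_groups_per_gene == len(group_names)).sum()),
        total=int(detected.sum()),
    )


def hypergeom_pathway_enrichment(
    selected: Iterable[str],
    universe: Iterable[str],
    pathways: Sequence[PathwayDefinition],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of ``selected`` in each pathway.

    Pathway member sets are intersected with the universe before testing;
    p = P(X >= x) for X ~ Hypergeometric(N_u, K, n).  Raw p-values are
    flagged significant at ``alpha``; BH-adjusted p-values are included.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    n_u = len(universe)
    n = len(selected)
    raw = []
    quads = []
    for pw in pathways:
        members = pw.members & universe
        k_size = len(members)
        x = len(selected & members)
        # sf(x-1) = P(X >= x); exactly 1.0 when x = 0
        p = float(hypergeom.sf(x - 1, n_u, k_size, n))
        p = min(p, 1.0)
        raw.append(p)
        quads.append((pw.pathway_id, x, k_size))
    adjusted = bh_adjust(raw)
    return [
        EnrichmentResult(
            pathway_id=pid, overlap=x, selected=n, pathway_size=k_size,
            universe=n_u, p_value=p, bh_adjusted=q, significant=p < alpha,
        )
        for (pid, x, k_size), p, q in zip(quads, raw, adjusted)
    ]


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return [float(v) for v in out]


def module_completeness(
    strain_genes: Iterable[str],
    mod: ModuleDefinition,
    all_modules: Mapping[str, ModuleDefinition] | None = None,
) -> ModuleStatus:
    """Classify a module as complete / partial / missing for one strain.

    Pathway module: complete if at most one required enzyme is missing;
    partial if more than one is missing but every core enzyme is present;
    missing otherwise.  Structural complex: complete if strictly more than
    half of its constituent modules are complete; missing if none is;
    partial otherwise (the exact-half case is partial).
    """
    genes = set(strain_genes)
    if mod.kind == "pathway_module":
        n_missing = len(mod.required - genes)
        if n_missing <= 1:
            return ModuleStatus.COMPLETE
        if mod.core <= genes:
            return ModuleStatus.PARTIAL
        return ModuleStatus.MISSING
    # structural complex
    if all_modules is None:
        raise ValueError("structural complex needs the module lookup")
    statuses = []
    for mid in mod.constituents:
        if mid not in all_modules:
            raise ValueError(f"complex {mod.module_id!r}: unknown constituent module {mid!r}")
        statuses.append(module_completeness(genes, all_modules[mid], all_modules))
    f = sum(1 for s in statuses if s is ModuleStatus.COMPLETE)
    if 2 * f > len(statuses):
        return ModuleStatus.COMPLETE
    if f == 0:
        return ModuleStatus.MISSING
    return ModuleStatus.PARTIAL


# ---------------------------------------------------------------------------
# TSV interfaces

def read_membership_table(path: str | Path) -> GeneMembershipTable:
    """Long-form TSV ``strain<TAB>gene_id`` (header required)."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["strain", "gene_id"]:
            raise ValueError(f"unexpected membership header: {header}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append((parts[0], parts[1]))
    if not rows:
        raise ValueError("empty membership table")
    return GeneMembershipTable.from_long(rows)


def read_pathway_definitions(path: str | Path) -> list[PathwayDefinition]:
    """TSV ``pathway_id<TAB>gene_id`` (header required)."""
    members: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["pathway_id", "gene_id"]:
            raise ValueError(f"unexpected pathway header: {header}")
        for line in fh:
            if not line.strip():
                continue
            pid, gid = line.rstrip("\n").split("\t")[:2]
            members.setdefault(pid, set()).add(gid)
    return [PathwayDefinition(pid, frozenset(g)) for pid, g in sorted(members.items())]


def read_module_definitions(path: str | Path) -> dict[str, ModuleDefinition]:
    """TSV ``module_id<TAB>kind<TAB>gene_id<TAB>is_core``.

    For pathway modules, ``gene_id`` rows list required enzymes (``is_core``
    = 1 marks the core subset).  For structural complexes, ``gene_id`` rows
    name constituent module ids (``is_core`` ignored).
    """
    req: dict[str, set[str]] = {}
    core: dict[str, set[str]] = {}
    cons: dict[str, list[str]] = {}
    kinds: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["module_id", "kind", "gene_id", "is_core"]:
            raise ValueError(f"unexpected module header: {header}")
        for line in fh:
            if not line.strip():
                continue
            mid, kind, gid, is_core = line.rstrip("\n").split("\t")[:4]
            prior = kinds.setdefault(mid, kind)
            if prior != kind:
                raise ValueError(f"module {mid!r} declared with two kinds")
            if kind == "pathway_module":
                req.setdefault(mid, set()).add(gid)
                if is_core.strip() in ("1", "true", "True"):
                    core.setdefault(mid, set()).add(gid)
            else:
                cons.setdefault(mid, []).append(gid)
    modules = {}
    for mid, kind in kinds.items():
        if kind == "pathway_module":
            modules[mid] = ModuleDefinition(
                module_id=mid, kind=kind,
                required=frozenset(req.get(mid, ())),
                core=frozenset(core.get(mid, ())),
            )
        else:
            modules[mid] = ModuleDefinition(
                module_id=mid, kind=kind, constituents=tuple(cons.get(mid, ())),
            )
    return modules


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\tx\tn\tK\tN_u\tp_value\tbh_adjusted\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.pathway_id}\t{r.overlap}\t{r.selected}\t{r.pathway_size}\t"
                f"{r.universe}\t{r.p_value!r}\t{r.bh_adjusted!r}\t{int(r.significant)}\n"
            )
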