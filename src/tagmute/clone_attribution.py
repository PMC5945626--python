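"""Resistant-clone hit attribution and clonality inference.

Colony-picked genome-wide screens yield one sgRNA complement per resistant
clone. A gene is a credible hit when it is targeted by two or more distinct
guide designs across clones (a single design recurring may be a jackpot
clone). Sister clones (descendants of one infected cell) are recognised by
shared integrated passenger guides: sharing two or more identical designs is
high-confidence sisterhood; sharing exactly one design is reported as a
candidate link but never merged, since confirming those requires genomic
indel identity, which is outside this pipeline's inputs.

Clones that are clonal (high confidence) with a cause-bearing clone inherit
that cause ("by clonality"). Genotyping failures ("ND") are retained as
unattributed clones.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "CloneRecord",
    "AttributionResult",
    "attribute_hits",
    "infer_clonality",
    "read_clone_table",
    "read_colony_table",
    "load_mouse_es_clone_fixture",
    "load_sum149_colony_fixture",
    "gene_of_design",
]


def gene_of_design(design_id: str) -> str:
    """Gene symbol of a design id ('Parp1#2' -> 'Parp1', 'Tdg' -> 'Tdg')."""
    return design_id.split("#")[0].split("_ex")[0]


@dataclass
class CloneRecord:
    clone_id: str
    sgrnas: frozenset[str]  # design ids; empty = failed genotyping (ND)
    likely_cause: str | None = None
    clonal_with: frozenset[str] = frozenset()


@dataclass(frozen=True)
class AttributionResult:
    genes: dict[str, tuple[frozenset[str], frozenset[str]]]  # gene -> (designs, clone_ids)
    multi_design_genes: frozenset[str]
    clone_counts_by_cause: dict[str, int]
    clones: tuple[CloneRecord, ...]


def infer_clonality(clones: list[CloneRecord]) -> tuple[list[frozenset[str]], list[tuple[str, str]]]:
    """Sister-clone groups from shared integrated guide designs.

    Returns (high_confidence_groups, candidate_links): groups are transitive
    closures over pairs sharing >= 2 designs; pairs sharing exactly 1 design
    are candidate links only. Invariant to clone ordering.
    """
    ids = sorted(c.clone_id for c in clones)
    by_id = {c.clone_id: c for c in clones}
    parent: dict[str, str] = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    candidates: list[tuple[str, str]] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            shared = by_id[a].sgrnas & by_id[b].sgrnas
            if len(shared) >= 2:
                parent[find(a)] = find(b)
            elif len(shared) == 1:
                candidates.append((a, b))
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    high = sorted(
        (frozenset(g) for g in groups.values() if len(g) > 1),
        key=lambda g: sorted(g)[0],
    )
    return high, candidates


def attribute_hits(clones: list[CloneRecord], library: dict[str, str] | None = None) -> AttributionResult:
    """Gene attribution by multiple distinct guide designs (plus clonality).

    ``library`` maps design_id -> gene; designs absent from it are counted
    under gene "unknown". Genes targeted by >= 2 distinct designs across
    clones are hits; clones carrying a hit-gene design get that gene as
    likely cause, and high-confidence sister clones inherit it.
    """
    clones = [CloneRecord(c.clone_id, c.sgrnas) for c in clones]  # fresh copies

    def gene_of(design: str) -> str:
        if library is not None:
            if design not in library:
                return "unknown"
            return library[design]
        return gene_of_design(design)

    genes: dict[str, tuple[set[str], set[str]]] = {}
    for c in clones:
        for d in c.sgrnas:
            g = gene_of(d)
            designs, cids = genes.setdefault(g, (set(), set()))
            designs.add(d)
            cids.add(c.clone_id)
    multi = frozenset(g for g, (designs, _) in genes.items() if len(designs) >= 2 and g != "unknown")

    for c in clones:
        hit_genes = sorted({gene_of(d) for d in c.sgrnas} & multi)
        if hit_genes:
            c.likely_cause = hit_genes[0]

    groups, _ = infer_clonality(clones)
    by_id = {c.clone_id: c for c in clones}
    for group in groups:
        for c in clones:
            if c.clone_id in group:
                c.clonal_with = frozenset(group - {c.clone_id})
        causes = sorted({by_id[i].likely_cause for i in group if by_id[i].likely_cause})
        if len(causes) == 1:
            for i in group:
                if by_id[i].likely_cause is None:
                    by_id[i].likely_cause = causes[0]

    counts: dict[str, int] = {}
    for c in clones:
        if c.likely_cause:
            counts[c.likely_cause] = counts.get(c.likely_cause, 0) + 1
    return AttributionResult(
        genes={g: (frozenset(d), frozenset(cid)) for g, (d, cid) in genes.items()},
        multi_design_genes=multi,
        clone_counts_by_cause=counts,
        clones=tuple(clones),
    )


# ---------------------------------------------------------------------------
# fixtures and I/O


def read_clone_table(path: str | Path) -> list[CloneRecord]:
    """TSV with columns clone_id, sgrnas (semicolon-separated design ids;
    empty or 'ND' = failed genotyping)."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            raw = row["sgrnas"].strip()
            designs = frozenset() if raw in ("", "ND") else frozenset(s.strip() for s in raw.split(";"))
            out.append(CloneRecord(row["clone_id"], designs))
    return out


def read_colony_table(path: str | Path) -> list[tuple[frozenset[str], int]]:
    """TSV with columns sgrnas (semicolon-separated), colonies."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            raw = row["sgrnas"].strip()
            designs = frozenset() if raw in ("", "ND") else frozenset(s.strip() for s in raw.split(";"))
            out.append((designs, int(row["colonies"])))
    return out


def _data_path(name: str) -> Path:
    return Path(str(resources.files("tagmute").joinpath("data", name)))


def load_mouse_es_clone_fixture() -> list[CloneRecord]:
    """Talazoparib-resistant mouse ES clone table (genome-wide screen)."""
    return read_clone_table(_data_path("mouse_es_resistant_clones.tsv"))


def load_sum149_colony_fixture() -> list[tuple[frozenset[str], int]]:
    """Talazoparib-resistant SUM149 colony counts (genome-wide screen)."""
    return read_colony_table(_data_path("sum149_resistant_colonies.tsv"))
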