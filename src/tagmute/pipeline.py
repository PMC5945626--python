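"""End-to-end composition: reads -> alignments -> alleles -> screen statistics.

These functions are the single path used by the CLI, the analysis drivers and
the acceptance checks, so every number reported anywhere is produced by the
same code.
"""

from __future__ import annotations

import logging
from dataclasses import asdict

import pandas as pd

from .mutation_calling import (
    BOUNDARY,
    FRAMESHIFT,
    IN_FRAME,
    NONSENSE,
    WILD_TYPE,
    Allele,
    call_variants,
    collapse_alleles,
    filter_alleles,
)
from .read_alignment import ScoringParams, align_read, shift_indels_3prime
from .reference_model import CodingTranscript, GuideDesign
from .screen_statistics import (
    PoolEnrichment,
    ProximityResult,
    inframe_enrichment_test,
    mc_proximity_test,
    min_distance_to_cut,
    per_base_density,
)

__all__ = [
    "call_reads",
    "coding_coverage",
    "allele_indel_positions",
    "enrichment_from_table",
    "proximity_from_table",
    "density_from_table",
    "table_for_export",
]

log = logging.getLogger(__name__)

MUTANT_CLASSES = (IN_FRAME, FRAMESHIFT, NONSENSE)


def call_reads(
    reads: list[tuple[str, str]],
    transcript: CodingTranscript,
    params: ScoringParams | None = None,
    min_reads: int = 0,
    min_fraction: float = 0.0,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Align, 3'-shift, call and collapse a batch of reads.

    Returns (allele table, per-coding-base coverage). Coverage counts every
    read whose aligned reference footprint spans the base (deleted bases
    included: the read covers the locus even where it lacks the base).
    """
    alleles: list[Allele] = []
    coverage: dict[int, int] = {}
    n_failed = 0
    for rid, seq in reads:
        try:
            aln = shift_indels_3prime(align_read(seq, transcript, params, read_id=rid), transcript)
        except ValueError:
            n_failed += 1
            continue
        alleles.append(call_variants(aln, transcript))
        lo = max(aln.ref_interval[0], transcript.cds_start)
        hi = min(aln.ref_interval[1], transcript.cds_end)
        for pos in range(lo, hi + 1):
            c = pos - transcript.cds_start + 1
            coverage[c] = coverage.get(c, 0) + 1
    if n_failed:
        log.info("call_reads: %d read(s) failed alignment/QC", n_failed)
    table = collapse_alleles(alleles)
    table = filter_alleles(table, min_reads=min_reads, min_fraction=min_fraction)
    return table, coverage


def coding_coverage(table_coverage: dict[int, int], transcript: CodingTranscript) -> dict[int, int]:
    """Coverage over every coding base (zero-filled)."""
    return {c: table_coverage.get(c, 0) for c in range(1, transcript.coding_length + 1)}


def allele_indel_positions(table: pd.DataFrame) -> list[tuple[int, float]]:
    """(3'-shifted indel start, read weight) per unique indel-bearing allele."""
    out = []
    for _, row in table.iterrows():
        allele: Allele = row["allele"]
        starts = [v.c_start for v in allele.variants if v.kind in ("deletion", "insertion", "delins")]
        if starts:
            out.append((min(starts), float(row["read_count"])))
    return out


def enrichment_from_table(
    table: pd.DataFrame, null_p0: float = 1 / 3, pool: str = "all", unit: str = "alleles"
) -> PoolEnrichment:
    """In-frame enrichment among mutant alleles (boundary/wild-type excluded)."""
    mutant = table[table["frame_class"].isin(MUTANT_CLASSES)]
    if unit == "reads":
        k = int(mutant.loc[mutant["frame_class"] == IN_FRAME, "read_count"].sum())
        n = int(mutant["read_count"].sum())
    else:
        k = int((mutant["frame_class"] == IN_FRAME).sum())
        n = int(len(mutant))
    return inframe_enrichment_test(k, n, null_p0, pool=pool, unit=unit)


def proximity_from_table(
    table: pd.DataFrame,
    guides: list[GuideDesign],
    transcript: CodingTranscript,
    window_bp: int = 5,
    n_iterations: int = 10_000,
    seed: int = 0,
    interval: tuple[int, int] | None = None,
    amplicon_halfwidth: int = 70,
) -> ProximityResult:
    """Cut-site proximity test over the assayed coding interval.

    The null interval defaults to the union span of the guides' amplicons
    clipped to the CDS (only assayed bases can yield observed indels)."""
    cuts = [transcript.cdna_to_c(g.cut_position) for g in guides]
    if interval is None:
        interval = (
            max(1, min(cuts) - amplicon_halfwidth),
            min(transcript.coding_length, max(cuts) + amplicon_halfwidth),
        )
    indels = allele_indel_positions(table)
    return mc_proximity_test(indels, cuts, interval, window_bp, n_iterations, seed)


def density_from_table(
    table: pd.DataFrame,
    coverage: dict[int, int],
    min_coverage: int = 500,
    inframe_only: bool = True,
):
    return per_base_density(table, coverage, min_coverage=min_coverage, inframe_only=inframe_only)


def table_for_export(
    table: pd.DataFrame,
    guides: list[GuideDesign] | None = None,
    transcript: CodingTranscript | None = None,
) -> pd.DataFrame:
    """Drop the in-memory allele column; add min_distance_to_cut if guides given."""
    out = table.drop(columns=["allele"]).copy()
    if guides and transcript is not None:
        cuts = [transcript.cdna_to_c(g.cut_position) for g in guides]
        dists = []
        for _, row in table.iterrows():
            starts = [
                v.c_start
                for v in row["allele"].variants
                if v.kind in ("deletion", "insertion", "delins")
            ]
            dists.append(min_distance_to_cut(min(starts), cuts) if starts else "")
        out["min_distance_to_cut"] = dists
    return out
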