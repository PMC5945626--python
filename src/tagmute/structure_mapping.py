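"""Per-residue mutation scores and PDB B-factor export.

Aggregates the tiling screen's per-base densities to one score per residue
(sum of the codon's three base densities; bases failing the coverage filter
contribute 0 and are counted) and writes the scores into the B-factor column
of a fixed-column PDB file so molecular viewers can colour a structure by
mutation frequency. Only columns 61-66 of matching ATOM records change; the
residue-number offset between transcript and structure numbering is an
explicit parameter, never guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .screen_statistics import BaseDensity

__all__ = ["ResidueScore", "residue_scores", "write_structure_scores", "read_structure_bfactors"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResidueScore:
    residue_index: int
    score: float | None  # None when every codon base failed the coverage filter
    rank_fraction: float
    n_bases_pass: int


def residue_scores(densities: list[BaseDensity], use_mean: bool = False) -> list[ResidueScore]:
    """Aggregate base densities to per-residue scores.

    Score = sum (default) or mean of the codon's passing base densities;
    failing bases contribute 0 but are counted, and a residue whose three
    bases all fail is emitted with a null score. rank_fraction is the
    fraction of scored residues with score <= this one.
    """
    by_res: dict[int, list[BaseDensity]] = {}
    for d in densities:
        by_res.setdefault((d.c_pos - 1) // 3 + 1, []).append(d)
    raw: dict[int, tuple[float | None, int]] = {}
    for res, ds in sorted(by_res.items()):
        passing = [d for d in ds if d.pass_filter]
        if not passing:
            raw[res] = (None, 0)
            continue
        total = sum(d.density for d in passing)
        raw[res] = (total / len(ds) if use_mean else total, len(passing))
    scored = sorted(s for s, _ in raw.values() if s is not None)
    out = []
    for res, (score, n_pass) in sorted(raw.items()):
        if score is None:
            rank = 0.0
        else:
            rank = sum(1 for s in scored if s <= score) / len(scored)
        out.append(ResidueScore(res, score, rank, n_pass))
    return out


def write_structure_scores(
    scores: list[ResidueScore],
    structure_file: str | Path,
    out_file: str | Path,
    chain: str = "A",
    residue_offset: int = 0,
) -> int:
    """Write residue scores into the B-factor column of a PDB file.

    ``residue_offset`` is added to the transcript residue index to obtain the
    PDB residue number. Matching residues get B = min(score, 999.99);
    unmatched residues are set to 0.00 (count returned as annotated count's
    complement via log). Only columns 61-66 change. Malformed ATOM records
    raise with the offending line number.
    """
    by_pdb_res = {
        s.residue_index + residue_offset: (s.score if s.score is not None else 0.0) for s in scores
    }
    annotated = 0
    unmatched = 0
    out_lines = []
    for lineno, line in enumerate(Path(structure_file).read_text().splitlines(keepends=True), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line.rstrip("\n")) < 66:
                raise ValueError(f"malformed ATOM record at line {lineno}: too short for a B-factor field")
            rec_chain = line[21]
            try:
                resnum = int(line[22:26])
            except ValueError as exc:
                raise ValueError(f"malformed ATOM record at line {lineno}: bad residue number") from exc
            if rec_chain == chain and resnum in by_pdb_res:
                b = min(by_pdb_res[resnum], 999.99)
                annotated += 1
            else:
                b = 0.0
                unmatched += 1
            line = line[:60] + f"{b:6.2f}" + line[66:]
        out_lines.append(line)
    if annotated == 0:
        log.warning("write_structure_scores: no residues matched chain %r", chain)
    Path(out_file).write_text("".join(out_lines))
    return annotated


def read_structure_bfactors(path: str | Path, chain: str = "A") -> dict[int, float]:
    """Parse one B-factor per residue back out of a PDB file."""
    out: dict[int, float] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith(("ATOM  ", "HETATM")) and line[21] == chain:
            out[int(line[22:26])] = float(line[60:66])
    return out
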