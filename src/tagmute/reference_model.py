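"""Coding transcripts, guide designs and coordinate arithmetic.

All analysis happens in cDNA space: a :class:`CodingTranscript` is a cDNA
sequence plus the 1-based positions of the first and last base of its CDS.
Guides are located on the transcript by exact protospacer + NGG PAM match on
either strand, and each located guide carries a predicted SpCas9 blunt-cut
position (3 bp 5' of the PAM on the guide strand, reported as the sense-strand
base immediately 5' of the cut).

Coordinate conventions
----------------------
Every public coordinate is 1-based and closed-interval (HGVS style).
``c.`` positions count from the A of the start codon (c.1); residue
``r = floor((c - 1) / 3) + 1``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "CodingTranscript",
    "GuideDesign",
    "CodingCoordinate",
    "locate_guide",
    "predict_cut_site",
    "c_to_residue",
    "read_transcript_fasta",
    "read_guide_library",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CodingTranscript:
    """A cDNA sequence with its coding region.

    Parameters
    ----------
    id : transcript identifier (used to match SAM reference names).
    sequence : cDNA, 5'->3', uppercase ACGT.
    cds_start : 1-based cDNA position of the A of the start codon.
    cds_end : 1-based cDNA position of the last base of the stop codon.
    """

    id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        n = len(self.sequence)
        if not (1 <= self.cds_start < self.cds_end <= n):
            raise ValueError(f"CDS [{self.cds_start}, {self.cds_end}] outside sequence of length {n}")
        clen = self.cds_end - self.cds_start + 1
        if clen % 3 != 0:
            raise ValueError(f"coding length {clen} is not a multiple of 3")
        if clen < 6:
            raise ValueError("coding region shorter than two codons")
        if self.sequence[self.cds_start - 1 : self.cds_start + 2] != "ATG":
            raise ValueError("CDS does not start with ATG")

    @property
    def coding_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def coding_sequence(self) -> str:
        return self.sequence[self.cds_start - 1 : self.cds_end]

    @property
    def protein(self) -> str:
        """Reference protein, stop codon excluded."""
        aa = str(Seq(self.coding_sequence).translate())
        return aa[:-1] if aa.endswith("*") else aa

    def cdna_to_c(self, pos: int) -> int:
        """cDNA position -> coding (c.) position; raises if outside the CDS."""
        if not (self.cds_start <= pos <= self.cds_end):
            raise ValueError(f"cDNA position {pos} outside CDS [{self.cds_start}, {self.cds_end}]")
        return pos - self.cds_start + 1

    def c_to_cdna(self, c_pos: int) -> int:
        if not (1 <= c_pos <= self.coding_length):
            raise ValueError(f"c.{c_pos} outside coding length {self.coding_length}")
        return c_pos + self.cds_start - 1


def c_to_residue(c_pos: int, coding_length: int | None = None) -> int:
    """Residue index of a coding position (c.127 -> residue 43)."""
    if c_pos < 1 or (coding_length is not None and c_pos > coding_length):
        raise ValueError(f"coding position {c_pos} out of range")
    return (c_pos - 1) // 3 + 1


def residue_to_codon_start(residue_index: int) -> int:
    return (residue_index - 1) * 3 + 1


@dataclass(frozen=True)
class CodingCoordinate:
    c_pos: int
    residue_index: int = field(init=False)
    codon_offset: int = field(init=False)

    def __post_init__(self) -> None:
        if self.c_pos < 1:
            raise ValueError("coding positions are 1-based")
        object.__setattr__(self, "residue_index", (self.c_pos - 1) // 3 + 1)
        object.__setattr__(self, "codon_offset", (self.c_pos - 1) % 3 + 1)


@dataclass(frozen=True)
class GuideDesign:
    """A located sgRNA: spacer, PAM and predicted cut position on the cDNA.

    ``protospacer_interval`` is always given in sense-strand coordinates;
    ``cut_position`` is the sense-strand base immediately 5' of the blunt cut.
    """

    id: str
    spacer: str
    pam: str
    strand: str  # "sense" | "antisense"
    protospacer_interval: tuple[int, int]
    cut_position: int
    pool: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.protospacer_interval
        if hi - lo + 1 != 20:
            raise ValueError("protospacer interval must span 20 nt")
        if len(self.spacer) != 20:
            raise ValueError("spacer must be 20 nt")
        if not (lo <= self.cut_position <= hi):
            raise ValueError("cut position outside protospacer")
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"bad strand {self.strand!r}")
        if len(self.pam) != 3 or not self.pam.endswith("GG"):
            raise ValueError(f"PAM {self.pam!r} does not match NGG")


def locate_guide(spacer: str, transcript: CodingTranscript, guide_id: str = "", pool: str = "") -> list[GuideDesign]:
    """All exact protospacer matches with an adjacent NGG PAM, both strands.

    Antisense hits are reported in sense-strand coordinates. Returns an empty
    list when the spacer does not occur with a valid PAM.
    """
    spacer = spacer.upper()
    if len(spacer) != 20 or set(spacer) - set("ACGT"):
        raise ValueError("spacer must be a 20-nt ACGT string")
    seq = transcript.sequence
    hits: list[GuideDesign] = []

    # sense strand: spacer at [i, i+19], PAM at [i+20, i+22] (1-based)
    start = 0
    while (idx := seq.find(spacer, start)) != -1:
        s = idx + 1
        pam = seq[idx + 20 : idx + 23]
        if len(pam) == 3 and pam[1:] == "GG":
            hits.append(
                GuideDesign(
                    id=guide_id or spacer,
                    spacer=spacer,
                    pam=pam,
                    strand="sense",
                    protospacer_interval=(s, s + 19),
                    cut_position=s + 16,
                    pool=pool,
                )
            )
        start = idx + 1

    # antisense strand: sense-strand interval [a, a+19] whose revcomp equals
    # the spacer; PAM is revcomp(seq[a-3..a-1])
    rc = revcomp(spacer)
    start = 0
    while (idx := seq.find(rc, start)) != -1:
        a = idx + 1
        if a >= 4:
            pam = revcomp(seq[idx - 3 : idx])
            if pam[1:] == "GG":
                hits.append(
                    GuideDesign(
                        id=guide_id or spacer,
                        spacer=spacer,
                        pam=pam,
                        strand="antisense",
                        protospacer_interval=(a, a + 19),
                        cut_position=a + 2,
                        pool=pool,
                    )
                )
        start = idx + 1

    hits.sort(key=lambda g: (g.protospacer_interval[0], g.strand))
    return hits


def predict_cut_site(guide: GuideDesign, transcript: CodingTranscript) -> CodingCoordinate:
    """Predicted blunt-cut position as a coding coordinate.

    SpCas9 cuts between protospacer bases 17 and 18 (3 bp 5' of the PAM on
    the guide strand); the cut is reported as the sense-strand base
    immediately 5' of the cut, converted to c. numbering.
    """
    return CodingCoordinate(transcript.cdna_to_c(guide.cut_position))


# ---------------------------------------------------------------------------
# I/O


def read_transcript_fasta(fasta_path: str | Path, cds_path: str | Path) -> list[CodingTranscript]:
    """Read transcripts from FASTA plus a CDS sidecar (TSV or JSON).

    The sidecar maps transcript_id -> (cds_start, cds_end); plain FASTA
    carries no CDS annotation. TSV columns: transcript_id, cds_start, cds_end.
    """
    cds_path = Path(cds_path)
    cds: dict[str, tuple[int, int]] = {}
    if cds_path.suffix.lower() == ".json":
        for tid, rec in json.loads(cds_path.read_text()).items():
            cds[tid] = (int(rec["cds_start"]), int(rec["cds_end"]))
    else:
        with open(cds_path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                cds[row["transcript_id"]] = (int(row["cds_start"]), int(row["cds_end"]))
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in cds:
            raise ValueError(f"no CDS annotation for transcript {rec.id!r}")
        start, end = cds[rec.id]
        out.append(CodingTranscript(id=rec.id, sequence=str(rec.seq), cds_start=start, cds_end=end))
    return out


def read_guide_library(path: str | Path, transcript: CodingTranscript) -> list[GuideDesign]:
    """Read a guide library TSV (columns: id, spacer, pool) and locate each
    spacer on the transcript. Guides that do not match are skipped (reported
    via the returned list simply not containing them)."""
    guides: list[GuideDesign] = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            guides.extend(locate_guide(row["spacer"], transcript, guide_id=row["id"], pool=row.get("pool", "")))
    return guides
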