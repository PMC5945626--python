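"""Variant calling, HGVS nomenclature and frame-effect classification.

From a 3'-shifted alignment this module extracts phased cDNA variants
(substitution / deletion / insertion / delins), renders them as HGVS ``c.``
strings, classifies the allele's net effect on the reading frame and
annotates it at protein level by editing the coding sequence, translating
both versions and diffing the peptides.

Frame classes
-------------
``wild_type``  no variants.
``frameshift`` net length change not a multiple of 3.
``nonsense``   frame preserved but a premature stop introduced.
``in_frame``   frame preserved, full-length protein (possibly mutant).
``boundary``   a variant straddles the CDS edge (splice/boundary); such
               alleles are excluded from frame statistics.

For the enrichment statistic "in-frame" means frame-preserving AND not
nonsense: the screen enriches for full-length protein, so nonsense alleles
are pooled with frameshifts as disruptive.

Protein nomenclature is emitted twice: canonical HGVS (three-letter codes,
e.g. ``p.Met43del``) and the compact screen style used in the field's
resistance tables (``p.43delM``, ``p.44F>I``, ``p.44F>fs49*``). The fsN*
count is the number of novel residues after the last reference-matching
residue, excluding the stop.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio.Seq import Seq

from .reference_model import CodingTranscript
from .read_alignment import (
    DELETION,
    INSERTION,
    MATCH,
    MISMATCH,
    PairwiseAlignment,
)

__all__ = [
    "CdnaVariant",
    "Allele",
    "ProteinChange",
    "call_variants",
    "classify_frame",
    "annotate_protein",
    "collapse_alleles",
    "filter_alleles",
    "parse_hgvs_c",
    "render_hgvs_c",
    "render_allele_hgvs",
    "parse_allele_hgvs",
    "apply_variants",
    "WILD_TYPE",
    "IN_FRAME",
    "FRAMESHIFT",
    "NONSENSE",
    "BOUNDARY",
]

log = logging.getLogger(__name__)

WILD_TYPE, IN_FRAME, FRAMESHIFT, NONSENSE, BOUNDARY = (
    "wild_type",
    "in_frame",
    "frameshift",
    "nonsense",
    "boundary",
)

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}


def _aa3(seq: str) -> str:
    return "".join(AA3[a] for a in seq)


@dataclass(frozen=True)
class CdnaVariant:
    """One phased variant in coding (c.) coordinates.

    Insertions use the flanking convention: ``c_start`` and ``c_end`` are the
    two bases the insertion falls between (c_end = c_start + 1, ref_seq "").
    """

    kind: str  # substitution | deletion | insertion | delins
    c_start: int
    c_end: int
    ref_seq: str
    alt_seq: str

    def __post_init__(self) -> None:
        if self.kind == "deletion" and self.alt_seq:
            raise ValueError("deletion must have empty alt_seq")
        if self.kind == "insertion" and (self.ref_seq or self.c_end != self.c_start + 1):
            raise ValueError("insertion must have empty ref_seq and flanking positions")

    @property
    def net_length_change(self) -> int:
        return len(self.alt_seq) - len(self.ref_seq)

    @property
    def hgvs_c(self) -> str:
        return "c." + render_hgvs_c(self)


def _pos_str(v: CdnaVariant) -> str:
    return str(v.c_start) if v.c_start == v.c_end else f"{v.c_start}_{v.c_end}"


def render_hgvs_c(v: CdnaVariant) -> str:
    """Variant body without the ``c.`` prefix (for bracketed alleles)."""
    if v.kind == "substitution":
        return f"{v.c_start}{v.ref_seq}>{v.alt_seq}"
    if v.kind == "deletion":
        return f"{_pos_str(v)}del{v.ref_seq}"
    if v.kind == "insertion":
        return f"{v.c_start}_{v.c_end}ins{v.alt_seq}"
    if v.kind == "delins":
        return f"{_pos_str(v)}delins{v.alt_seq}"
    raise ValueError(f"unknown variant kind {v.kind!r}")


_SUB_RE = re.compile(r"^(\d+)([ACGT])>([ACGT])$")
_DEL_RE = re.compile(r"^(\d+)(?:_(\d+))?del([ACGT]*)$")
_INS_RE = re.compile(r"^(\d+)_(\d+)ins([ACGT]+)$")
_DELINS_RE = re.compile(r"^(\d+)(?:_(\d+))?delins([ACGT]+)$")


def parse_hgvs_c(s: str, transcript: CodingTranscript | None = None) -> CdnaVariant:
    """Parse a single ``c.`` variant string (cDNA coordinates only)."""
    body = s[2:] if s.startswith("c.") else s
    if m := _SUB_RE.match(body):
        pos = int(m.group(1))
        return CdnaVariant("substitution", pos, pos, m.group(2), m.group(3))
    if m := _DELINS_RE.match(body):
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        ref = transcript.coding_sequence[start - 1 : end] if transcript else "N" * (end - start + 1)
        return CdnaVariant("delins", start, end, ref, m.group(3))
    if m := _DEL_RE.match(body):
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        ref = m.group(3)
        if not ref:
            if transcript is None:
                raise ValueError(f"cannot infer deleted bases of {s!r} without a transcript")
            ref = transcript.coding_sequence[start - 1 : end]
        if len(ref) != end - start + 1:
            raise ValueError(f"deleted sequence length mismatch in {s!r}")
        return CdnaVariant("deletion", start, end, ref, "")
    if m := _INS_RE.match(body):
        return CdnaVariant("insertion", int(m.group(1)), int(m.group(2)), "", m.group(3))
    raise ValueError(f"unparseable HGVS c. string: {s!r}")


def render_allele_hgvs(variants: list[CdnaVariant]) -> str:
    if not variants:
        return "c.="
    if len(variants) == 1:
        return variants[0].hgvs_c
    return "c.[" + ";".join(render_hgvs_c(v) for v in variants) + "]"


def parse_allele_hgvs(s: str, transcript: CodingTranscript | None = None) -> list[CdnaVariant]:
    if s in ("c.=", ""):
        return []
    if s.startswith("c.[") and s.endswith("]"):
        return [parse_hgvs_c(part, transcript) for part in s[3:-1].split(";")]
    return [parse_hgvs_c(s, transcript)]


@dataclass(frozen=True)
class ProteinChange:
    hgvs_p: str                      # canonical HGVS (three-letter)
    hgvs_p_compact: str          # compact table style ("p.43delM")
    affected_residues: frozenset[int]
    novel_residues_before_stop: int | None
    frame_class: str
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class Allele:
    """Phased variants on one read or clone, with frame/protein annotation."""

    variants: tuple[CdnaVariant, ...]
    read_count: int = 1
    frame_class: str = WILD_TYPE
    protein_change: ProteinChange | None = None
    boundary: bool = False

    @property
    def hgvs_c_allele(self) -> str:
        return render_allele_hgvs(list(self.variants))

    @property
    def net_length_change(self) -> int:
        return sum(v.net_length_change for v in self.variants)

    @property
    def key(self) -> str:
        return self.hgvs_c_allele


# ---------------------------------------------------------------------------
# calling


def call_variants(aln: PairwiseAlignment, transcript: CodingTranscript) -> Allele:
    """Extract phased coding variants from a (3'-shifted) alignment.

    Mismatches become substitutions, indel ops deletions/insertions; a
    deletion immediately adjacent to an insertion is merged into a delins.
    Variants wholly outside the CDS are dropped (count logged); a variant
    straddling the CDS boundary marks the allele ``boundary``.
    """
    raw: list[tuple[str, int, int, str, str]] = []  # kind, cdna_start, cdna_end, ref, alt
    r = aln.ref_interval[0]  # 1-based cDNA cursor
    for op in aln.ops:
        if op.kind == MATCH:
            r += op.length
        elif op.kind == MISMATCH:
            for k in range(op.length):
                raw.append(("substitution", r + k, r + k, transcript.sequence[r + k - 1], op.seq[k]))
            r += op.length
        elif op.kind == DELETION:
            raw.append(("deletion", r, r + op.length - 1, op.seq, ""))
            r += op.length
        elif op.kind == INSERTION:
            raw.append(("insertion", r - 1, r, "", op.seq))

    # merge a deletion touching an insertion at the same point into a delins
    merged: list[tuple[str, int, int, str, str]] = []
    i = 0
    while i < len(raw):
        cur = raw[i]
        nxt = raw[i + 1] if i + 1 < len(raw) else None
        if nxt is not None and {cur[0], nxt[0]} == {"deletion", "insertion"}:
            dele = cur if cur[0] == "deletion" else nxt
            ins = nxt if cur[0] == "deletion" else cur
            if ins[1] in (dele[1] - 1, dele[2]):  # flanking the deletion
                merged.append(("delins", dele[1], dele[2], dele[3], ins[4]))
                i += 2
                continue
        merged.append(cur)
        i += 1

    variants: list[CdnaVariant] = []
    dropped = 0
    boundary = False
    for kind, s, e, ref, alt in merged:
        if kind == "insertion":
            inside = transcript.cds_start <= s and e <= transcript.cds_end
            if not inside:
                dropped += 1
                continue
        else:
            if e < transcript.cds_start or s > transcript.cds_end:
                dropped += 1
                continue
            if s < transcript.cds_start or e > transcript.cds_end:
                boundary = True
                continue
        variants.append(
            CdnaVariant(kind, transcript.cdna_to_c(s), transcript.cdna_to_c(e), ref, alt)
        )
    if dropped:
        log.debug("call_variants: dropped %d non-coding variant(s) from %s", dropped, aln.read_id)
    if not variants and not boundary and not merged:
        pass  # clean wild type
    allele = Allele(variants=tuple(variants), boundary=boundary)
    return classify_frame(allele, transcript)


def apply_variants(coding_plus_tail: str, variants: tuple[CdnaVariant, ...]) -> str:
    """Apply coding variants to a sequence whose first base is c.1."""
    seq = coding_plus_tail
    for v in sorted(variants, key=lambda v: v.c_start, reverse=True):
        if v.kind == "insertion":
            seq = seq[: v.c_start] + v.alt_seq + seq[v.c_start :]
        else:
            if seq[v.c_start - 1 : v.c_end] != v.ref_seq:
                raise ValueError(
                    f"reference mismatch applying {v.hgvs_c}: "
                    f"expected {v.ref_seq!r}, found {seq[v.c_start - 1 : v.c_end]!r}"
                )
            seq = seq[: v.c_start - 1] + v.alt_seq + seq[v.c_end :]
    return seq


def _translate_to_stop(seq: str) -> tuple[str, bool]:
    """Translate in frame from position 0; returns (peptide, stop_found)."""
    aa = str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
    idx = aa.find("*")
    if idx == -1:
        return aa, False
    return aa[:idx], True


def classify_frame(allele: Allele, transcript: CodingTranscript) -> Allele:
    """Assign the frame class (and protein annotation) to an allele."""
    if allele.boundary and not allele.variants:
        return replace(allele, frame_class=BOUNDARY, protein_change=None)
    if not allele.variants:
        pc = ProteinChange("p.(=)", "p.(=)", frozenset(), None, WILD_TYPE)
        return replace(allele, frame_class=WILD_TYPE, protein_change=pc)
    if allele.boundary:
        return replace(allele, frame_class=BOUNDARY, protein_change=None)
    pc = annotate_protein(allele, transcript)
    return replace(allele, frame_class=pc.frame_class, protein_change=pc)


def annotate_protein(allele: Allele, transcript: CodingTranscript) -> ProteinChange:
    """Protein-level annotation by translate-and-diff.

    The coding sequence plus downstream cDNA tail is edited with the allele's
    variants and translated from the start codon to the first stop;
    comparison with the reference protein yields the change and its class.
    """
    ref_p = transcript.protein
    tail = transcript.sequence[transcript.cds_start - 1 :]
    mutant = apply_variants(tail, allele.variants)
    mut_p, stop_found = _translate_to_stop(mutant)
    net = allele.net_length_change
    flags: list[str] = []

    if net % 3 != 0:
        # frameshift: first altered residue and novel-residue count
        p = _common_prefix(ref_p, mut_p)
        first = p + 1
        ref_aa = ref_p[p] if p < len(ref_p) else "*"
        if not stop_found:
            flags.append("no_stop_found")
            novel = None
            canonical = f"p.{_aa3(ref_aa)}{first}fs"
            compact = f"p.{first}{ref_aa}>fs?"
        else:
            novel = len(mut_p) - p
            mut_aa = mut_p[p] if p < len(mut_p) else "*"
            if novel == 0:
                canonical = f"p.{_aa3(ref_aa)}{first}Ter"
                compact = f"p.{first}{ref_aa}>*"
            else:
                canonical = f"p.{_aa3(ref_aa)}{first}{_aa3(mut_aa)}fsTer{novel + 1}"
                compact = f"p.{first}{ref_aa}>fs{novel}*"
        affected = frozenset(range(first, len(ref_p) + 1)) or frozenset({first})
        return ProteinChange(canonical, compact, affected, novel, FRAMESHIFT, tuple(flags))

    # frame preserved
    expected_len = len(ref_p) + net // 3
    if stop_found and len(mut_p) < expected_len:
        # premature stop: nonsense
        p = _common_prefix(ref_p, mut_p)
        if p == len(mut_p):  # clean truncation at residue p+1
            first = p + 1
            ref_aa = ref_p[p] if p < len(ref_p) else "*"
            canonical = f"p.{_aa3(ref_aa)}{first}Ter"
            compact = f"p.{first}{ref_aa}>*"
            affected = frozenset({first})
        else:
            first = p + 1
            canonical = f"p.{_aa3(ref_p[p])}{first}delinsTer"
            compact = f"p.{first}{ref_p[p]}>*"
            affected = frozenset(range(first, len(ref_p) + 1))
        return ProteinChange(canonical, compact, affected, 0, NONSENSE, tuple(flags))

    if mut_p == ref_p:
        return ProteinChange("p.(=)", "p.(=)", frozenset(), None, IN_FRAME, tuple(flags))

    # in-frame change: 3'-most placement via maximal prefix, then suffix
    p = _common_prefix(ref_p, mut_p)
    s_max = min(len(ref_p), len(mut_p)) - p
    s = 0
    while s < s_max and ref_p[len(ref_p) - 1 - s] == mut_p[len(mut_p) - 1 - s]:
        s += 1
    deleted = ref_p[p : len(ref_p) - s]
    inserted = mut_p[p : len(mut_p) - s]
    start, end = p + 1, len(ref_p) - s

    if deleted and not inserted:
        if start == end:
            canonical = f"p.{_aa3(deleted)}{start}del"
            compact = f"p.{start}del{deleted}"
        else:
            canonical = f"p.{_aa3(deleted[0])}{start}_{_aa3(deleted[-1])}{end}del"
            compact = f"p.{start}_{end}del{deleted}"
        affected = frozenset(range(start, end + 1))
    elif inserted and not deleted:
        left3 = _aa3(ref_p[p - 1]) if p >= 1 else "Met"
        right3 = _aa3(ref_p[p]) if p < len(ref_p) else "Ter"
        canonical = f"p.{left3}{p}_{right3}{p + 1}ins{_aa3(inserted)}"
        compact = f"p.{p}_{p + 1}ins{inserted}"
        affected = frozenset({max(p, 1), p + 1})
    elif len(deleted) == 1 and len(inserted) == 1:
        canonical = f"p.{_aa3(deleted)}{start}{_aa3(inserted)}"
        compact = f"p.{start}{deleted}>{inserted}"
        affected = frozenset({start})
    else:
        if start == end:
            canonical = f"p.{_aa3(deleted)}{start}delins{_aa3(inserted)}"
        else:
            canonical = f"p.{_aa3(deleted[0])}{start}_{_aa3(deleted[-1])}{end}delins{_aa3(inserted)}"
        compact = f"p.{start}_{end}{deleted}>{inserted}"
        affected = frozenset(range(start, end + 1))
    return ProteinChange(canonical, compact, affected, None, IN_FRAME, tuple(flags))


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


# ---------------------------------------------------------------------------
# allele tables


def collapse_alleles(alleles: list[Allele]) -> pd.DataFrame:
    """Group per-read alleles by identical variant content.

    Returns a DataFrame sorted by read_count descending (ties by HGVS string)
    with one row per distinct allele, the Allele object kept in the
    ``allele`` column.
    """
    groups: dict[str, Allele] = {}
    counts: dict[str, int] = {}
    for a in alleles:
        k = a.key
        counts[k] = counts.get(k, 0) + a.read_count
        groups.setdefault(k, a)
    total = sum(counts.values())
    rows = []
    for k, a in groups.items():
        pc = a.protein_change
        rows.append(
            {
                "hgvs_c": k,
                "hgvs_p": pc.hgvs_p if pc else "",
                "hgvs_p_compact": pc.hgvs_p_compact if pc else "",
                "frame_class": a.frame_class,
                "net_length_change": a.net_length_change,
                "read_count": counts[k],
                "fraction": counts[k] / total if total else 0.0,
                "allele": replace(a, read_count=counts[k]),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["read_count", "hgvs_c"], ascending=[False, True], kind="mergesort")
        df.insert(0, "allele_id", [f"A{i + 1}" for i in range(len(df))])
        df = df.reset_index(drop=True)
    else:
        df = pd.DataFrame(
            columns=[
                "allele_id", "hgvs_c", "hgvs_p", "hgvs_p_compact", "frame_class",
                "net_length_change", "read_count", "fraction", "allele",
            ]
        )
    return df


def filter_alleles(table: pd.DataFrame, min_reads: int = 0, min_fraction: float = 0.0) -> pd.DataFrame:
    """Drop low-support alleles (sequencing-error suppression)."""
    if min_reads < 0 or min_fraction < 0:
        raise ValueError("thresholds must be non-negative")
    if not len(table):
        return table
    keep = (table["read_count"] >= min_reads) & (table["fraction"] >= min_fraction)
    removed = table.loc[~keep, "read_count"].sum()
    if removed:
        log.info("filter_alleles: removed %d reads in %d alleles", removed, int((~keep).sum()))
    return table.loc[keep].reset_index(drop=True)
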