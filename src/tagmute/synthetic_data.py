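"""Synthetic inputs for every pipeline stage.

Nothing here is downloaded: a deterministic synthetic PARP1-like coding
transcript is built in memory (same length class as the real one, with the
residues the resistance literature cares about planted at their canonical
indices: M43/F44/D45 in ZnF1, K119/S120 in ZnF2, N329, H742/D743, Y848/K849,
A925), guide libraries are derived by scanning it for NGG protospacers, and
amplicon reads, clone-sgRNA tables and microirradiation curves are simulated
with known truth. All generators are deterministic given their seed and
write truth alongside outputs; tests never reach into generator internals.

The read simulator emulates the statistical structure of a CRISPR screen's
amplicon sequencing: indels concentrated near predicted cut sites (offsets
Normal(0, sd), default sd 1.5 bp, which reproduces the "almost everything
within 5 bp of a target site" signature), a configurable indel length
distribution (uniform 1..30 gives the 1/3 in-frame null), an 80:20
deletion:insertion split typical of SpCas9 NHEJ, and a flat per-base
substitution error rate.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference_model import CodingTranscript, GuideDesign, locate_guide

__all__ = [
    "SimConfig",
    "make_synthetic_transcript",
    "candidate_guides",
    "focused_library",
    "dense_library",
    "simulate_amplicon_reads",
    "draw_indel_lengths",
    "write_fastq",
    "simulate_clone_table",
    "simulate_recruitment_curve",
]

_CODONS_NO_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

# planted codons: residue index -> codon (canonical resistance-associated
# residues of the PARP1 literature, synthetic context around them)
_PLANTED = {
    43: "ATG",  # M43
    44: "TTT",  # F44
    45: "GAT",  # D45
    119: "AAA",  # K119
    120: "AGC",  # S120
    329: "AAT",  # N329
    591: "CGT",  # R591
    742: "CAT",  # H742
    743: "GAT",  # D743
    848: "TAT",  # Y848
    849: "AAA",  # K849
    850: "CCT",  # P850
    851: "TTT",  # F851
    925: "GCT",  # A925
}


def make_synthetic_transcript(
    n_residues: int = 1014,
    utr5: int = 24,
    utr3: int = 180,
    seed: int = 7342,
    transcript_id: str = "SYNTH_PARP1_LIKE",
) -> CodingTranscript:
    """Deterministic synthetic PARP1-like cDNA (synthetic stand-in; the real
    transcript is not shipped). CDS of ``n_residues`` codons plus a stop,
    with the literature's key residues planted at their canonical indices."""
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    codons += [_CODONS_NO_STOP[i] for i in rng.integers(0, len(_CODONS_NO_STOP), size=n_residues - 1)]
    for res, codon in _PLANTED.items():
        if res <= n_residues:
            codons[res - 1] = codon
    cds = "".join(codons) + "TAA"
    bases = "ACGT"
    five = "".join(bases[i] for i in rng.integers(0, 4, size=utr5))
    three = "".join(bases[i] for i in rng.integers(0, 4, size=utr3))
    seq = five + cds + three
    return CodingTranscript(
        id=transcript_id,
        sequence=seq,
        cds_start=utr5 + 1,
        cds_end=utr5 + len(cds),
    )


def candidate_guides(transcript: CodingTranscript, margin: int = 40) -> list[GuideDesign]:
    """Every NGG protospacer on either strand whose predicted cut falls in
    the CDS at least ``margin`` nt from the CDS edges."""
    seq = transcript.sequence
    lo = transcript.cds_start + margin
    hi = transcript.cds_end - margin
    out: list[GuideDesign] = []
    for idx in range(len(seq) - 22):
        # sense: protospacer at [idx+1, idx+20], PAM at idx+21..23
        if seq[idx + 21 : idx + 23] == "GG":
            cut = idx + 17  # 1-based sense base 5' of cut
            if lo <= cut <= hi:
                spacer = seq[idx : idx + 20]
                out.append(
                    GuideDesign(
                        id=f"g{cut}s",
                        spacer=spacer,
                        pam=seq[idx + 20 : idx + 23],
                        strand="sense",
                        protospacer_interval=(idx + 1, idx + 20),
                        cut_position=cut,
                    )
                )
    rc = str.maketrans("ACGT", "TGCA")
    for idx in range(3, len(seq) - 20):
        # antisense: sense interval [idx+1, idx+20], PAM = revcomp(seq[idx-3:idx])
        if seq[idx - 3 : idx - 1] == "CC":
            cut = idx + 3
            if lo <= cut <= hi:
                sense_proto = seq[idx : idx + 20]
                spacer = sense_proto.translate(rc)[::-1]
                pam = seq[idx - 3 : idx].translate(rc)[::-1]
                out.append(
                    GuideDesign(
                        id=f"g{cut}a",
                        spacer=spacer,
                        pam=pam,
                        strand="antisense",
                        protospacer_interval=(idx + 1, idx + 20),
                        cut_position=cut,
                    )
                )
    out.sort(key=lambda g: (g.cut_position, g.strand))
    return out


def _sample_evenly(guides: list[GuideDesign], n: int) -> list[GuideDesign]:
    if len(guides) <= n:
        return list(guides)
    idx = np.linspace(0, len(guides) - 1, n).round().astype(int)
    return [guides[i] for i in sorted(set(idx.tolist()))]


def focused_library(transcript: CodingTranscript, n_guides: int = 29, n_pools: int = 6) -> list[GuideDesign]:
    """A focused library of ``n_guides`` guides spread along the CDS,
    grouped into ``n_pools`` positional pools (pool 1 = 5'-most region)."""
    picked = _sample_evenly(candidate_guides(transcript), n_guides)
    out = []
    for i, g in enumerate(picked):
        pool = f"pool{i * n_pools // len(picked) + 1}"
        out.append(
            GuideDesign(
                id=f"focus_{i + 1:02d}",
                spacer=g.spacer,
                pam=g.pam,
                strand=g.strand,
                protospacer_interval=g.protospacer_interval,
                cut_position=g.cut_position,
                pool=pool,
            )
        )
    return out


def dense_library(transcript: CodingTranscript, n_guides: int = 489) -> list[GuideDesign]:
    """A dense tiling library: up to ``n_guides`` guides, densest available
    coverage of the CDS."""
    picked = _sample_evenly(candidate_guides(transcript), n_guides)
    return [
        GuideDesign(
            id=f"tile_{i + 1:03d}",
            spacer=g.spacer,
            pam=g.pam,
            strand=g.strand,
            protospacer_interval=g.protospacer_interval,
            cut_position=g.cut_position,
            pool="tiling",
        )
        for i, g in enumerate(picked)
    ]


@dataclass(frozen=True)
class SimConfig:
    """Amplicon-read simulation parameters.

    ``indel_length_distribution`` is ("uniform", L) for uniform on 1..L or
    ("geometric", p); ``target_inframe_fraction`` None lets the length
    distribution set the in-frame rate (uniform 1..30 gives exactly 1/3).
    """

    seed: int
    n_reads: int
    guides: tuple[GuideDesign, ...]
    edit_probability: float = 0.8
    indel_length_distribution: tuple = ("uniform", 30)
    indel_offset_sd: float = 1.5
    insertion_fraction: float = 0.2
    substitution_error_rate: float = 0.0
    target_inframe_fraction: float | None = None
    amplicon_halfwidth: int = 70

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        for p in (self.edit_probability, self.insertion_fraction, self.substitution_error_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")


def draw_indel_lengths(seed: int, n: int, distribution: tuple = ("uniform", 30)) -> np.ndarray:
    """Draw ``n`` indel lengths from the configured distribution.

    Uniform lengths on 1..30 are the null model for the in-frame fraction:
    exactly one length in three is a multiple of 3."""
    rng = np.random.default_rng(seed)
    kind, param = distribution
    if kind == "uniform":
        return rng.integers(1, param + 1, size=n)
    if kind == "geometric":
        return rng.geometric(param, size=n)
    raise ValueError(f"unknown indel length distribution {kind!r}")


def _draw_indel_length(rng: np.random.Generator, cfg: SimConfig) -> int:
    kind, param = cfg.indel_length_distribution
    if cfg.target_inframe_fraction is not None:
        L = param if kind == "uniform" else 30
        inframe = rng.random() < cfg.target_inframe_fraction
        choices = [l for l in range(1, L + 1) if (l % 3 == 0) == inframe]
        return int(choices[rng.integers(0, len(choices))])
    if kind == "uniform":
        return int(rng.integers(1, param + 1))
    if kind == "geometric":
        return int(rng.geometric(param))
    raise ValueError(f"unknown indel length distribution {kind!r}")


def simulate_amplicon_reads(
    config: SimConfig, transcript: CodingTranscript
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate amplicon reads with planted CRISPR-like indels.

    Each read is drawn from the amplicon spanning a uniformly chosen guide;
    with ``edit_probability`` an indel (deletion or insertion, 80:20 by
    default) is planted at cut_position + round(Normal(0, offset_sd)),
    resampled if it would leave the amplicon interior (resample count in the
    truth attrs). Substitution errors are then sprinkled per base. Returns
    (reads, truth): reads as (read_id, sequence), truth one row per read.
    """
    rng = np.random.default_rng(config.seed)
    seq = transcript.sequence
    reads: list[tuple[str, str]] = []
    rows = []
    resamples = 0
    bases = "ACGT"
    for i in range(config.n_reads):
        g = config.guides[int(rng.integers(0, len(config.guides)))]
        a = max(1, g.cut_position - config.amplicon_halfwidth)
        b = min(len(seq), g.cut_position + config.amplicon_halfwidth)
        amplicon = seq[a - 1 : b]
        read = amplicon
        edited = rng.random() < config.edit_probability
        kind, pos, length, ins_seq = "", 0, 0, ""
        if edited:
            for _ in range(100):
                length = _draw_indel_length(rng, config)
                offset = int(round(rng.normal(0.0, config.indel_offset_sd)))
                pos = g.cut_position + offset  # cDNA coordinate
                is_ins = rng.random() < config.insertion_fraction
                if is_ins:
                    if a + 5 <= pos <= b - 5:
                        break
                else:
                    if a + 5 <= pos and pos + length - 1 <= b - 5:
                        break
                resamples += 1
            else:
                raise RuntimeError("could not place indel inside amplicon")
            j = pos - a  # 0-based within amplicon
            if is_ins:
                kind = "insertion"
                ins_seq = "".join(bases[k] for k in rng.integers(0, 4, size=length))
                read = read[: j + 1] + ins_seq + read[j + 1 :]  # inserted after base pos
            else:
                kind = "deletion"
                read = read[:j] + read[j + length :]
        pre_error = read
        n_subs = 0
        if config.substitution_error_rate > 0:
            arr = list(read)
            hits = np.flatnonzero(rng.random(len(arr)) < config.substitution_error_rate)
            for h in hits:
                others = [b for b in bases if b != arr[h]]
                arr[h] = others[int(rng.integers(0, 3))]
            n_subs = len(hits)
            read = "".join(arr)
        read_id = f"sim_{i:06d}"
        reads.append((read_id, read))
        rows.append(
            {
                "read_id": read_id,
                "guide_id": g.id,
                "pool": g.pool,
                "amplicon_start": a,
                "amplicon_end": b,
                "edited": edited,
                "kind": kind,
                "cdna_pos": pos,
                "indel_len": length if edited else 0,
                "inserted_seq": ins_seq,
                "n_error_subs": n_subs,
                "pre_error_seq": pre_error,
                "read_seq": read,
            }
        )
    truth = pd.DataFrame(rows)
    truth.attrs["resamples"] = resamples
    truth.attrs["seed"] = config.seed
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    """Plain or gzipped FASTQ (constant Q30 qualities)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'?' * len(seq)}\n")


def simulate_clone_table(
    seed: int,
    n_clones: int,
    library: dict[str, str],
    hit_gene: str,
    moi_lambda: float = 1.0,
    n_sister_pairs: int = 0,
) -> tuple[list, dict]:
    """Simulate a resistant-clone sgRNA table with planted structure.

    ``library`` maps design_id -> gene; ``hit_gene`` must have >= 2 designs.
    Each clone receives Poisson(moi_lambda) + 1 distinct guides and is forced
    to carry one hit-gene design (rotating among them, so the hit gene ends
    up multi-design). ``n_sister_pairs`` extra clones duplicate existing
    clones' guide sets. Returns (clones, truth)."""
    from .clone_attribution import CloneRecord

    hit_designs = sorted(d for d, g in library.items() if g == hit_gene)
    if len(hit_designs) < 2:
        raise ValueError(f"hit gene {hit_gene!r} needs >= 2 designs in the library")
    other = sorted(d for d, g in library.items() if g != hit_gene)
    rng = np.random.default_rng(seed)
    clones = []
    for i in range(n_clones):
        n_guides = 1 + int(rng.poisson(moi_lambda))
        designs = {hit_designs[i % len(hit_designs)]}
        pool = list(other)
        while len(designs) < n_guides and pool:
            designs.add(pool.pop(int(rng.integers(0, len(pool)))))
        clones.append(CloneRecord(f"C{i + 1}", frozenset(designs)))
    sisters = []
    # sisters are detectable only through shared passenger integrations, so
    # plant them from clones carrying at least one passenger beside the hit
    multi = [c for c in clones if len(c.sgrnas) >= 2] or clones
    for j in range(n_sister_pairs):
        src = multi[int(rng.integers(0, len(multi)))]
        sid = f"C{n_clones + j + 1}"
        clones.append(CloneRecord(sid, src.sgrnas))
        sisters.append((src.clone_id, sid))
    truth = {"cause": hit_gene, "sister_pairs": sisters, "seed": seed}
    return clones, truth


def simulate_recruitment_curve(
    seed: int,
    timepoints: np.ndarray | None = None,
    peak_time: float = 4.0,
    decay_rate: float = 0.05,
    background_level: float = 100.0,
    amplitude: float = 50.0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Microirradiation-style recruitment signal: background + a kinetic
    pulse peaking at ``peak_time`` seconds with slow decay, plus Gaussian
    noise. Returns (t, raw, background, truth_noise_free_raw)."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 60.0, 0.5) if timepoints is None else np.asarray(timepoints, dtype=float)
    x = np.clip(t / peak_time, 0, None)
    kinetic = (x**2) * np.exp(2 * (1 - x))  # unit peak at t = peak_time
    kinetic = kinetic * np.exp(-decay_rate * np.clip(t - peak_time, 0, None))
    truth = background_level + amplitude * kinetic
    raw = truth + rng.normal(0.0, noise_sd, size=t.size)
    background = np.full_like(t, background_level)
    return t, raw, background, truth
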