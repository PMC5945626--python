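import numpy as np
import pytest

from tagmute.reference_model import CodingTranscript
from tagmute.synthetic_data import focused_library, make_synthetic_transcript

NO_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def build_toy_cds(n_codons: int = 60, seed: int = 1, planted: dict[int, str] | None = None) -> str:
    """Deterministic stop-free CDS with specific codons planted (1-based residue)."""
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [NO_STOP[i] for i in rng.integers(0, len(NO_STOP), size=n_codons - 1)]
    for res, codon in (planted or {}).items():
        codons[res - 1] = codon
    return "".join(codons) + "TAA"


@pytest.fixture(scope="session")
def toy_transcript() -> CodingTranscript:
    """60-codon toy CDS with codons 43-45 = ATG TTT GAT (M43 F44 D45) at
    coding 127-135; no UTRs, so cDNA position == c. position."""
    seq = build_toy_cds(60, seed=1, planted={43: "ATG", 44: "TTT", 45: "GAT"})
    return CodingTranscript("toy", seq, 1, len(seq))


@pytest.fixture(scope="session")
def utr_transcript() -> CodingTranscript:
    """Toy transcript with UTRs so cDNA and c. coordinates differ."""
    cds = build_toy_cds(40, seed=3, planted={20: "AAA", 21: "AGC"})
    seq = "GATTACAGATTACA" + cds + "CCGTTACGGATTTACGGATCCA"
    return CodingTranscript("toy_utr", seq, 15, 14 + len(cds))


@pytest.fixture(scope="session")
def synth_transcript() -> CodingTranscript:
    return make_synthetic_transcript()


@pytest.fixture(scope="session")
def synth_guides(synth_transcript):
    return focused_library(synth_transcript)
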