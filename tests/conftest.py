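from collections import Counter

import numpy as np
import pytest

from ribortc.genomics_io import TranscriptModel
from ribortc.psite import PsiteProfile
from ribortc.ribosim import make_ptc_transcript


@pytest.fixture
def tp53_model() -> TranscriptModel:
    """TP53-like single-exon transcript: 394 CDS codons, PTC at codon 213."""
    return make_ptc_transcript()


@pytest.fixture
def two_exon_minus_model() -> TranscriptModel:
    """Hand-checkable 2-exon minus-strand transcript (110 nt)."""
    return TranscriptModel(
        transcript_id="txm", gene_id="gm", chrom="chr1", strand="-",
        exons=((200, 260), (100, 150)),
        cds_start_codon_tx=9, canonical_stop_tx=96,
    )


def profile_from_codons(model: TranscriptModel, counts: dict[int, int]) -> PsiteProfile:
    """Build a PsiteProfile directly from in-frame per-codon counts."""
    codon = np.zeros(model.max_codon_index + 1, dtype=np.int64)
    pos = np.zeros(model.tx_length, dtype=np.int64)
    for ci, c in counts.items():
        codon[ci] = c
        pos[model.codon_tx(ci)] = c
    n = int(pos.sum())
    return PsiteProfile(model.transcript_id, pos, codon, (n, 0, 0), n, Counter())


def write_sam(path, refs: dict[str, int], reads: list[tuple]) -> str:
    """Write a minimal SAM. reads: (name, flag, ref, pos0, cigar)."""
    lines = ["@HD\tVN:1.6"]
    lines += [f"@SQ\tSN:{name}\tLN:{length}" for name, length in refs.items()]
    for name, flag, ref, pos0, cigar in reads:
        lines.append(
            f"{name}\t{flag}\t{ref}\t{pos0 + 1}\t255\t{cigar}\t*\t0\t0\t*\t*"
        )
    path.write_text("\n".join(lines) + "\n")
    return str(path)
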