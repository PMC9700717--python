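"""Transcript coordinate systems and standard-format I/O.

Every interval is 0-based, half-open internally; GTF's 1-based closed
intervals are converted on read.  Codon indices are 1-based with codon 1 at
the annotated start codon, matching protein mutation nomenclature: the TP53
R213X premature termination codon sits at codon 213.

A :class:`TranscriptModel` owns the mapping between genomic and transcript
coordinates for a (possibly spliced) transcript and knows where its CDS,
canonical stop codon and optional premature termination codon (PTC) are.
Ribosome footprints enter as genome-space SAM/BAM and are projected into
transcript space (:func:`project_to_transcript`), or are read directly from
transcript-space SAM (:func:`read_transcript_alignments`).
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "FootprintAlignment",
    "read_annotation",
    "read_ptc_table",
    "project_to_transcript",
    "read_transcript_alignments",
    "write_transcript_sam",
    "write_coverage_track",
    "read_coverage_track",
]


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's exon structure and CDS coordinate system.

    ``exons`` are genomic 0-based half-open intervals in *transcription*
    order (descending genomic coordinate on the minus strand).
    ``cds_start_codon_tx`` / ``canonical_stop_tx`` are transcript
    coordinates of the first nucleotide of the start / canonical stop codon.
    ``ptc_codon_index`` is the optional 1-based codon index of a premature
    termination codon, strictly inside the CDS.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_codon_tx: int
    canonical_stop_tx: int
    ptc_codon_index: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        for s, e in self.exons:
            if not 0 <= s < e:
                raise ValueError(f"{self.transcript_id}: bad exon interval ({s},{e})")
        # non-overlap + transcription order
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            ok = e1 <= s2 if self.strand == "+" else e2 <= s1
            if not ok:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are not in transcription order"
                )
        span = self.canonical_stop_tx - self.cds_start_codon_tx
        if span <= 0 or span % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS span {span} nt is not a positive multiple of 3"
            )
        if not 0 <= self.cds_start_codon_tx < self.tx_length:
            raise ValueError(f"{self.transcript_id}: CDS start outside transcript")
        if self.canonical_stop_tx + 3 > self.tx_length:
            raise ValueError(f"{self.transcript_id}: stop codon extends past transcript end")
        if self.ptc_codon_index is not None:
            if not 1 < self.ptc_codon_index < self.stop_codon_index:
                raise ValueError(
                    f"{self.transcript_id}: PTC codon {self.ptc_codon_index} not strictly "
                    f"inside CDS (stop codon index {self.stop_codon_index})"
                )

    @property
    def tx_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def stop_codon_index(self) -> int:
        """1-based codon index of the canonical stop codon."""
        return (self.canonical_stop_tx - self.cds_start_codon_tx) // 3 + 1

    @property
    def n_cds_codons(self) -> int:
        """Number of CDS codons including the stop codon."""
        return self.stop_codon_index

    @property
    def cds_length(self) -> int:
        """CDS length in nt, stop codon included."""
        return self.canonical_stop_tx + 3 - self.cds_start_codon_tx

    @property
    def max_codon_index(self) -> int:
        """Last codon slot (in CDS frame) fully contained in the transcript."""
        return (self.tx_length - self.cds_start_codon_tx) // 3

    def codon_tx(self, codon_index: int) -> int:
        """Transcript coordinate of the first nt of a 1-based codon index."""
        return self.cds_start_codon_tx + 3 * (codon_index - 1)

    def genome_to_tx(self, gpos: int) -> int | None:
        """Map a genomic position into transcript coordinates (None if intronic)."""
        off = 0
        for s, e in self.exons:
            if s <= gpos < e:
                return off + (gpos - s if self.strand == "+" else e - 1 - gpos)
            off += e - s
        return None

    def tx_to_genome(self, tpos: int) -> int:
        if not 0 <= tpos < self.tx_length:
            raise IndexError(f"transcript position {tpos} outside [0,{self.tx_length})")
        off = 0
        for s, e in self.exons:
            n = e - s
            if tpos < off + n:
                d = tpos - off
                return s + d if self.strand == "+" else e - 1 - d
            off += n
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class FootprintAlignment:
    """A ribosome footprint in transcript space.

    ``five_prime_tx`` is the 0-based transcript coordinate of the footprint
    5' end (the end the P-site offset is measured from).
    """

    read_id: str
    transcript_id: str
    five_prime_tx: int
    length: int
    mapq: int = 255
    multimap_count: int = 1

    def __post_init__(self) -> None:
        if self.five_prime_tx < 0 or self.length <= 0:
            raise ValueError(f"{self.read_id}: invalid footprint coordinates")


def _feature_tx_id(feature) -> str | None:
    if "transcript_id" in feature.attributes:
        return feature.attributes["transcript_id"][0]
    if "Parent" in feature.attributes:
        return feature.attributes["Parent"][0].removeprefix("transcript:")
    return None


def _feature_gene_id(feature) -> str:
    if "gene_id" in feature.attributes:
        return feature.attributes["gene_id"][0]
    return _feature_tx_id(feature) or "NA"


def read_ptc_table(path: str | Path) -> dict[str, int]:
    """Read a TSV with columns ``transcript_id`` and ``ptc_codon_index``."""
    table: dict[str, int] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[row["transcript_id"]] = int(row["ptc_codon_index"])
    return table


def read_annotation(
    gtf_path: str | Path,
    ptc_table: Mapping[str, int] | None = None,
) -> tuple[dict[str, TranscriptModel], dict[str, str]]:
    """Build :class:`TranscriptModel` objects from a GTF/GFF3 annotation.

    One model per protein-coding transcript with a complete CDS (length
    divisible by 3).  If ``stop_codon`` features are present the CDS is taken
    to exclude the stop codon (Ensembl GTF convention); otherwise the last
    three CDS nucleotides are taken as the stop codon.  Transcripts failing
    validation are skipped; returns ``(models, skipped_reasons)``.

    A PTC index outside the CDS interior is a fatal error naming the
    transcript, since it invalidates any downstream readthrough ratio.
    """
    ptc_table = dict(ptc_table or {})
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    for ftype, key in (("exon", "exons"), ("CDS", "cds"), ("stop_codon", "stop")):
        for f in db.features_of_type(ftype):
            tid = _feature_tx_id(f)
            if tid is None:
                continue
            rec = per_tx.setdefault(
                tid, {"exons": [], "cds": [], "stop": [], "chrom": f.seqid,
                      "strand": f.strand, "gene_id": _feature_gene_id(f)}
            )
            rec[key].append((f.start - 1, f.end))  # GTF 1-based closed -> 0-based half-open

    models: dict[str, TranscriptModel] = {}
    skipped: dict[str, str] = {}
    for tid, rec in per_tx.items():
        if not rec["cds"]:
            skipped[tid] = "no CDS"
            continue
        exons = sorted(rec["exons"]) if rec["exons"] else sorted(rec["cds"] + rec["stop"])
        if rec["strand"] == "-":
            exons = exons[::-1]
        try:
            probe = TranscriptModel(
                transcript_id=tid, gene_id=rec["gene_id"], chrom=rec["chrom"],
                strand=rec["strand"], exons=tuple(exons),
                cds_start_codon_tx=0, canonical_stop_tx=3,
            ) if sum(e - s for s, e in exons) >= 6 else None
        except ValueError as exc:
            skipped[tid] = str(exc)
            continue
        if probe is None:
            skipped[tid] = "transcript too short"
            continue
        tx_pos = []
        for s, e in rec["cds"]:
            a, b = probe.genome_to_tx(s), probe.genome_to_tx(e - 1)
            if a is None or b is None:
                tx_pos = None
                break
            tx_pos.extend((min(a, b), max(a, b)))
        if tx_pos is None:
            skipped[tid] = "CDS outside exons"
            continue
        cds_lo, cds_hi = min(tx_pos), max(tx_pos) + 1  # half-open tx interval
        cds_len = cds_hi - cds_lo
        if sum(e - s for s, e in rec["cds"]) != cds_len:
            skipped[tid] = "CDS parts not contiguous in transcript space"
            continue
        if rec["stop"]:
            stop_tx = [probe.genome_to_tx(s) for s, e in rec["stop"]] + [
                probe.genome_to_tx(e - 1) for s, e in rec["stop"]
            ]
            if any(p is None for p in stop_tx):
                skipped[tid] = "stop codon outside exons"
                continue
            stop_first = min(p for p in stop_tx)
            if stop_first != cds_hi:
                skipped[tid] = "stop codon not adjacent to CDS"
                continue
            start_tx, stop_tx0 = cds_lo, stop_first
            total = cds_len + 3
        else:
            start_tx, stop_tx0 = cds_lo, cds_hi - 3
            total = cds_len
        if total % 3 != 0 or total < 6:
            skipped[tid] = "malformed CDS (length not a positive multiple of 3)"
            continue
        ptc = ptc_table.get(tid)
        n_codons = total // 3
        if ptc is not None and not 1 < ptc < n_codons:
            raise ValueError(
                f"PTC codon index {ptc} outside CDS interior of {tid} "
                f"({n_codons} codons incl. stop)"
            )
        try:
            models[tid] = TranscriptModel(
                transcript_id=tid, gene_id=rec["gene_id"], chrom=rec["chrom"],
                strand=rec["strand"], exons=tuple(exons),
                cds_start_codon_tx=start_tx, canonical_stop_tx=stop_tx0,
                ptc_codon_index=ptc,
            )
        except ValueError as exc:
            skipped[tid] = str(exc)
    for tid, reason in skipped.items():
        logger.info("skipped transcript %s: %s", tid, reason)
    return models, skipped


def _project_blocks(blocks: list[tuple[int, int]], model: TranscriptModel):
    """Per-base projection of aligned blocks onto one transcript.

    Returns ``(five_prime_tx, length)`` if every aligned base is exonic and
    the projected bases form one contiguous transcript interval (i.e. read
    splices match the transcript's introns); else None.
    """
    tx = []
    for s, e in blocks:
        for g in range(s, e):
            t = model.genome_to_tx(g)
            if t is None:
                return None
            tx.append(t)
    tx.sort()
    if tx[-1] - tx[0] + 1 != len(tx):
        return None
    return tx[0], len(tx)


def project_to_transcript(
    sam_path: str | Path | pysam.AlignmentFile,
    models: Mapping[str, TranscriptModel],
    max_multimap: int = 1,
) -> tuple[list[FootprintAlignment], Counter]:
    """Project genome-space alignments into transcript coordinates.

    Emits each alignment once per compatible transcript (all aligned bases
    exonic, contiguous in transcript space, read strand matching transcript
    strand).  Reads compatible with no transcript, or exceeding
    ``max_multimap`` genomic mapping sites (NH tag; default unique mappers
    only, as in standard Ribo-seq QC), are tallied in the returned Counter.
    Conservation: assigned reads + sum(discarded) == mapped input reads.
    """
    if not models:
        raise ValueError("no transcript models with exon structure supplied")
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in models.values():
        by_chrom.setdefault(m.chrom, []).append(m)

    own = isinstance(sam_path, (str, Path))
    fh = pysam.AlignmentFile(str(sam_path)) if own else sam_path
    out: list[FootprintAlignment] = []
    discarded: Counter = Counter()
    try:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped:
                discarded["unmapped"] += 1
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            if nh > max_multimap:
                discarded["multimapper"] += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            hits = 0
            for model in by_chrom.get(rec.reference_name, []):
                if model.strand != strand:
                    continue
                proj = _project_blocks(rec.get_blocks(), model)
                if proj is None:
                    continue
                five, length = proj
                out.append(
                    FootprintAlignment(
                        read_id=rec.query_name, transcript_id=model.transcript_id,
                        five_prime_tx=five, length=length,
                        mapq=rec.mapping_quality, multimap_count=nh,
                    )
                )
                hits += 1
            if hits == 0:
                discarded["no_transcript"] += 1
    finally:
        if own:
            fh.close()
    return out, discarded


def read_transcript_alignments(
    sam_path: str | Path,
    models: Mapping[str, TranscriptModel] | None = None,
    max_multimap: int = 1,
) -> tuple[list[FootprintAlignment], Counter]:
    """Read transcript-space SAM/BAM (reference names are transcript ids)."""
    out: list[FootprintAlignment] = []
    discarded: Counter = Counter()
    with pysam.AlignmentFile(str(sam_path)) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped:
                discarded["unmapped"] += 1
                continue
            if models is not None and rec.reference_name not in models:
                discarded["unknown_transcript"] += 1
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            if nh > max_multimap:
                discarded["multimapper"] += 1
                continue
            out.append(
                FootprintAlignment(
                    read_id=rec.query_name, transcript_id=rec.reference_name,
                    five_prime_tx=rec.reference_start,
                    length=rec.reference_length or len(rec.query_sequence or ""),
                    mapq=rec.mapping_quality, multimap_count=nh,
                )
            )
    return out, discarded


def write_transcript_sam(
    alignments: Iterable[FootprintAlignment],
    models: Mapping[str, TranscriptModel],
    path: str | Path,
) -> None:
    """Write footprints as transcript-space SAM (one @SQ per transcript)."""
    tids = sorted(models)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": t, "LN": models[t].tx_length} for t in tids],
    }
    ref_index = {t: i for i, t in enumerate(tids)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = a.read_id
            rec.reference_id = ref_index[a.transcript_id]
            rec.reference_start = a.five_prime_tx
            rec.mapping_quality = a.mapq
            rec.cigartuples = [(0, a.length)]
            rec.set_tag("NH", a.multimap_count)
            fh.write(rec)


def write_annotation_gtf(models: Mapping[str, TranscriptModel],
                         path: str | Path) -> None:
    """Write models as GTF (exon + CDS features, CDS including the stop).

    Round-trips through :func:`read_annotation` for exon-resolved models.
    """
    with open(path, "w") as fh:
        for m in models.values():
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for s, e in sorted(m.exons):
                fh.write(f"{m.chrom}\tribortc\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")
            # CDS in genomic coordinates, stop codon included
            gpos = sorted(m.tx_to_genome(t)
                          for t in range(m.cds_start_codon_tx, m.canonical_stop_tx + 3))
            start = prev = gpos[0]
            for g in gpos[1:] + [None]:
                if g is None or g != prev + 1:
                    fh.write(f"{m.chrom}\tribortc\tCDS\t{start + 1}\t{prev + 1}\t.\t{m.strand}\t.\t{attrs}\n")
                    if g is not None:
                        start = g
                prev = g if g is not None else prev


def write_ptc_table(models: Mapping[str, TranscriptModel], path: str | Path) -> None:
    """Write transcript_id / ptc_codon_index TSV for models carrying a PTC."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tptc_codon_index\n")
        for m in models.values():
            if m.ptc_codon_index is not None:
                fh.write(f"{m.transcript_id}\t{m.ptc_codon_index}\n")


def write_coverage_track(profile, path: str | Path, name: str | None = None) -> None:
    """Write per-position counts as a bedGraph in transcript space.

    ``profile`` is either a ``PsiteProfile`` (uses its ``transcript_id`` and
    ``position_counts``) or a ``(track_id, counts)`` pair.  Adjacent equal
    nonzero values are merged into one record.
    """
    if hasattr(profile, "position_counts"):
        track_id, counts = profile.transcript_id, profile.position_counts
    else:
        track_id, counts = profile
    name = name or track_id
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        start = None
        cur = 0.0
        for i, v in enumerate(list(counts) + [0]):
            if start is not None and v != cur:
                fh.write(f"{track_id}\t{start}\t{i}\t{_fmt(cur)}\n")
                start = None
            if v != 0 and start is None:
                start, cur = i, v


def _fmt(v) -> str:
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def read_coverage_track(path: str | Path) -> dict[str, dict[int, float]]:
    """Parse a bedGraph written by :func:`write_coverage_track`."""
    out: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            tid, s, e, v = line.rstrip("\n").split("\t")
            d = out.setdefault(tid, {})
            for pos in range(int(s), int(e)):
                d[pos] = float(v)
    return out
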