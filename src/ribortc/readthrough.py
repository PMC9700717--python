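"""Stop-codon readthrough statistics from in-frame P-site counts.

Two headline quantities:

* :func:`ptc_readthrough_ratio` — on a transcript carrying a premature
  termination codon (PTC), the length-normalized in-frame P-site density
  between the PTC and the canonical stop divided by the density between the
  start codon and the PTC.  The PTC codon itself is excluded from both
  regions (and the canonical stop from the downstream region) because the
  terminating-ribosome pile-up there would bias the densities.
* :func:`metagene_stop_readthrough` — across many genes aligned at their
  annotated stop codon, the length-normalized in-frame density in the
  3'UTR window (annotated frame extended past the stop) divided by the
  density in the CDS window upstream, with the stop codon excluded.

Both are plain density ratios: 0.10 means the downstream region carries
10% of the upstream per-codon ribosome density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genomics_io import TranscriptModel
from .psite import PsiteProfile

__all__ = [
    "ReadthroughResult",
    "MetageneProfile",
    "ptc_readthrough_ratio",
    "metagene_stop_readthrough",
    "readthrough_report",
    "representative_transcripts",
]


@dataclass(frozen=True)
class ReadthroughResult:
    """PTC readthrough ratio for one transcript and sample."""

    transcript_id: str
    n_pre: int
    n_post: int
    L_pre: int
    L_post: int
    ratio: float
    sample_id: str = ""

    @property
    def percent(self) -> float:
        return 100.0 * self.ratio


@dataclass
class MetageneProfile:
    """In-frame coverage binned around the canonical stop across genes.

    ``bin_percent`` covers, in order, the upstream bins (``bin_codons``
    codons each), the stop-codon bin (always exactly one codon, whatever
    the bin width), then the downstream bins; the values are percentages
    of the window total.  ``readthrough_ratio`` excludes the stop codon
    from both sides.
    """

    bin_percent: np.ndarray
    bin_codons: int
    window_before: int
    window_after: int
    n_genes_included: int
    readthrough_ratio: float
    n_pre: int
    n_post: int

    @property
    def percent(self) -> float:
        return 100.0 * self.readthrough_ratio

    @property
    def stop_bin_index(self) -> int:
        return self.window_before // self.bin_codons


def ptc_readthrough_ratio(
    profile: PsiteProfile, model: TranscriptModel, sample_id: str = ""
) -> ReadthroughResult:
    """Readthrough ratio at the PTC of one transcript.

    n_pre sums in-frame counts over codons 1..(ptc-1); n_post over codons
    (ptc+1)..(stop-1); ratio = (n_post/L_post) / (n_pre/L_pre).  A zero
    pre-PTC signal leaves the ratio undefined and is an error.
    """
    if model.ptc_codon_index is None:
        raise ValueError(f"{model.transcript_id}: no PTC codon index annotated")
    p, ns = model.ptc_codon_index, model.stop_codon_index
    counts = profile.codon_counts
    n_pre = int(counts[1:p].sum())
    n_post = int(counts[p + 1:ns].sum())
    l_pre, l_post = p - 1, ns - 1 - p
    if n_pre == 0:
        raise ValueError(f"{model.transcript_id}: no pre-PTC signal, ratio undefined")
    ratio = (n_post / l_post) / (n_pre / l_pre)
    return ReadthroughResult(model.transcript_id, n_pre, n_post, l_pre, l_post,
                             ratio, sample_id)


def representative_transcripts(
    models: Mapping[str, TranscriptModel]
) -> dict[str, TranscriptModel]:
    """One transcript per gene: longest CDS, ties broken by transcript id."""
    best: dict[str, TranscriptModel] = {}
    for m in models.values():
        cur = best.get(m.gene_id)
        if cur is None or (m.cds_length, cur.transcript_id) > (cur.cds_length, m.transcript_id):
            best[m.gene_id] = m
    return {m.transcript_id: m for m in best.values()}


def metagene_stop_readthrough(
    profiles: Mapping[str, PsiteProfile],
    models: Mapping[str, TranscriptModel],
    window_before: int = 50,
    window_after: int = 50,
    bin_codons: int = 1,
    min_cds_reads: int = 32,
) -> MetageneProfile:
    """Canonical-stop readthrough ratio over a gene set.

    Genes are represented by their longest-CDS transcript and included when
    they carry at least ``min_cds_reads`` in-frame CDS reads (the
    operational definition of "translated").  In-frame counts at codon
    offsets -window_before..-1 and +1..+window_after from the stop are
    accumulated; offsets a transcript cannot provide (short 3'UTR or short
    CDS) contribute nothing for that gene.  The ratio is
    (post sum / window_after) / (pre sum / window_before); windows are in
    codons and must be multiples of ``bin_codons``.
    """
    if window_before % bin_codons or window_after % bin_codons:
        raise ValueError("bin_codons must divide both windows")
    reps = representative_transcripts(models)
    pre = np.zeros(window_before, dtype=np.int64)   # offsets -wb..-1
    post = np.zeros(window_after, dtype=np.int64)   # offsets +1..+wa
    stop_total = 0
    n_genes = 0
    for tid, m in reps.items():
        prof = profiles.get(tid)
        if prof is None:
            continue
        ns = m.stop_codon_index
        cds_reads = int(prof.codon_counts[1:ns].sum())
        if cds_reads < min_cds_reads:
            continue
        n_genes += 1
        for d in range(-window_before, window_after + 1):
            ci = ns + d
            if ci < 1 or ci > m.max_codon_index:
                continue
            c = int(prof.codon_counts[ci])
            if d < 0:
                pre[d + window_before] += c
            elif d == 0:
                stop_total += c
            else:
                post[d - 1] += c
    n_pre, n_post = int(pre.sum()), int(post.sum())
    if n_pre == 0:
        raise ValueError("no pre-stop metagene signal, ratio undefined")
    ratio = (n_post / window_after) / (n_pre / window_before)
    pre_bins = pre.reshape(-1, bin_codons).sum(axis=1)
    post_bins = post.reshape(-1, bin_codons).sum(axis=1)
    bins = np.concatenate([pre_bins, [stop_total], post_bins]).astype(float)
    total = bins.sum()
    bin_percent = 100.0 * bins / total if total > 0 else bins
    return MetageneProfile(bin_percent=bin_percent, bin_codons=bin_codons,
                           window_before=window_before, window_after=window_after,
                           n_genes_included=n_genes, readthrough_ratio=ratio,
                           n_pre=n_pre, n_post=n_post)


def readthrough_report(
    results: Iterable[tuple[str, str, float]] | pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-condition median, quartiles and a bootstrap CI of the median.

    ``results`` is a DataFrame with columns condition, sample_id, ratio or
    an iterable of such triples.  The CI is a seeded percentile bootstrap;
    single-replicate conditions get a degenerate CI and are flagged.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(results, columns=["condition", "sample_id", "ratio"])
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0
    rows = []
    for cond, grp in results.groupby("condition", sort=True):
        vals = grp["ratio"].to_numpy(dtype=float)
        med = float(np.median(vals))
        if len(vals) == 1:
            lo = hi = med
            degenerate = True
        else:
            boots = np.median(
                rng.choice(vals, size=(n_boot, len(vals)), replace=True), axis=1
            )
            lo, hi = (float(np.quantile(boots, q)) for q in (alpha, 1.0 - alpha))
            degenerate = False
        rows.append(
            {"condition": cond, "n": len(vals), "median": med,
             "q1": float(np.quantile(vals, 0.25)), "q3": float(np.quantile(vals, 0.75)),
             "ci_low": lo, "ci_high": hi, "ci_degenerate": degenerate}
        )
    return pd.DataFrame(rows)
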