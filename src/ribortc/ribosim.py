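"""Synthetic-data generators with recorded ground truth.

Three generators mirror the three data types the analysis consumes:

* :func:`simulate_footprints` — ribosome footprints on transcripts, with a
  uniform codon-wise Poisson elongation density, a configurable fraction of
  ribosomes reading through a premature termination codon (PTC) and through
  canonical stop codons, a terminating-ribosome pile-up at stop codons,
  28/29-nt footprint lengths, 3-nt periodicity with sub-codon jitter, and
  optional uniform background.  Every emitted footprint is attributable to
  a placement category via its read id, so recovery tests can compare
  estimates against the exact realized truth.
* :func:`simulate_gi50_matrix` — a compounds x cell-lines GI50 matrix over
  an NCI-60-style colon/renal panel with planted differentially sensitive
  compounds.
* :func:`simulate_confluence` — logistic confluence time courses.

All randomness flows through one ``numpy`` generator seeded per call; the
same seed and configuration reproduce the output exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomics_io import FootprintAlignment, TranscriptModel
from .growth_logistic import ConfluenceSeries

__all__ = [
    "SimConfig",
    "SimTruth",
    "PlantedCompound",
    "DEFAULT_NCI60_PANEL",
    "simulate_footprints",
    "simulate_gi50_matrix",
    "simulate_confluence",
    "make_ptc_transcript",
    "make_plain_transcript",
]


def make_ptc_transcript(
    transcript_id: str = "TP53sim",
    n_cds_codons: int = 394,
    ptc_codon_index: int | None = 213,
    utr5: int = 40,
    utr3: int = 250,
    gene_id: str | None = None,
) -> TranscriptModel:
    """Single-exon transcript with ``n_cds_codons`` CDS codons (stop included).

    Defaults mimic the TP53 coding sequence: 394 codons with the R213X
    premature stop at codon 213.
    """
    cds_nt = 3 * n_cds_codons
    length = utr5 + cds_nt + utr3
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id or transcript_id,
        chrom=transcript_id,
        strand="+",
        exons=((0, length),),
        cds_start_codon_tx=utr5,
        canonical_stop_tx=utr5 + cds_nt - 3,
        ptc_codon_index=ptc_codon_index,
    )


def make_plain_transcript(
    transcript_id: str,
    n_cds_codons: int = 151,
    utr5: int = 40,
    utr3: int = 250,
) -> TranscriptModel:
    """Single-exon transcript without a PTC (for metagene simulations)."""
    return make_ptc_transcript(
        transcript_id, n_cds_codons=n_cds_codons, ptc_codon_index=None,
        utr5=utr5, utr3=utr3,
    )


@dataclass
class SimConfig:
    """Footprint simulation parameters.

    ``lambda_pre`` is the mean number of in-frame ribosomes per codon on the
    CDS upstream of the PTC (or the whole CDS for non-PTC transcripts);
    ``rho_ptc`` / ``rho_canonical`` are readthrough fractions so that
    downstream density is rho * lambda; ``pi_frame`` is the probability a
    footprint's P-site falls exactly on the codon first nucleotide (the
    remaining mass is shifted +-1 nt with equal probability); ``stop_peak``
    multiplies the density at terminating stop codons, emulating ribosomes
    piled up before release; ``beta_bg`` is uniform background footprints
    per nt; ``utr3_span_codons`` bounds how far past a canonical stop
    readthrough extension is simulated.
    """

    seed: int
    transcripts: Sequence[TranscriptModel]
    lambda_pre: float = 20.0
    rho_ptc: float = 0.0
    rho_canonical: float = 0.0
    length_dist: Mapping[int, float] = field(default_factory=lambda: {28: 0.5, 29: 0.5})
    true_offsets: Mapping[int, int] = field(default_factory=lambda: {28: 12, 29: 12})
    pi_frame: float = 0.9
    stop_peak: float = 5.0
    beta_bg: float = 0.0
    utr3_span_codons: int = 50

    def validate(self) -> None:
        if self.lambda_pre <= 0:
            raise ValueError("lambda_pre must be > 0")
        for name in ("rho_ptc", "rho_canonical", "pi_frame"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not math.isclose(sum(self.length_dist.values()), 1.0, abs_tol=1e-9):
            raise ValueError("length_dist probabilities must sum to 1")
        if self.beta_bg < 0 or self.stop_peak < 0:
            raise ValueError("beta_bg and stop_peak must be >= 0")
        max_len = max(self.length_dist)
        for m in self.transcripts:
            if m.tx_length < max_len:
                raise ValueError(
                    f"transcript {m.transcript_id} shorter than max footprint length"
                )
            if m.transcript_id not in {t.transcript_id for t in self.transcripts}:
                raise AssertionError
        for length in self.length_dist:
            if length not in self.true_offsets:
                raise ValueError(f"no true offset for footprint length {length}")


@dataclass
class SimTruth:
    """Exact per-transcript placement counts for emitted footprints.

    ``counts[tid][category]`` counts footprints that survived boundary
    clipping, by category: ``pre_ptc``, ``ptc_peak``, ``post_ptc``,
    ``pre_stop``, ``stop_peak``, ``post_stop``, ``background``.
    """

    counts: dict[str, dict[str, int]]
    models: dict[str, TranscriptModel]
    utr3_span_codons: int = 50

    def realized_rho_ptc(self, transcript_id: str) -> float:
        m = self.models[transcript_id]
        c = self.counts[transcript_id]
        p, ns = m.ptc_codon_index, m.stop_codon_index
        l_pre, l_post = p - 1, ns - 1 - p
        pre = c.get("pre_ptc", 0) / l_pre
        if pre == 0:
            return float("nan")
        return (c.get("post_ptc", 0) / l_post) / pre

    def realized_rho_canonical(self, transcript_id: str) -> float:
        m = self.models[transcript_id]
        c = self.counts[transcript_id]
        n_utr = (
            min(m.max_codon_index, m.stop_codon_index + self.utr3_span_codons)
            - m.stop_codon_index
        )
        pre_key = "pre_stop" if "pre_stop" in c else "post_ptc"
        l_pre = (
            m.stop_codon_index - 1
            if "pre_stop" in c
            else m.stop_codon_index - 1 - m.ptc_codon_index
        )
        pre = c.get(pre_key, 0) / l_pre
        if pre == 0 or n_utr == 0:
            return float("nan")
        return (c.get("post_stop", 0) / n_utr) / pre


def _category_plan(model: TranscriptModel, cfg: SimConfig):
    ns = model.stop_codon_index
    utr_last = min(ns + cfg.utr3_span_codons, model.max_codon_index)
    lam = cfg.lambda_pre
    if model.ptc_codon_index is not None:
        p = model.ptc_codon_index
        return [
            ("pre_ptc", np.arange(1, p), lam),
            ("ptc_peak", np.array([p]), lam * cfg.stop_peak),
            ("post_ptc", np.arange(p + 1, ns), lam * cfg.rho_ptc),
            ("stop_peak", np.array([ns]), lam * cfg.rho_ptc * cfg.stop_peak),
            ("post_stop", np.arange(ns + 1, utr_last + 1),
             lam * cfg.rho_ptc * cfg.rho_canonical),
        ]
    return [
        ("pre_stop", np.arange(1, ns), lam),
        ("stop_peak", np.array([ns]), lam * cfg.stop_peak),
        ("post_stop", np.arange(ns + 1, utr_last + 1), lam * cfg.rho_canonical),
    ]


def simulate_footprints(config: SimConfig) -> tuple[list[FootprintAlignment], SimTruth]:
    """Draw footprints codon-wise Poisson per the configuration.

    Each ribosome at codon ``i`` yields one footprint whose P-site is the
    codon's first nucleotide, jittered off-frame with probability
    ``1 - pi_frame`` (+-1 nt, equal odds); the footprint 5' end is
    P-site - offset(length).  Footprints extending past either transcript
    end are dropped before being counted in the truth, so truth counts equal
    emitted alignments per category exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = np.array(sorted(config.length_dist))
    probs = np.array([config.length_dist[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    offsets = np.array([config.true_offsets[l] for l in lengths])

    alignments: list[FootprintAlignment] = []
    truth_counts: dict[str, dict[str, int]] = {}
    for model in config.transcripts:
        tid = model.transcript_id
        cat_counts: dict[str, int] = {}
        for cat, codons, mu in _category_plan(model, config):
            if len(codons) == 0 or mu == 0:
                cat_counts.setdefault(cat, 0)
                continue
            k = rng.poisson(mu, len(codons))
            psites = np.repeat(model.cds_start_codon_tx + 3 * (codons - 1), k)
            n = psites.size
            if n:
                off_frame = rng.random(n) >= config.pi_frame
                shift = rng.integers(0, 2, n) * 2 - 1
                psites = psites + off_frame * shift
                li = rng.choice(len(lengths), n, p=probs)
                five = psites - offsets[li]
                ok = (five >= 0) & (five + lengths[li] <= model.tx_length)
                five, li = five[ok], li[ok]
            else:
                five = psites
                li = psites
            cat_counts[cat] = int(five.size)
            for j in range(five.size):
                alignments.append(
                    FootprintAlignment(
                        read_id=f"{tid}|{cat}|{j}", transcript_id=tid,
                        five_prime_tx=int(five[j]), length=int(lengths[li[j]]),
                    )
                )
        # uniform background over the whole transcript, random frame
        n_bg = rng.poisson(config.beta_bg * model.tx_length) if config.beta_bg else 0
        emitted_bg = 0
        if n_bg:
            li = rng.choice(len(lengths), n_bg, p=probs)
            five = rng.integers(0, model.tx_length, n_bg)
            ok = five + lengths[li] <= model.tx_length
            five, li = five[ok], li[ok]
            for j in range(five.size):
                alignments.append(
                    FootprintAlignment(
                        read_id=f"{tid}|background|{j}", transcript_id=tid,
                        five_prime_tx=int(five[j]), length=int(lengths[li[j]]),
                    )
                )
            emitted_bg = int(five.size)
        cat_counts["background"] = emitted_bg
        truth_counts[tid] = cat_counts
    truth = SimTruth(counts=truth_counts,
                     models={m.transcript_id: m for m in config.transcripts},
                     utr3_span_codons=config.utr3_span_codons)
    return alignments, truth


# ---------------------------------------------------------------------------
# GI50 matrices

# The 15-line colon/renal panel used for the differential-sensitivity screen:
# each tissue contributes one TP53-nonsense line, plus WT and missense/other-
# mutant lines.
DEFAULT_NCI60_PANEL = pd.DataFrame(
    [
        ("HCC-2998", "colon", "nonsense"),
        ("HCT116", "colon", "WT"),
        ("HCT-15", "colon", "other-mut"),
        ("HT29", "colon", "other-mut"),
        ("KM12", "colon", "other-mut"),
        ("SW-620", "colon", "other-mut"),
        ("COLO205", "colon", "other-mut"),
        ("SN12C", "renal", "nonsense"),
        ("A498", "renal", "WT"),
        ("ACHN", "renal", "WT"),
        ("CAKI-1", "renal", "WT"),
        ("UO-31", "renal", "WT"),
        ("RXF-393", "renal", "other-mut"),
        ("786-0", "renal", "other-mut"),
        ("TK-10", "renal", "other-mut"),
    ],
    columns=["cell_line", "tissue", "tp53_status"],
).set_index("cell_line")


@dataclass(frozen=True)
class PlantedCompound:
    """A compound planted with exact group-mean GI50 ratios.

    ``ratio_mut`` = mean GI50(other-mut)/mean GI50(nonsense) and
    ``ratio_wt`` = mean GI50(WT)/mean GI50(nonsense), realized in every
    tissue listed in ``tissues`` (None = all panel tissues).
    """

    compound: str
    ratio_mut: float
    ratio_wt: float
    tissues: tuple[str, ...] | None = None


def simulate_gi50_matrix(
    n_compounds: int,
    panel_spec: pd.DataFrame | None = None,
    planted: Sequence[PlantedCompound] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Generate a GI50 matrix with planted differential compounds.

    Unplanted compounds get one shared log-normal GI50 across all lines
    (ratios exactly 1 before noise); planted compounds realize their target
    group-mean ratios exactly at ``noise_sd=0``.  ``noise_sd`` is the SD of
    multiplicative log-normal noise on each entry.  Returns
    ``(GI50Matrix, truth)`` where ``truth`` is a DataFrame of planted
    compounds and their target ratios per tissue.
    """
    from .screen_gi50 import GI50Matrix

    panel = DEFAULT_NCI60_PANEL if panel_spec is None else panel_spec
    for p in planted:
        if p.ratio_mut <= 0 or p.ratio_wt <= 0:
            raise ValueError(f"planted ratio must be > 0 for {p.compound}")
    rng = np.random.default_rng(seed)
    names = [p.compound for p in planted]
    names += [f"C{i:05d}" for i in range(n_compounds - len(names))]
    if len(set(names)) != n_compounds:
        raise ValueError("duplicate compound names")
    tissues = list(dict.fromkeys(panel["tissue"]))
    values = pd.DataFrame(index=names, columns=panel.index, dtype=float)
    truth_rows = []
    for i, name in enumerate(names):
        base = 10.0 ** rng.normal(-5.0, 0.5)
        row = np.full(len(panel.index), base)
        if i < len(planted):
            p = planted[i]
            target = set(p.tissues) if p.tissues is not None else set(tissues)
            for j, line in enumerate(panel.index):
                if panel.loc[line, "tissue"] not in target:
                    continue
                status = panel.loc[line, "tp53_status"]
                if status == "other-mut":
                    row[j] = base * p.ratio_mut
                elif status == "WT":
                    row[j] = base * p.ratio_wt
            for t in sorted(target):
                truth_rows.append(
                    {"compound": name, "tissue": t,
                     "ratio_mut": p.ratio_mut, "ratio_wt": p.ratio_wt}
                )
        values.loc[name] = row
    if noise_sd > 0:
        values *= np.exp(rng.normal(0.0, noise_sd, values.shape))
    truth = pd.DataFrame(truth_rows, columns=["compound", "tissue", "ratio_mut", "ratio_wt"])
    return GI50Matrix(values=values, labels=panel.copy()), truth


def simulate_confluence(
    K: float,
    A: float,
    r: float,
    t0: float,
    noise_sd: float,
    times: Sequence[float],
    seed: int = 0,
    condition: str = "sim",
    replicate: str | int = 1,
) -> ConfluenceSeries:
    """Logistic confluence curve C(t) = A + (K-A)/(1+exp(-r(t-t0))) + noise.

    Gaussian noise with SD ``noise_sd``; values clipped to [0, 100] %.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be a strictly increasing vector")
    if not (K > A >= 0):
        raise ValueError("require K > A >= 0")
    if r <= 0:
        raise ValueError("require r > 0")
    rng = np.random.default_rng(seed)
    c = A + (K - A) / (1.0 + np.exp(-r * (t - t0)))
    if noise_sd > 0:
        c = c + rng.normal(0.0, noise_sd, len(t))
    c = np.clip(c, 0.0, 100.0)
    return ConfluenceSeries(condition=condition, replicate=str(replicate),
                            times=t, values=c)
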