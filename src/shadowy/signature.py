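"""Male-vs-female alignment-feature contrasts: the duplication signature.

A diverged retrocopy on the Y chromosome leaves a characteristic footprint
in male (never female) short-read alignments over the parent gene's exons:
extra read depth (the Y copy's reads pile onto the parent locus), apparent
heterozygous sites (the diverged nucleotides), discordant mate pairs
(mates landing on unassembled Y sequence) and depressed mapping quality
(reads fitting two loci).  This module turns per-window feature summaries
into explicit duplication calls and rolls them up to a gene-level
retrocopy verdict — retrocopies are spliced, so the signal must be
exon-restricted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

FEATURES = ["depth", "het_density", "discordant_frac", "lowmapq_frac"]


@dataclass
class SignatureThresholds:
    """Decision thresholds for a male-specific duplication call.

    A window is called when the male/female depth ratio reaches
    ``min_depth_ratio`` *and* at least ``min_supporting_criteria`` of the
    heterozygosity / discordant-mate / low-mapQ excesses (male mean minus
    female mean) clear their thresholds.  Units: het excess in sites per
    kb, the two fractions in absolute proportion.
    """

    min_depth_ratio: float = 1.3
    min_het_excess: float = 1.0
    min_discordant_excess: float = 0.05
    min_lowmapq_excess: float = 0.05
    min_supporting_criteria: int = 2

    def __post_init__(self) -> None:
        vals = (self.min_depth_ratio, self.min_het_excess,
                self.min_discordant_excess, self.min_lowmapq_excess,
                self.min_supporting_criteria)
        if any(v < 0 for v in vals):
            raise ValueError("thresholds must be non-negative")


@dataclass
class SignatureCall:
    window_start: int
    window_end: int
    depth_ratio: float
    het_excess: float
    discordant_excess: float
    lowmapq_excess: float
    n_criteria_met: int
    is_duplication: bool
    uninformative: bool = False


@dataclass
class GeneVerdict:
    gene: str
    n_exon_windows: int
    n_exon_called: int
    n_intron_called: int
    is_candidate: bool
    flag: str = ""


def contrast_windows(
    tracks: pd.DataFrame, thresholds: SignatureThresholds | None = None
) -> list[SignatureCall]:
    """Per-window male-vs-female contrast over a feature-track table.

    ``tracks`` is long-format with columns ``sample, sex, window_start,
    window_end, depth, het_density, discordant_frac, lowmapq_frac``.
    Features are averaged within each sex per window.  The depth ratio is
    male mean over female mean; a zero-coverage female window falls back
    to a 0.5 pseudocount denominator so the ratio stays finite.  Windows
    missing either sex are flagged uninformative and never called.
    Female-elevated windows cannot be called: all excesses are signed.
    """
    thr = thresholds or SignatureThresholds()
    calls: list[SignatureCall] = []
    for (ws, we), grp in tracks.groupby(["window_start", "window_end"], sort=True):
        males = grp[grp["sex"] == "male"]
        females = grp[grp["sex"] == "female"]
        if males.empty or females.empty:
            calls.append(SignatureCall(int(ws), int(we), float("nan"), float("nan"),
                                       float("nan"), float("nan"), 0, False,
                                       uninformative=True))
            continue
        m = males[FEATURES].mean()
        f = females[FEATURES].mean()
        denom = f["depth"] if f["depth"] > 0 else 0.5
        ratio = m["depth"] / denom
        het_ex = m["het_density"] - f["het_density"]
        dis_ex = m["discordant_frac"] - f["discordant_frac"]
        mq_ex = m["lowmapq_frac"] - f["lowmapq_frac"]
        met = int(het_ex >= thr.min_het_excess) + \
            int(dis_ex >= thr.min_discordant_excess) + \
            int(mq_ex >= thr.min_lowmapq_excess)
        is_dup = ratio >= thr.min_depth_ratio and met >= thr.min_supporting_criteria
        calls.append(SignatureCall(int(ws), int(we), float(ratio), float(het_ex),
                                   float(dis_ex), float(mq_ex), met, bool(is_dup)))
    return calls


def summarize_region_call(
    calls: list[SignatureCall],
    exon_windows: set[tuple[int, int]],
    intron_windows: set[tuple[int, int]] | None = None,
    gene: str = "",
    min_exon_fraction: float = 0.5,
) -> GeneVerdict:
    """Gene-level retrocopy verdict from per-window duplication calls.

    A gene is a retrocopy candidate when at least ``min_exon_fraction`` of
    its exon windows carry duplication calls and none of its intron-only
    windows do.  Intronic calls suggest a tandem (unspliced) duplication
    and veto the retrocopy interpretation; the verdict is flagged.
    """
    if not exon_windows:
        raise ValueError(f"gene {gene!r}: no exon windows supplied")
    intron_windows = intron_windows or set()
    by_win = {(c.window_start, c.window_end): c for c in calls}
    n_exon_called = sum(
        1 for w in exon_windows if w in by_win and by_win[w].is_duplication
    )
    n_intron_called = sum(
        1 for w in intron_windows if w in by_win and by_win[w].is_duplication
    )
    frac = n_exon_called / len(exon_windows)
    is_candidate = frac >= min_exon_fraction and n_intron_called == 0
    flag = ""
    if n_intron_called > 0 and frac >= min_exon_fraction:
        flag = "intronic signal: tandem-duplication-like, not a retrocopy"
    return GeneVerdict(
        gene=gene,
        n_exon_windows=len(exon_windows),
        n_exon_called=n_exon_called,
        n_intron_called=n_intron_called,
        is_candidate=is_candidate,
        flag=flag,
    )


def calls_to_frame(calls: list[SignatureCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])
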