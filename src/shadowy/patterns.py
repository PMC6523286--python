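"""Genotype-pattern classification and genomic region clustering.

After the sex scan, each significant marker is inspected for the diagnostic
hemizygous-paralog pattern: every male heterozygous (the "heterozygosity"
is really the diverged Y paralog read against the homologous reference
allele) and every female carrying one and the same homozygous genotype.
Markers where males instead mix heterozygous and homozygous calls — the
pattern seen at a pseudoautosomal or otherwise genuinely segregating locus
— are excluded.  Classified markers are merged into regions by
single-linkage clustering along each chromosome and annotated against
gene, telomere and centromere intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import HOM_REF, HET, HOM_ALT, MISSING

SHADOW_Y = "SHADOW_Y"
EXCLUDED_HOM = "EXCLUDED_HOM"
OTHER = "OTHER"


@dataclass
class PatternCall:
    marker: str
    pattern: str  # SHADOW_Y | EXCLUDED_HOM | OTHER
    n_male_het: int
    n_male_hom_ref: int
    n_male_hom_alt: int
    n_female_distinct_genotypes: int


@dataclass
class Region:
    """A run of markers on one chromosome, merged at <= max_gap spacing."""

    chrom: str
    start: int
    end: int
    members: list[tuple[str, int]]  # (marker id, pos), sorted by pos
    categories: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationSet:
    """Gene/centromere intervals and chromosome lengths, 1-based inclusive.

    ``telomere_window`` / ``centromere_window`` give the distance from a
    chromosome end (resp. a centromere interval) within which a marker is
    called telomeric (resp. centromeric).
    """

    genes: pd.DataFrame  # columns chrom, start, end, name
    chrom_lengths: dict[str, int]
    centromeres: pd.DataFrame | None = None  # columns chrom, start, end
    telomere_window: int = 500_000
    centromere_window: int = 500_000

    @classmethod
    def from_bed(cls, genes_bed: pd.DataFrame, chrom_lengths, centromeres_bed=None, **kw):
        """Build from 0-based half-open BED frames (converted on ingest)."""
        def conv(df):
            out = df.copy()
            out["start"] = out["start"] + 1
            return out

        cen = conv(centromeres_bed) if centromeres_bed is not None else None
        return cls(genes=conv(genes_bed), chrom_lengths=dict(chrom_lengths),
                   centromeres=cen, **kw)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_marker(
    male_calls: np.ndarray,
    female_calls: np.ndarray,
    marker: str = "",
    male_tolerance: float = 0.0,
) -> PatternCall:
    """Call the sex-genotype pattern of one marker.

    ``SHADOW_Y``: the fraction of non-missing males that are *not*
    heterozygous is <= ``male_tolerance`` and all non-missing females share
    a single homozygous genotype.  ``EXCLUDED_HOM``: females are
    monoallelic but males mix heterozygous and homozygous calls beyond the
    tolerance (the pattern of a truly segregating X/pseudoautosomal locus).
    Anything else is ``OTHER``.
    """
    male_calls = np.asarray(male_calls)
    female_calls = np.asarray(female_calls)
    m_ok = male_calls[male_calls != MISSING]
    f_ok = female_calls[female_calls != MISSING]
    if m_ok.size == 0 or f_ok.size == 0:
        raise ValueError(f"marker {marker!r}: one sex has no non-missing calls")
    n_het = int((m_ok == HET).sum())
    n_hr = int((m_ok == HOM_REF).sum())
    n_ha = int((m_ok == HOM_ALT).sum())
    fem_genotypes = np.unique(f_ok)
    fem_mono = fem_genotypes.size == 1 and fem_genotypes[0] in (HOM_REF, HOM_ALT)
    frac_not_het = (n_hr + n_ha) / m_ok.size
    if fem_mono and frac_not_het <= male_tolerance:
        pattern = SHADOW_Y
    elif fem_mono and n_het > 0 and (n_hr + n_ha) > 0:
        pattern = EXCLUDED_HOM
    else:
        pattern = OTHER
    return PatternCall(
        marker=marker,
        pattern=pattern,
        n_male_het=n_het,
        n_male_hom_ref=n_hr,
        n_male_hom_alt=n_ha,
        n_female_distinct_genotypes=int(fem_genotypes.size),
    )


# ---------------------------------------------------------------------------
# region clustering & annotation
# ---------------------------------------------------------------------------

def _chrom_key(ch: str):
    s = str(ch)
    return (0, int(s)) if s.isdigit() else (1, s)


def cluster_regions(markers: pd.DataFrame, max_gap: int = 1_000_000) -> list[Region]:
    """Single-linkage merge of markers into regions per chromosome.

    Consecutive markers on the same chromosome join one region when their
    gap is <= ``max_gap``; a region spans min..max member position.
    ``markers`` needs columns ``id``, ``chrom``, ``pos``.  Input order is
    irrelevant; empty input yields no regions.
    """
    if len(markers) == 0:
        return []
    df = markers.copy()
    df["_ck"] = df["chrom"].map(_chrom_key)
    df = df.sort_values(["_ck", "pos"], kind="mergesort")
    regions: list[Region] = []
    cur: Region | None = None
    for row in df.itertuples(index=False):
        if cur is not None and str(row.chrom) == cur.chrom and row.pos - cur.end <= max_gap:
            cur.members.append((row.id, int(row.pos)))
            cur.end = int(row.pos)
        else:
            cur = Region(chrom=str(row.chrom), start=int(row.pos), end=int(row.pos),
                         members=[(row.id, int(row.pos))])
            regions.append(cur)
    return regions


def _marker_category(chrom: str, pos: int, ann: AnnotationSet) -> tuple[str, str | None]:
    hits = ann.genes[
        (ann.genes["chrom"].astype(str) == chrom)
        & (ann.genes["start"] <= pos)
        & (pos <= ann.genes["end"])
    ]
    if len(hits):
        return "genic", str(hits["name"].iloc[0])
    length = ann.chrom_lengths[chrom]
    if pos <= ann.telomere_window or pos > length - ann.telomere_window:
        return "telomeric", None
    if ann.centromeres is not None:
        cen = ann.centromeres[ann.centromeres["chrom"].astype(str) == chrom]
        for c in cen.itertuples(index=False):
            if c.start - ann.centromere_window <= pos <= c.end + ann.centromere_window:
                return "centromeric", None
    return "intergenic", None


def annotate_regions(regions: list[Region], ann: AnnotationSet) -> list[Region]:
    """Assign each region the union of its member markers' categories.

    Per marker: gene overlap beats telomere proximity beats centromere
    proximity beats intergenic.  Raises if a region sits on a chromosome
    absent from the lengths table.
    """
    for reg in regions:
        if reg.chrom not in ann.chrom_lengths:
            raise KeyError(f"chromosome {reg.chrom!r} missing from lengths table")
        for _, pos in reg.members:
            cat, gene = _marker_category(reg.chrom, pos, ann)
            reg.categories.add(cat)
            if gene is not None:
                reg.genes.add(gene)
    return regions


# ---------------------------------------------------------------------------
# catalog summary
# ---------------------------------------------------------------------------

def summarize_catalog(
    calls: list[PatternCall],
    markers: pd.DataFrame,
    max_gap: int = 1_000_000,
) -> dict:
    """Headline counts for a classified marker set.

    ``markers`` needs ``id``, ``chrom``, ``pos`` and optionally ``gene``
    (empty string / NaN = no gene).  *Retained* markers are the non-Y
    SHADOW_Y calls; the summary reports pattern counts, chromosome-class
    counts, the genic marker and distinct gene counts among retained
    markers, and the number of regions the retained markers merge into.
    """
    df = markers.set_index("id")
    by_pattern: dict[str, int] = {}
    for c in calls:
        by_pattern[c.pattern] = by_pattern.get(c.pattern, 0) + 1
    call_by_id = {c.marker: c for c in calls}

    def chrom_class(ch) -> str:
        s = str(ch)
        return "Y" if s == "Y" else ("X" if s == "X" else "autosome")

    by_class: dict[str, int] = {"autosome": 0, "X": 0, "Y": 0}
    for c in calls:
        by_class[chrom_class(df.loc[c.marker, "chrom"])] += 1

    retained_ids = [
        c.marker
        for c in calls
        if c.pattern == SHADOW_Y and chrom_class(df.loc[c.marker, "chrom"]) != "Y"
    ]
    retained = df.loc[retained_ids]
    if "gene" in retained.columns:
        genes = retained["gene"].fillna("").astype(str)
        genic = genes[genes != ""]
    else:
        genic = pd.Series(dtype=str)
    regions = cluster_regions(retained.reset_index(), max_gap=max_gap)
    return {
        "n_markers": len(calls),
        "by_pattern": by_pattern,
        "by_chrom_class": by_class,
        "n_excluded": by_pattern.get(EXCLUDED_HOM, 0),
        "n_retained_non_y": len(retained_ids),
        "n_genic_retained": int(len(genic)),
        "n_genes": int(genic.nunique()),
        "n_regions": len(regions),
        "regions": regions,
        "call_by_id": call_by_id,
    }
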