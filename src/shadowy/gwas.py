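"""Sex case-control scan over SNP-array genotypes.

A marker whose probe cross-hybridizes with a diverged, hemizygous
Y-chromosome paralog appears heterozygous in every male and monomorphic in
every female, producing an extreme allele-frequency difference between the
sexes.  A genome-wide association study with sex as the phenotype therefore
flags such "shadow-Y" markers.  This module provides the QC filters
(marker call rate / minor allele frequency, sample call rate), a
from-scratch two-sided Fisher's exact test under the dominant model, and
the Bonferroni-thresholded genome scan.

Genotypes are coded ``0`` (hom-ref), ``1`` (het), ``2`` (hom-alt) and
``-1`` (missing) in a samples x markers int8 array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

MALE, FEMALE = "male", "female"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic genotype calls for a sexed cohort.

    Parameters
    ----------
    markers : pandas.DataFrame
        One row per marker with columns ``id``, ``chrom``, ``pos`` and the
        two allele letters ``ref`` and ``alt`` (``ref`` < ``alt``
        alphabetically by convention of the writers in this package).
    samples : pandas.DataFrame
        One row per sample with columns ``id`` and ``sex`` (``"male"`` or
        ``"female"``).
    calls : numpy.ndarray
        ``int8`` array of shape ``(n_samples, n_markers)`` with codes
        0/1/2/-1.
    """

    markers: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad_sex = set(self.samples["sex"]) - {MALE, FEMALE}
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
        if not np.isin(self.calls, (HOM_REF, HET, HOM_ALT, MISSING)).all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sex_mask(self, sex: str) -> np.ndarray:
        return (self.samples["sex"] == sex).to_numpy()

    def subset(self, marker_mask=None, sample_mask=None) -> "GenotypeMatrix":
        mm = np.ones(self.n_markers, bool) if marker_mask is None else np.asarray(marker_mask)
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask)
        return GenotypeMatrix(
            markers=self.markers.loc[mm].reset_index(drop=True),
            samples=self.samples.loc[sm].reset_index(drop=True),
            calls=self.calls[np.ix_(sm, mm)],
        )


@dataclass
class QCReport:
    """Per-marker / per-sample QC metrics plus the removal list."""

    marker_call_rate: pd.Series | None = None
    marker_maf: pd.Series | None = None
    sample_call_rate: pd.Series | None = None
    removed: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def removed_ids(self) -> list[str]:
        return [rid for rid, _ in self.removed]


@dataclass
class AssociationResult:
    """One marker's 2x2 sex-by-carrier table and exact test outcome.

    ``a``/``b`` are male carriers/non-carriers, ``c``/``d`` female
    carriers/non-carriers, counted over non-missing calls only.
    """

    marker: str
    a: int
    b: int
    c: int
    d: int
    p_value: float
    significant: bool = False
    threshold_used: float = float("nan")
    note: str = ""


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _lchoose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


@lru_cache(maxsize=None)
def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact P for the 2x2 table [[a, b], [c, d]].

    The two-sided P is the sum, over all tables with the observed margins,
    of hypergeometric point probabilities no larger than that of the
    observed table (ties included; no continuity or mid-P adjustment).
    Point probabilities are evaluated in log space so that cohorts of 50+
    samples do not overflow.  A table with a zero margin admits a single
    configuration and returns exactly 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    if (a + b, a, b) > (c + d, c, d):
        # canonical row order makes the sex-swap symmetry exact in floats
        a, b, c, d = c, d, a, b
    n1, n2 = a + b, c + d          # row margins
    k = a + c                      # carrier margin
    n = n1 + n2
    if n == 0:
        raise ValueError("empty table")
    ldenom = _lchoose(n, k)
    lobs = _lchoose(n1, a) + _lchoose(n2, c) - ldenom
    # relative tie tolerance ~1e-7, in log space
    cutoff = lobs + 1e-7
    total = 0.0
    n_tables = n_included = 0
    for x in range(max(0, k - n2), min(n1, k) + 1):
        n_tables += 1
        lp = _lchoose(n1, x) + _lchoose(n2, k - x) - ldenom
        if lp <= cutoff:
            n_included += 1
            total += math.exp(lp)
    if n_included == n_tables:
        return 1.0  # every table is at most as probable: P is 1 by definition
    return min(total, 1.0)


def dominant_fisher(
    male_calls: np.ndarray,
    female_calls: np.ndarray,
    marker: str = "",
    alleles: tuple[str, str] | None = None,
) -> AssociationResult:
    """Dominant-model exact test of sex vs carrier status for one marker.

    A sample is a *carrier* when it bears at least one copy of the minor
    allele, where the minor allele is determined from the pooled
    non-missing calls of both sexes.  At an allele-frequency tie of 0.5 the
    alphabetically first allele of ``alleles`` (``(ref, alt)`` letters) is
    taken as minor; without letters the alt allele is used.  Missing calls
    are dropped per marker (complete-case).
    """
    male_calls = np.asarray(male_calls)
    female_calls = np.asarray(female_calls)
    m_ok = male_calls[male_calls != MISSING]
    f_ok = female_calls[female_calls != MISSING]
    if m_ok.size == 0 or f_ok.size == 0:
        raise ValueError(f"marker {marker!r}: one sex has no non-missing calls")
    pooled = np.concatenate([m_ok, f_ok])
    alt_freq = pooled.sum() / (2 * pooled.size)
    if alt_freq < 0.5:
        minor_is_alt = True
    elif alt_freq > 0.5:
        minor_is_alt = False
    elif alleles is not None:
        ref, alt = alleles
        minor_is_alt = alt < ref
    else:
        minor_is_alt = True
    if minor_is_alt:
        m_car, f_car = (m_ok >= HET).sum(), (f_ok >= HET).sum()
    else:
        m_car, f_car = (m_ok <= HET).sum(), (f_ok <= HET).sum()
    a, b = int(m_car), int(m_ok.size - m_car)
    c, d = int(f_car), int(f_ok.size - f_car)
    p = fisher_exact_two_sided(a, b, c, d)
    return AssociationResult(marker=marker, a=a, b=b, c=c, d=d, p_value=p)


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Family-wise significance threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def marker_qc_metrics(gm: GenotypeMatrix) -> tuple[pd.Series, pd.Series]:
    """Per-marker call rate and minor allele frequency (non-missing calls)."""
    ok = gm.calls != MISSING
    n_ok = ok.sum(axis=0)
    call_rate = n_ok / gm.n_samples
    alt_counts = np.where(ok, gm.calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = np.where(n_ok > 0, alt_counts / (2 * n_ok), np.nan)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    ids = gm.markers["id"]
    return pd.Series(call_rate, index=ids), pd.Series(maf, index=ids)


def filter_markers(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop markers with call rate or MAF below threshold (inclusive keep).

    Markers at exactly the threshold are retained.  A marker with no data
    at all is removed with reason ``"no data"``.
    """
    if gm.n_markers == 0:
        raise ValueError("empty genotype matrix")
    call_rate, maf = marker_qc_metrics(gm)
    removed: list[tuple[str, str]] = []
    keep = np.ones(gm.n_markers, bool)
    for i, mid in enumerate(gm.markers["id"]):
        if call_rate.iloc[i] == 0:
            removed.append((mid, "no data"))
            keep[i] = False
        elif call_rate.iloc[i] < min_call_rate:
            removed.append((mid, f"call rate {call_rate.iloc[i]:.4f} < {min_call_rate}"))
            keep[i] = False
        elif maf.iloc[i] < min_maf:
            removed.append((mid, f"MAF {maf.iloc[i]:.4f} < {min_maf}"))
            keep[i] = False
    report = QCReport(marker_call_rate=call_rate, marker_maf=maf, removed=removed)
    return gm.subset(marker_mask=keep), report


def filter_samples(
    gm: GenotypeMatrix, min_call_rate: float = 0.97
) -> tuple[GenotypeMatrix, QCReport]:
    """Keep samples whose call rate is strictly above ``min_call_rate``."""
    if gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    ok = gm.calls != MISSING
    call_rate = ok.sum(axis=1) / max(gm.n_markers, 1)
    keep = call_rate > min_call_rate
    removed = [
        (sid, f"call rate {cr:.4f} <= {min_call_rate}")
        for sid, cr, k in zip(gm.samples["id"], call_rate, keep)
        if not k
    ]
    if not keep.any():
        raise ValueError("sample QC removed every sample; cohort unusable")
    report = QCReport(
        sample_call_rate=pd.Series(call_rate, index=gm.samples["id"]),
        removed=removed,
    )
    return gm.subset(sample_mask=keep), report


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def run_sex_gwas(
    gm: GenotypeMatrix, alpha: float = 0.05
) -> tuple[list[AssociationResult], pd.DataFrame]:
    """Exact dominant-model test of every marker against sample sex.

    Returns one :class:`AssociationResult` per marker (markers where one
    sex is entirely missing are flagged in ``note`` with ``p_value`` NaN,
    never raised) and a Manhattan-plot table with columns
    ``marker, chrom, pos, p, minus_log10_p, significant``.  Significance is
    ``p <= alpha / n_markers`` (inclusive).
    """
    if gm.n_markers == 0:
        raise ValueError("empty genotype matrix")
    threshold = bonferroni_threshold(alpha, gm.n_markers)
    male = gm.sex_mask(MALE)
    female = gm.sex_mask(FEMALE)
    results: list[AssociationResult] = []
    for j in range(gm.n_markers):
        mid = gm.markers["id"].iloc[j]
        alleles = None
        if {"ref", "alt"}.issubset(gm.markers.columns):
            alleles = (gm.markers["ref"].iloc[j], gm.markers["alt"].iloc[j])
        try:
            res = dominant_fisher(
                gm.calls[male, j], gm.calls[female, j], marker=mid, alleles=alleles
            )
        except ValueError as exc:
            res = AssociationResult(
                marker=mid, a=0, b=0, c=0, d=0, p_value=float("nan"), note=str(exc)
            )
        res = replace(
            res,
            significant=bool(res.p_value <= threshold) if res.note == "" else False,
            threshold_used=threshold,
        )
        results.append(res)
    with np.errstate(divide="ignore"):
        pvals = np.array([r.p_value for r in results])
        mlog = -np.log10(pvals)
    manhattan = pd.DataFrame(
        {
            "marker": gm.markers["id"],
            "chrom": gm.markers["chrom"],
            "pos": gm.markers["pos"],
            "p": pvals,
            "minus_log10_p": mlog,
            "significant": [r.significant for r in results],
        }
    )
    return results, manhattan


def plot_manhattan(manhattan: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """Write a Manhattan plot PNG (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = manhattan.dropna(subset=["minus_log10_p"]).copy()
    chroms = list(dict.fromkeys(df["chrom"]))
    offset, xs, ticks = 0, [], []
    for ch in chroms:
        sub = df[df["chrom"] == ch]
        xs.append(sub["pos"] + offset)
        ticks.append(offset + sub["pos"].max() / 2)
        offset += sub["pos"].max() + 1
    fig, ax = plt.subplots(figsize=(10, 3))
    for i, (ch, x) in enumerate(zip(chroms, xs)):
        sub = df[df["chrom"] == ch]
        ax.scatter(x, sub["minus_log10_p"], s=4, c=f"C{i % 2}")
    thr = bonferroni_threshold(alpha, len(df))
    ax.axhline(-math.log10(thr), color="black", lw=0.8)
    ax.set_xticks(ticks, chroms, fontsize=6)
    ax.set_ylabel(r"$-\log_{10} P$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
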