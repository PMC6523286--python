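"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators, each fully seeded and returning ground truth alongside
the data:

* :func:`simulate_genotypes` — a SNP-array cohort mixing neutral
  Hardy–Weinberg markers, planted shadow-Y markers (every male
  heterozygous, every female the same homozygote), X-linked markers
  (hemizygous males emitted as homozygous calls, as arrays report them)
  and "excluded-type" markers where males mix heterozygous and homozygous
  calls — the pattern of a genuinely segregating X locus.
* :func:`simulate_feature_tracks` — per-window alignment feature
  summaries in which male samples carry a duplication signature (scaled
  depth, elevated heterozygous-site density, discordant-mate and low-mapQ
  fractions) restricted to designated exon windows.
* :func:`simulate_retrocopy_sequences` — a parent gene sequence plus a
  retrocopy born on a chosen branch of a species tree by point
  substitution (and optional 1-bp indels), then inherited and further
  mutated down the descendant branches.

All draws flow from one ``numpy.random.Generator`` per call; no global
random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import HOM_REF, HET, HOM_ALT, MISSING, GenotypeMatrix
from .phylo import EventPlacement, SpeciesTree

NULL = "NULL"
SHADOW_Y = "SHADOW_Y"
X_LINKED = "X_LINKED"
EXCLUDED_TYPE = "EXCLUDED_TYPE"

BASES = np.array(list("ACGT"))
N_AUTOSOMES = 38  # canid karyotype


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Cohort and marker-mix configuration for the array generator.

    Defaults mirror a balanced 25-male / 25-female case-control cohort at
    array scale with a handful of planted shadow-Y markers.
    """

    n_males: int = 25
    n_females: int = 25
    n_null_markers: int = 5000
    n_shadow_markers: int = 10
    n_xlinked_markers: int = 0
    n_excluded_markers: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    excluded_het_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_males, self.n_females, self.n_null_markers,
                  self.n_shadow_markers, self.n_xlinked_markers,
                  self.n_excluded_markers)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class TrackSimConfig:
    """Feature-track generator settings.

    ``het_site_rate`` / ``discordant_frac`` / ``lowmapq_frac`` are the
    *elevated* values applied in male exon windows; the ``background_*``
    fields are the baseline all other sample/window combinations draw
    from.  Depth is Poisson around ``base_depth`` (scaled by
    ``dup_depth_factor`` in male exon windows); het sites are Poisson per
    window and reported per kb.
    """

    n_windows: int = 50
    exon_windows: frozenset[int] = field(default_factory=frozenset)
    base_depth: float = 30.0
    dup_depth_factor: float = 1.5
    het_site_rate: float = 0.004        # per bp, male exon windows
    discordant_frac: float = 0.15       # male exon windows
    lowmapq_frac: float = 0.15          # male exon windows
    background_het_rate: float = 0.001  # per bp
    background_discordant: float = 0.02
    background_lowmapq: float = 0.02
    window_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.exon_windows = frozenset(self.exon_windows)
        if any(not 0 <= w < self.n_windows for w in self.exon_windows):
            raise ValueError("exon_windows must lie in [0, n_windows)")
        if self.dup_depth_factor <= 1:
            raise ValueError("dup_depth_factor must be > 1")
        if self.n_windows < 1 or self.window_size < 1 or self.base_depth < 0:
            raise ValueError("invalid track dimensions")


@dataclass
class SeqSimConfig:
    """Retrocopy sequence-evolution settings.

    ``divergence_rate`` is the per-site substitution probability applied
    on the gain branch itself (a 0.02 rate yields ~98% parent/copy
    identity); ``branch_rate`` is applied again on every branch below the
    gain as the copy is inherited.  ``gain_branch`` is a clade-style
    branch id (comma-joined sorted tip names) or ``None`` for no event.
    """

    parent_length: int = 1000
    divergence_rate: float = 0.02
    indel_rate: float = 0.0
    tree: str = "(urocyon,(vulpes,(lycaon,(latrans,familiaris))));"
    gain_branch: str | None = None
    branch_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.divergence_rate, self.indel_rate, self.branch_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must be in [0, 1)")
        if self.parent_length < 1:
            raise ValueError("parent_length must be positive")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _marker_frame(ids, chroms, positions, rng) -> pd.DataFrame:
    pairs = [rng.choice(4, size=2, replace=False) for _ in ids]
    ref = [BASES[min(p)] for p in pairs]
    alt = [BASES[max(p)] for p in pairs]
    return pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": positions, "ref": ref, "alt": alt}
    )


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Generate a sexed genotype matrix plus per-marker truth labels.

    Marker classes (before missingness):

    * ``NULL`` — Hardy–Weinberg at a MAF uniform in ``maf_range``,
      independent of sex.
    * ``SHADOW_Y`` — every male heterozygous, every female one and the
      same homozygote.
    * ``X_LINKED`` — females Hardy–Weinberg; hemizygous males carry one
      allele, emitted as a homozygous call.
    * ``EXCLUDED_TYPE`` — females monomorphic homozygous; males a mix of
      heterozygous and the opposite homozygote (both guaranteed present
      when there are >= 2 males).

    Missingness is then applied uniformly at ``missing_rate``.  Identical
    config (including seed) reproduces the matrix exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n_s = cfg.n_males + cfg.n_females
    if (cfg.n_shadow_markers or cfg.n_excluded_markers) and (
        cfg.n_males == 0 or cfg.n_females == 0
    ):
        raise ValueError(
            "shadow-Y / excluded patterns are undefined without both sexes"
        )
    samples = pd.DataFrame(
        {
            "id": [f"M{i + 1:03d}" for i in range(cfg.n_males)]
            + [f"F{i + 1:03d}" for i in range(cfg.n_females)],
            "sex": ["male"] * cfg.n_males + ["female"] * cfg.n_females,
        }
    )
    male = slice(0, cfg.n_males)
    female = slice(cfg.n_males, n_s)

    blocks: list[np.ndarray] = []
    ids: list[str] = []
    chroms: list[str] = []
    labels: dict[str, str] = {}
    chrom_cursor: dict[str, int] = {}

    def place(tag: str, idx: int, chrom: str) -> tuple[str, str, int]:
        mid = f"{tag.lower()}{idx + 1:05d}"
        chrom_cursor[chrom] = chrom_cursor.get(chrom, 0) + 1
        return mid, chrom, 1_000_000 + 50_000 * chrom_cursor[chrom]

    positions: list[int] = []

    def add(tag: str, n: int, chrom_fn, geno_fn) -> None:
        for i in range(n):
            chrom = chrom_fn(i)
            mid, chrom, pos = place(tag, i, chrom)
            ids.append(mid)
            chroms.append(chrom)
            positions.append(pos)
            labels[mid] = tag
            blocks.append(geno_fn())

    def null_geno() -> np.ndarray:
        maf = rng.uniform(*cfg.maf_range)
        return rng.binomial(2, maf, size=n_s).astype(np.int8)

    def shadow_geno() -> np.ndarray:
        g = np.empty(n_s, np.int8)
        hom = HOM_REF if rng.random() < 0.5 else HOM_ALT
        g[male] = HET
        g[female] = hom
        return g

    def xlinked_geno() -> np.ndarray:
        maf = rng.uniform(*cfg.maf_range)
        g = np.empty(n_s, np.int8)
        g[male] = np.where(rng.random(cfg.n_males) < maf, HOM_ALT, HOM_REF)
        g[female] = rng.binomial(2, maf, size=cfg.n_females).astype(np.int8)
        return g

    def excluded_geno() -> np.ndarray:
        g = np.empty(n_s, np.int8)
        fem_hom = HOM_REF if rng.random() < 0.5 else HOM_ALT
        other_hom = HOM_ALT if fem_hom == HOM_REF else HOM_REF
        while True:
            het_mask = rng.random(cfg.n_males) < cfg.excluded_het_fraction
            if cfg.n_males < 2 or (het_mask.any() and not het_mask.all()):
                break
        g[male] = np.where(het_mask, HET, other_hom)
        g[female] = fem_hom
        return g

    add(NULL, cfg.n_null_markers, lambda i: str(i % N_AUTOSOMES + 1), null_geno)
    add(SHADOW_Y, cfg.n_shadow_markers,
        lambda i: str(rng.integers(1, N_AUTOSOMES + 1)), shadow_geno)
    add(X_LINKED, cfg.n_xlinked_markers, lambda i: "X", xlinked_geno)
    add(EXCLUDED_TYPE, cfg.n_excluded_markers, lambda i: "X", excluded_geno)

    calls = (
        np.stack(blocks, axis=1) if blocks else np.empty((n_s, 0), np.int8)
    )
    if cfg.missing_rate > 0 and calls.size:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(miss, MISSING, calls).astype(np.int8)
    markers = _marker_frame(ids, chroms, positions, rng)
    return GenotypeMatrix(markers=markers, samples=samples, calls=calls), labels


# ---------------------------------------------------------------------------
# feature tracks
# ---------------------------------------------------------------------------

def simulate_feature_tracks(
    cfg: TrackSimConfig, sex_of_samples: dict[str, str]
) -> pd.DataFrame:
    """Long-format per-sample, per-window alignment feature table.

    Female samples draw every window from the background distributions;
    male samples additionally receive the duplication signature (depth x
    ``dup_depth_factor`` and the elevated rates) in ``exon_windows``.
    Columns: ``sample, sex, window_start, window_end, depth, het_density,
    discordant_frac, lowmapq_frac``.
    """
    bad = {s for s in sex_of_samples.values()} - {"male", "female"}
    if bad:
        raise ValueError(f"unknown sex labels: {sorted(bad)}")
    rng = np.random.default_rng(cfg.seed)
    ws = cfg.window_size
    read_len = 150  # nominal short-read length sizing the fraction draws
    rows = []
    exon = cfg.exon_windows
    for sample, sex in sex_of_samples.items():
        for w in range(cfg.n_windows):
            signal = sex == "male" and w in exon
            lam = cfg.base_depth * (cfg.dup_depth_factor if signal else 1.0)
            # mean per-base coverage of the window: total base coverage is
            # Poisson(lam * ws), so the mean has variance lam / ws
            depth = rng.poisson(lam * ws) / ws
            het_rate = cfg.het_site_rate if signal else cfg.background_het_rate
            het_sites = rng.poisson(het_rate * ws)
            n_reads = max(int(round(depth * ws / read_len)), 1)
            p_dis = cfg.discordant_frac if signal else cfg.background_discordant
            p_mq = cfg.lowmapq_frac if signal else cfg.background_lowmapq
            rows.append(
                {
                    "sample": sample,
                    "sex": sex,
                    "window_start": w * ws + 1,
                    "window_end": (w + 1) * ws,
                    "depth": depth,
                    "het_density": het_sites / (ws / 1000),
                    "discordant_frac": rng.binomial(n_reads, p_dis) / n_reads,
                    "lowmapq_frac": rng.binomial(n_reads, p_mq) / n_reads,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# retrocopy sequences
# ---------------------------------------------------------------------------

def _substitute(seq: str, rate: float, rng) -> tuple[str, list[tuple[int, str, str]]]:
    """Mutate each site with probability ``rate`` to one of the 3 others."""
    arr = np.array(list(seq))
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    changes = []
    for i in hit:
        old = arr[i]
        choices = [b for b in "ACGT" if b != old]
        new = choices[rng.integers(3)]
        arr[i] = new
        changes.append((int(i) + 1, str(old), new))
    return "".join(arr), changes


def _apply_indels(seq: str, rate: float, rng) -> str:
    if rate == 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # 1-bp deletion
        out.append(ch)
        if rate / 2 <= r < rate:
            out.append(str(rng.choice(list("ACGT"))))  # 1-bp insertion
    return "".join(out)


def simulate_retrocopy_sequences(
    cfg: SeqSimConfig,
) -> tuple[str, dict[str, str | None], EventPlacement]:
    """Evolve a retrocopy down a species tree from a single gain.

    Returns ``(parent_seq, copies, truth)`` where ``copies`` maps every
    tip name to its retrocopy sequence, or ``None`` for species that do
    not descend from the gain branch, and ``truth`` is the generating
    :class:`~shadowy.phylo.EventPlacement`.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = SpeciesTree.from_newick(cfg.tree)
    parent = "".join(rng.choice(BASES, size=cfg.parent_length))
    copies: dict[str, str | None] = {t: None for t in tree.tip_names}
    if cfg.gain_branch is None:
        return parent, copies, EventPlacement(gain_branches=(), tree=tree)
    gain_node = tree.node(cfg.gain_branch)  # KeyError if invalid

    birth, _ = _substitute(parent, cfg.divergence_rate, rng)
    birth = _apply_indels(birth, cfg.indel_rate, rng)

    def descend(node, seq: str) -> None:
        if node.is_leaf():
            copies[node.taxon.label] = seq
        for child in node.child_nodes():
            mutated, _ = _substitute(seq, cfg.branch_rate, rng)
            descend(child, mutated)

    descend(gain_node, birth)
    truth = EventPlacement(gain_branches=(cfg.gain_branch,), tree=tree)
    return parent, copies, truth
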