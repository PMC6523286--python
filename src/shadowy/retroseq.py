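"""Sequence-level retrocopy characterization.

Compares a retrocopy against its parent gene: global affine-gap alignment,
percent identity, extraction of diverged sites (the substitutions that
masquerade as SNPs on the array), the shared-polymorphism rule for calling
a retrocopy ancestral across species, and prediction of frameshifts and
premature stops in the copy's reading frame.

A *polymorphism* here is a single-base substitution relative to the parent
sequence, identified by its 1-based position on the ungapped parent and
the substituted base.  Two retrocopies sharing more than 2 such
substitutions are taken to descend from one ancestral insertion (shared
derived states are vanishingly unlikely to recur independently); sharing
exactly 2 or fewer is attributed to chance or homoplasy and does not
support common ancestry.  Indels are reported but never counted toward
the rule.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Seq import Seq

DNA = set("ACGT")


@dataclass
class RetrocopyAlignment:
    """A global parent/copy alignment and its derived site sets.

    ``diverged_sites`` holds ``(parent_pos, parent_base, copy_base)``
    substitution triples with 1-based positions on the ungapped parent;
    ``indels`` holds ``(parent_pos, length, kind)`` with kind ``"ins"``
    (bases present in the copy only) or ``"del"`` (parent bases missing
    from the copy), positioned at the last parent base before the event.
    """

    parent_id: str
    copy_id: str
    aligned_parent: str
    aligned_copy: str
    score: float
    identity: float
    diverged_sites: frozenset[tuple[int, str, str]]
    indels: tuple[tuple[int, int, str], ...]


@dataclass
class SharedPolymorphismReport:
    reference_copy: str
    query_copy: str
    n_shared: int
    n_reference_only: int
    n_query_only: int
    ancestral_call: bool
    shared_indels: int = 0


@dataclass
class OrfPrediction:
    parent_protein_length: int
    copy_protein_length: int
    frameshift_positions: tuple[int, ...]
    truncation_fraction: float


def _check_dna(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = sorted(set(seq) - DNA)
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    if bad:
        raise ValueError(f"{name}: non-DNA characters {bad}")
    return seq


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    aln = Align.PairwiseAligner()
    aln.mode = "global"
    aln.match_score = match
    aln.mismatch_score = mismatch
    aln.open_gap_score = gap_open      # score of the first gap position
    aln.extend_gap_score = gap_extend  # each further gap position
    return aln


def align_global(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
    parent_id: str = "parent",
    copy_id: str = "copy",
) -> RetrocopyAlignment:
    """Optimal global alignment of two DNA sequences with affine gaps.

    A length-L gap scores ``gap_open + gap_extend * (L - 1)``.  Among
    co-optimal alignments the first in the aligner's deterministic
    traversal order is returned, so output is reproducible.
    """
    a = _check_dna(seq_a, parent_id)
    b = _check_dna(seq_b, copy_id)
    result = _aligner(match, mismatch, gap_open, gap_extend).align(a, b)
    best = result[0]
    row_a, row_b = str(best[0]), str(best[1])
    sites, indels = _diff_sites(row_a, row_b)
    ident = percent_identity_rows(row_a, row_b)
    return RetrocopyAlignment(
        parent_id=parent_id,
        copy_id=copy_id,
        aligned_parent=row_a,
        aligned_copy=row_b,
        score=float(best.score),
        identity=ident,
        diverged_sites=frozenset(sites),
        indels=tuple(indels),
    )


def _diff_sites(row_a: str, row_b: str):
    sites = []
    indels = []
    ppos = 0
    gap_len = 0
    gap_kind = None
    for ca, cb in zip(row_a, row_b):
        if ca != "-":
            ppos += 1
        if ca == "-" or cb == "-":
            kind = "ins" if ca == "-" else "del"
            if gap_kind == kind:
                gap_len += 1
            else:
                if gap_kind is not None:
                    indels.append((gap_start, gap_len, gap_kind))
                gap_kind, gap_len = kind, 1
                # last parent base before the event ("ins": gap in parent
                # row, so ppos did not advance; "del": it did)
                gap_start = ppos if kind == "ins" else ppos - 1
            continue
        if gap_kind is not None:
            indels.append((gap_start, gap_len, gap_kind))
            gap_kind, gap_len = None, 0
        if ca != cb:
            sites.append((ppos, ca, cb))
    if gap_kind is not None:
        indels.append((gap_start, gap_len, gap_kind))
    return sites, indels


def percent_identity_rows(
    row_a: str, row_b: str, mode: str = "exclude_gap_columns"
) -> float:
    """Percent identity of an aligned pair, reported to 1 decimal.

    ``exclude_gap_columns`` counts only columns where both rows carry a
    base (the conventional "identity"); ``include_gap_columns`` divides
    by every alignment column instead.
    """
    if mode not in ("exclude_gap_columns", "include_gap_columns"):
        raise ValueError(f"unknown mode {mode!r}")
    matched = counted = 0
    for ca, cb in zip(row_a, row_b):
        gap = ca == "-" or cb == "-"
        if gap and mode == "exclude_gap_columns":
            continue
        counted += 1
        if not gap and ca == cb:
            matched += 1
    if counted == 0:
        raise ValueError("no counted columns: cannot compute identity")
    return round(100.0 * matched / counted, 1)


def percent_identity(aln: RetrocopyAlignment, mode: str = "exclude_gap_columns") -> float:
    return percent_identity_rows(aln.aligned_parent, aln.aligned_copy, mode=mode)


def shared_polymorphisms(
    parent: str,
    reference_copy: str,
    query_copy: str,
    reference_id: str = "reference",
    query_id: str = "query",
    min_identity: float = 50.0,
) -> SharedPolymorphismReport:
    """Count substitutions shared by two retrocopies of one parent.

    Both copies are aligned to the parent; a shared polymorphism is a
    diverged site with identical parent position *and* identical
    substituted base.  The ancestral call requires strictly more than 2
    shared sites.  Copies aligning below ``min_identity`` % to the parent
    raise (likely the wrong parent gene).
    """
    aln_ref = align_global(parent, reference_copy, copy_id=reference_id)
    aln_qry = align_global(parent, query_copy, copy_id=query_id)
    for aln in (aln_ref, aln_qry):
        if aln.identity < min_identity:
            raise ValueError(
                f"{aln.copy_id}: identity {aln.identity}% to parent below "
                f"{min_identity}% — wrong parent sequence?"
            )
    ref_sites = {(pos, alt) for pos, _, alt in aln_ref.diverged_sites}
    qry_sites = {(pos, alt) for pos, _, alt in aln_qry.diverged_sites}
    shared = ref_sites & qry_sites
    shared_indels = len(set(aln_ref.indels) & set(aln_qry.indels))
    return SharedPolymorphismReport(
        reference_copy=reference_id,
        query_copy=query_id,
        n_shared=len(shared),
        n_reference_only=len(ref_sites - qry_sites),
        n_query_only=len(qry_sites - ref_sites),
        ancestral_call=len(shared) > 2,
        shared_indels=shared_indels,
    )


STOPS = {"TAA", "TAG", "TGA"}


def predict_orf_truncation(parent_cds: str, copy_seq: str) -> OrfPrediction:
    """Predict the protein a retrocopy would encode in the parent frame.

    The parent must be a clean CDS (length divisible by 3, ATG start,
    terminal stop).  The copy is aligned to the parent; translation starts
    at the copy base aligned to the parent's first codon position and
    proceeds along the raw copy sequence, so insertions/deletions of
    length not divisible by 3 shift the frame exactly as they would in
    vivo.  The predicted protein length is the number of complete codons
    before the first stop; the truncation fraction is
    ``1 - copy_len / parent_len`` when the copy protein is shorter, else 0.
    """
    parent_cds = _check_dna(parent_cds, "parent_cds")
    if len(parent_cds) % 3 != 0:
        raise ValueError("parent CDS length not divisible by 3")
    if not parent_cds.startswith("ATG"):
        raise ValueError("parent CDS does not start with ATG")
    if parent_cds[-3:] not in STOPS:
        raise ValueError("parent CDS does not end with a stop codon")
    parent_aa = len(parent_cds) // 3 - 1

    aln = align_global(parent_cds, copy_seq)
    # copy offset aligned to parent position 1
    ppos = cpos = 0
    start = None
    for ca, cb in zip(aln.aligned_parent, aln.aligned_copy):
        if ca != "-":
            ppos += 1
        if ppos == 1 and ca != "-":
            if cb == "-":
                break
            start = cpos
            break
        if cb != "-":
            cpos += 1
    if start is None:
        raise ValueError("copy has no base aligned to the parent start codon")

    frame = aln.aligned_copy.replace("-", "")[start:]
    copy_aa = 0
    for i in range(0, len(frame) - len(frame) % 3, 3):
        if frame[i:i + 3] in STOPS:
            break
        copy_aa += 1
    frameshifts = tuple(
        pos for pos, length, _ in aln.indels if length % 3 != 0
    )
    trunc = 1.0 - copy_aa / parent_aa if copy_aa < parent_aa else 0.0
    return OrfPrediction(
        parent_protein_length=parent_aa,
        copy_protein_length=copy_aa,
        frameshift_positions=frameshifts,
        truncation_fraction=trunc,
    )


def translate(cds: str) -> str:
    """Standard-code translation helper (stops as ``*``)."""
    return str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
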