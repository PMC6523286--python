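"""File-format adapters: PLINK ped/map, FASTA, and the TSV contracts.

PLINK dialect: whitespace-delimited ``.ped`` with columns FID, IID, PAT,
MAT, SEX (1 = male, 2 = female), PHENO, then two allele letters per
marker (``0 0`` = missing); ``.map`` with columns chrom, id, cM (written
0), bp.  Coordinates are 1-based throughout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gwas import HOM_REF, HET, HOM_ALT, MISSING, GenotypeMatrix

SEX_CODE = {"male": "1", "female": "2"}
SEX_DECODE = {"1": "male", "2": "female"}


# ---------------------------------------------------------------------------
# PLINK
# ---------------------------------------------------------------------------

def write_plink(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write a genotype matrix as whitespace-delimited ped/map."""
    markers = gm.markers
    with open(map_path, "w") as fh:
        for row in markers.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos}\n")
    ref = markers["ref"].to_numpy()
    alt = markers["alt"].to_numpy()
    pair = {
        HOM_REF: lambda r, a: f"{r} {r}",
        HET: lambda r, a: f"{r} {a}",
        HOM_ALT: lambda r, a: f"{a} {a}",
        MISSING: lambda r, a: "0 0",
    }
    with open(ped_path, "w") as fh:
        for i, srow in enumerate(gm.samples.itertuples(index=False)):
            fields = [srow.id, srow.id, "0", "0", SEX_CODE[srow.sex], "0"]
            fields += [
                pair[int(gm.calls[i, j])](ref[j], alt[j])
                for j in range(gm.n_markers)
            ]
            fh.write(" ".join(fields) + "\n")


def read_plink(ped_path, map_path) -> GenotypeMatrix:
    """Read ped/map into a genotype matrix.

    Allele orientation is recovered from the data: the alphabetically
    first of the (at most two) observed allele letters per marker becomes
    ``ref``.  A monomorphic marker gets ``alt = "N"``.
    """
    markers = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos"], dtype={"chrom": str},
    )[["id", "chrom", "pos"]]
    n_markers = len(markers)
    sample_rows = []
    geno_rows = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts)} fields, expected {6 + 2 * n_markers}"
                )
            if parts[4] not in SEX_DECODE:
                raise ValueError(f"sample {parts[1]}: unknown sex code {parts[4]!r}")
            sample_rows.append({"id": parts[1], "sex": SEX_DECODE[parts[4]]})
            geno_rows.append(parts[6:])
    samples = pd.DataFrame(sample_rows)
    alleles = np.array(geno_rows).reshape(len(samples), n_markers, 2)
    refs, alts = [], []
    calls = np.full((len(samples), n_markers), MISSING, np.int8)
    for j in range(n_markers):
        col = alleles[:, j, :]
        seen = sorted(set(col.ravel()) - {"0"})
        if len(seen) > 2:
            raise ValueError(f"marker {markers['id'].iloc[j]}: >2 alleles {seen}")
        ref = seen[0] if seen else "N"
        alt = seen[1] if len(seen) == 2 else "N"
        refs.append(ref)
        alts.append(alt)
        a1, a2 = col[:, 0], col[:, 1]
        ok = (a1 != "0") & (a2 != "0")
        dose = (a1 == alt).astype(np.int8) + (a2 == alt).astype(np.int8)
        calls[:, j] = np.where(ok, dose, MISSING)
    markers["ref"] = refs
    markers["alt"] = alts
    return GenotypeMatrix(markers=markers, samples=samples, calls=calls)


# ---------------------------------------------------------------------------
# FASTA / trees / tracks / tables
# ---------------------------------------------------------------------------

def write_fasta(records: dict[str, str], path) -> None:
    """Write ``{id: sequence}`` as 60-column wrapped FASTA."""
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()],
        str(path), "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_tracks(tracks: pd.DataFrame, path) -> None:
    tracks.to_csv(path, sep="\t", index=False)


def read_tracks(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_labels(labels: dict[str, str], path) -> None:
    pd.DataFrame(
        {"marker": list(labels), "label": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_truth_labels(path) -> dict[str, str]:
    # keep_default_na: the NULL class tag is data, not a missing value
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return dict(zip(df["marker"], df["label"]))


def write_association_results(results, markers: pd.DataFrame, path) -> None:
    pos = markers.set_index("id")
    rows = []
    for r in results:
        rows.append(
            {
                "marker": r.marker,
                "chrom": pos.loc[r.marker, "chrom"],
                "pos": pos.loc[r.marker, "pos"],
                "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                "p": r.p_value,
                "significant": r.significant,
                "note": r.note,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_presence_profile(path) -> dict[str, str]:
    """Two-column TSV (tip, state) -> presence profile dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["tip", "state"],
                     comment="#")
    return dict(zip(df["tip"].astype(str), df["state"].astype(str)))


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) with optional name column."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
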