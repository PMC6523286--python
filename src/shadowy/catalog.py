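"""Bundled reference data.

* ``canid_sex_markers.tsv`` — the 50 CanineHD-array markers reaching
  genome-wide significance in a sex GWAS of a German shepherd dog cohort,
  with map position and (where applicable) the overlapped gene: the
  classic shadow-Y marker catalog this package's pipeline re-derives on
  synthetic data.  One marker (chrX:60395963, in *PGK1*) shows the
  excluded mixed-male pattern rather than the shadow-Y pattern.
* ``canid_tree.nwk`` — a five-taxon canid species topology (island fox,
  red fox, African wild dog, coyote, domestic dog) used as the default
  tree for retrocopy event placement.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

PGK1_MARKER = ("X", 60395963)


def load_marker_catalog() -> pd.DataFrame:
    """The bundled sex-GWAS marker catalog.

    Columns ``id`` (``chr{chrom}:{pos}``), ``chrom``, ``pos``, ``gene``
    (empty string when intergenic/unannotated) and ``context``.
    """
    path = files("shadowy").joinpath("data/canid_sex_markers.tsv")
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    df["gene"] = df["gene"].fillna("")
    df["context"] = df["context"].fillna("")
    df.insert(0, "id", "chr" + df["chrom"] + ":" + df["pos"].astype(str))
    return df


def load_canid_tree() -> str:
    """Default canid species tree, as a Newick string."""
    return files("shadowy").joinpath("data/canid_tree.nwk").read_text().strip()
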