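"""Packaged reference data.

``minor_ampullate_properties`` is the published per-species table of
minor ampullate fiber tensile properties together with the species-mean
GPG motif percentage of the corresponding MiSp sequences; species with
fiber data from several published sources carry one row per source,
ranked in the order the sources are cited (``source_rank``).

``species_tree_divtimes_synthetic.nwk`` is a SYNTHETIC ultrametric
stand-in for the divergence-time tree used in the contrasts analysis:
the topology follows published spider phylogenies, but the branch
lengths (My) are plausible round numbers, not the unpublished
calibrated estimates — contrast results on it are sensitivity checks,
not reproductions.

GenBank accession FASTA files are not redistributed; place downloaded
accession sequences under a directory of your choice and point the
accession-based helpers at it (default ``data/accessions`` under the
repository root).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import dendropy
import pandas as pd

__all__ = [
    "minor_ampullate_properties",
    "regression_species_data",
    "species_tree",
    "accessions_dir",
]


def _data_path(name: str):
    return resources.files("spidrokit.data") / name


def minor_ampullate_properties() -> pd.DataFrame:
    """Full per-source tensile property / GPG%% table."""
    with resources.as_file(_data_path("minor_ampullate_properties.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def regression_species_data(source_rank: int = 1) -> pd.DataFrame:
    """One row per species with both GPG%% and extensibility.

    Several species have fiber measurements from multiple sources; the
    published regression uses one value per species.  ``source_rank``
    selects which source supplies it (1 = first-listed, the default).
    """
    df = minor_ampullate_properties()
    df = df[df["gpg_percent"].notna() & df["extensibility"].notna()]
    picked = []
    for _, grp in df.groupby("species", sort=False):
        ranks = grp[grp["source_rank"] == source_rank]
        picked.append(ranks.iloc[0] if len(ranks) else grp.iloc[0])
    return pd.DataFrame(picked).reset_index(drop=True)


def species_tree() -> dendropy.Tree:
    """Synthetic divergence-time species tree for the five regression species."""
    with resources.as_file(_data_path("species_tree_divtimes_synthetic.nwk")) as p:
        tree = dendropy.Tree.get(path=str(p), schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def accessions_dir(base: str | Path | None = None) -> Path:
    """Directory where user-downloaded accession FASTA files live."""
    if base is not None:
        return Path(base)
    return Path(__file__).resolve().parents[2] / "data" / "accessions"
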