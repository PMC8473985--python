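"""Shannon diversity of orthogroup abundance.

The community-ecology mapping: each gene subfamily is a "community", each
orthogroup a "site", and the abundance of a site for a species is the number
of that species' gene copies in the orthogroup. Shannon entropy
H' = -sum_i p_i ln p_i (nats) is computed at three levels:

* per orthogroup — over the species' counts within one orthogroup;
* per subfamily x species — over one species' counts across the orthogroups
  of one subfamily;
* pooled per species — over one species' counts across all orthogroups, the
  repertoire-wide diversity compared among species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orthology import OrthogroupSet

__all__ = [
    "AbundanceMatrix",
    "build_abundance_matrix",
    "shannon",
    "orthogroup_diversity",
    "species_diversity",
    "summarize_diversity",
]


@dataclass
class AbundanceMatrix:
    """Orthogroup x species gene-count table, grouped by subfamily.

    ``table`` has one row per orthogroup (index ``subfamily:OGxxxx``), a
    ``subfamily`` column, and one integer count column per species in the
    declared species order.
    """

    table: pd.DataFrame
    species: list[str]

    @property
    def counts(self) -> pd.DataFrame:
        return self.table[self.species]

    @property
    def subfamilies(self) -> list[str]:
        return sorted(self.table["subfamily"].unique())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="orthogroup")

    @classmethod
    def from_tsv(cls, path, species: list[str] | None = None) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="orthogroup")
        df.index.name = None
        sp = species or [c for c in df.columns if c != "subfamily"]
        return cls(table=df, species=list(sp))


def build_abundance_matrix(
    ogsets: list[OrthogroupSet], species: list[str]
) -> AbundanceMatrix:
    """Assemble the orthogroup x species count matrix from orthogroup sets.

    ``ogsets`` must come from distinct subfamilies; any leaf species absent
    from ``species`` is an error. Every cell sum equals the total number of
    genes partitioned.
    """
    seen_subfams = [s.subfamily for s in ogsets]
    if len(set(seen_subfams)) != len(seen_subfams):
        raise ValueError("orthogroup sets must come from distinct subfamilies")
    species = list(species)
    rows = []
    index = []
    for ogset in sorted(ogsets, key=lambda s: (s.subfamily or "")):
        subfam = ogset.subfamily or ""
        ogs = sorted(ogset.orthogroups, key=lambda og: min(og.members))
        for i, og in enumerate(ogs, start=1):
            counts = og.species_counts()
            unknown = set(counts) - set(species)
            if unknown:
                raise ValueError(
                    f"species {sorted(unknown)} present in tree for subfamily "
                    f"{subfam!r} but missing from the declared species list {species}"
                )
            rows.append({"subfamily": subfam, **{sp: counts.get(sp, 0) for sp in species}})
            index.append(f"{subfam}:OG{i:04d}")
    table = pd.DataFrame(rows, index=index, columns=["subfamily"] + species)
    if rows:
        table[species] = table[species].astype(int)
    return AbundanceMatrix(table=table, species=species)


def shannon(counts) -> float:
    """Shannon entropy H' = -sum p_i ln p_i (nats) of a count vector.

    Zero entries contribute nothing; an all-zero or negative vector is an
    error.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0 or np.all(x == 0):
        raise ValueError("shannon is undefined for an empty or all-zero vector")
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    p = x[x > 0]
    p = p / p.sum()
    h = float(-(p * np.log(p)).sum())
    return h if h > 0.0 else 0.0


def orthogroup_diversity(matrix: AbundanceMatrix) -> pd.DataFrame:
    """H' per orthogroup over the species' counts within it (level=orthogroup)."""
    rows = []
    for og_id, row in matrix.counts.iterrows():
        rows.append(
            {
                "orthogroup": og_id,
                "subfamily": matrix.table.loc[og_id, "subfamily"],
                "H": shannon(row.to_numpy()),
            }
        )
    return pd.DataFrame(rows, columns=["orthogroup", "subfamily", "H"])


def species_diversity(matrix: AbundanceMatrix, scope: str = "pooled") -> pd.DataFrame:
    """Per-species H' over orthogroup abundances.

    ``scope="pooled"``: one H' per species across all orthogroups the species
    occupies (rows with zero count for that species are excluded — identical
    value either way since 0 ln 0 := 0, but the exclusion is explicit).
    ``scope="by_subfamily"``: the same computation restricted to each
    subfamily's rows, one H' per (subfamily, species). Species with no genes
    are omitted with a warning.
    """
    if scope not in {"pooled", "by_subfamily"}:
        raise ValueError(f"scope must be 'pooled' or 'by_subfamily', got {scope!r}")
    rows = []
    if scope == "pooled":
        for sp in matrix.species:
            vec = matrix.counts[sp].to_numpy()
            vec = vec[vec > 0]
            if vec.size == 0:
                warnings.warn(f"species {sp!r} has no genes; omitted from diversity table")
                continue
            rows.append({"species": sp, "H": shannon(vec)})
        return pd.DataFrame(rows, columns=["species", "H"])
    for subfam, sub in matrix.table.groupby("subfamily", sort=True):
        for sp in matrix.species:
            vec = sub[sp].to_numpy()
            vec = vec[vec > 0]
            if vec.size == 0:
                warnings.warn(
                    f"species {sp!r} has no genes in subfamily {subfam!r}; omitted"
                )
                continue
            rows.append({"subfamily": subfam, "species": sp, "H": shannon(vec)})
    return pd.DataFrame(rows, columns=["subfamily", "species", "H"])


def summarize_diversity(
    pooled: pd.DataFrame | None = None,
    by_subfamily: pd.DataFrame | None = None,
    per_orthogroup: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Deterministic plot-ready summary of diversity tables.

    Returns mean H' per species (pooled level), mean H' per species across
    subfamilies, mean H' per subfamily across species, and the long tables
    themselves for plotting.
    """
    out: dict[str, pd.DataFrame] = {}
    if pooled is not None and len(pooled):
        out["species_pooled"] = pooled.sort_values("species").reset_index(drop=True)
    if by_subfamily is not None and len(by_subfamily):
        long = by_subfamily.sort_values(["subfamily", "species"]).reset_index(drop=True)
        out["subfamily_by_species"] = long
        out["species_mean_over_subfamilies"] = (
            long.groupby("species", sort=True)["H"].mean().reset_index()
        )
        out["subfamily_mean_over_species"] = (
            long.groupby("subfamily", sort=True)["H"].mean().reset_index()
        )
    if per_orthogroup is not None and len(per_orthogroup):
        out["orthogroup"] = per_orthogroup.sort_values("orthogroup").reset_index(drop=True)
    if not out:
        raise ValueError("no nonempty diversity tables to summarize")
    return out
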