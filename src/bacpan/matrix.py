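"""Gene-family presence/absence container shared by every pipeline stage.

The matrix is stored families x genomes (rows are gene families, columns are
genomes), matching the on-disk binary TSV layout.  Cell values are copy
numbers (occupancy counts); most analyses only consume the boolean presence
view.  Optional per-genome metadata carries the isolation niche
(``marine``/``land``) and a species label.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

NICHE_MARINE = "marine"
NICHE_LAND = "land"


class PresenceAbsenceMatrix:
    """Families x genomes occupancy-count matrix with genome metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by family id with one integer column per genome.
        Values are gene copy numbers (0 = absent).
    metadata
        Optional DataFrame indexed by genome id with columns ``niche``
        and/or ``species``.  Its index must cover all genomes in `counts`.
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame | None = None):
        counts = counts.copy()
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate family ids: {dups[:5]}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate genome ids: {dups[:5]}")
        values = counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("occupancy counts must be non-negative")
        self.counts = counts.astype(int)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)
        if metadata is not None:
            metadata = metadata.copy()
            metadata.index = metadata.index.astype(str)
            missing = set(self.genomes) - set(metadata.index)
            if missing:
                raise ValueError(f"metadata missing genomes: {sorted(missing)[:5]}")
            metadata = metadata.loc[list(self.genomes)]
        self.metadata = metadata

    # -- basic views -------------------------------------------------------
    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_genomes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_families(self) -> int:
        return self.counts.shape[0]

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean families x genomes view."""
        return self.counts > 0

    def occupancy(self) -> pd.Series:
        """Number of genomes each family occupies."""
        return self.presence.sum(axis=1)

    def genome_sizes(self) -> pd.Series:
        """Number of families present in each genome."""
        return self.presence.sum(axis=0)

    # -- metadata helpers --------------------------------------------------
    def niche_of(self, genome: str) -> str | None:
        if self.metadata is None or "niche" not in self.metadata.columns:
            return None
        return self.metadata.loc[genome, "niche"]

    def genomes_in_niche(self, niche: str) -> list[str]:
        if self.metadata is None or "niche" not in self.metadata.columns:
            raise ValueError("matrix has no niche metadata")
        return [g for g in self.genomes if self.metadata.loc[g, "niche"] == niche]

    def genomes_in_species(self, species: str) -> list[str]:
        if self.metadata is None or "species" not in self.metadata.columns:
            raise ValueError("matrix has no species metadata")
        return [g for g in self.genomes if self.metadata.loc[g, "species"] == species]

    def species_labels(self) -> list[str] | None:
        if self.metadata is None or "species" not in self.metadata.columns:
            return None
        return sorted(self.metadata["species"].dropna().unique())

    def subset_genomes(self, genomes: Iterable[str]) -> "PresenceAbsenceMatrix":
        """Restrict to a genome subset, dropping families absent everywhere."""
        genomes = [str(g) for g in genomes]
        unknown = set(genomes) - set(self.genomes)
        if unknown:
            raise KeyError(f"unknown genomes: {sorted(unknown)[:5]}")
        sub = self.counts[genomes]
        sub = sub[sub.sum(axis=1) > 0]
        meta = self.metadata.loc[genomes] if self.metadata is not None else None
        return PresenceAbsenceMatrix(sub, meta)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceAbsenceMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return (
            f"PresenceAbsenceMatrix({self.n_families} families x "
            f"{self.n_genomes} genomes)"
        )


def from_membership(
    members: Mapping[str, Mapping[str, int]],
    genomes: Iterable[str],
    metadata: pd.DataFrame | None = None,
) -> PresenceAbsenceMatrix:
    """Build a matrix from {family: {genome: copy_number}} membership maps."""
    genomes = [str(g) for g in genomes]
    fams = sorted(members)
    data = np.zeros((len(fams), len(genomes)), dtype=int)
    gidx = {g: j for j, g in enumerate(genomes)}
    for i, fam in enumerate(fams):
        for g, c in members[fam].items():
            data[i, gidx[str(g)]] = c
    counts = pd.DataFrame(data, index=fams, columns=genomes)
    return PresenceAbsenceMatrix(counts, metadata)
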