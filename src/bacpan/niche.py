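"""Niche-associated accessory genes and COG enrichment.

Two complementary selections:

* ``shared_dispensable`` — dispensable families carried by *every* genome
  of a group (e.g. all marine isolates), with no condition on the other
  group; candidates for habitat-associated accessory functions.
* ``niche_specific`` — families present in at least a fraction (default
  one third, ceiling rule) of the focal group and essentially absent from
  the background group (default: absent from all of it).

Category enrichment between two family sets uses the two-sided Fisher
exact test on per-category 2x2 tables, optionally Benjamini-Hochberg
corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .matrix import NICHE_LAND, NICHE_MARINE, PresenceAbsenceMatrix
from .profile import CLASS_DISPENSABLE, PanPartition


@dataclass(frozen=True)
class NicheRule:
    """Presence/absence rule for niche-specific families."""

    min_presence_fraction: float = 1.0 / 3.0
    max_background_presence: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_presence_fraction <= 1:
            raise ValueError("min_presence_fraction must be in (0, 1]")
        if self.max_background_presence < 0:
            raise ValueError("max_background_presence must be >= 0")

    def min_count(self, group_size: int) -> int:
        """'At least one third' with a ceiling rule for indivisible sizes."""
        return max(1, math.ceil(self.min_presence_fraction * group_size))


def shared_dispensable(
    matrix: PresenceAbsenceMatrix, part: PanPartition, group: Sequence[str]
) -> set[str]:
    """Dispensable families present in every genome of ``group``.

    No requirement is placed on genomes outside the group (a family shared
    by all marine isolates may also occur in some terrestrial ones).
    """
    group = [str(g) for g in group]
    if not group:
        raise ValueError("empty group")
    unknown = set(group) - set(matrix.genomes)
    if unknown:
        raise ValueError(f"group contains unknown genomes: {sorted(unknown)[:5]}")
    dispensable = part.families_in_class(CLASS_DISPENSABLE)
    presence = matrix.presence[group]
    in_all = presence.all(axis=1)
    return {f for f in presence.index[in_all] if f in dispensable}


def niche_specific(
    matrix: PresenceAbsenceMatrix,
    focal: Sequence[str],
    background: Sequence[str],
    rule: NicheRule | None = None,
) -> set[str]:
    """Families present in >= ceil(fraction * |focal|) focal genomes and in
    at most ``max_background_presence`` background genomes."""
    rule = rule or NicheRule()
    focal = [str(g) for g in focal]
    background = [str(g) for g in background]
    if not focal:
        raise ValueError("empty focal group")
    overlap = set(focal) & set(background)
    if overlap:
        raise ValueError(f"focal and background groups overlap: {sorted(overlap)[:5]}")
    unknown = (set(focal) | set(background)) - set(matrix.genomes)
    if unknown:
        raise ValueError(f"unknown genomes: {sorted(unknown)[:5]}")
    presence = matrix.presence
    n_focal = presence[focal].sum(axis=1)
    n_back = presence[background].sum(axis=1) if background else 0
    ok = (n_focal >= rule.min_count(len(focal))) & (n_back <= rule.max_background_presence)
    return set(presence.index[ok])


@dataclass
class EnrichmentResult:
    category: str
    count_a: int
    total_a: int
    count_b: int
    total_b: int
    odds_ratio: float
    p_value: float
    q_value: float | None
    significant: bool

    @property
    def table(self) -> list[list[int]]:
        return [
            [self.count_a, self.total_a - self.count_a],
            [self.count_b, self.total_b - self.count_b],
        ]


def cog_enrichment(
    set_a: Iterable[str],
    set_b: Iterable[str],
    cog_table: pd.Series,
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[EnrichmentResult]:
    """Per-category two-sided Fisher exact contrast of two family sets.

    Families absent from ``cog_table`` are labelled "unknown".
    ``correction`` is ``None`` (raw p < alpha, the default) or ``"bh"``
    for Benjamini-Hochberg; with correction the significance flag uses
    the adjusted q-value.  Results are sorted by p-value then category.
    """
    set_a, set_b = sorted(set(set_a)), sorted(set(set_b))
    if not set_a and not set_b:
        raise ValueError("both family sets are empty")
    if correction not in (None, "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    cats_a = pd.Series([cog_table.get(f, "unknown") for f in set_a], dtype=object)
    cats_b = pd.Series([cog_table.get(f, "unknown") for f in set_b], dtype=object)
    counts_a = cats_a.value_counts()
    counts_b = cats_b.value_counts()
    categories = sorted(set(counts_a.index) | set(counts_b.index))
    rows = []
    for cat in categories:
        a = int(counts_a.get(cat, 0))
        c = int(counts_b.get(cat, 0))
        table = [[a, len(set_a) - a], [c, len(set_b) - c]]
        odds, p = fisher_exact(table, alternative="two-sided")
        rows.append((cat, a, c, float(odds), float(p)))
    if correction == "bh":
        qvals = multipletests([r[4] for r in rows], method="fdr_bh")[1]
    else:
        qvals = [None] * len(rows)
    results = [
        EnrichmentResult(
            category=cat,
            count_a=a,
            total_a=len(set_a),
            count_b=c,
            total_b=len(set_b),
            odds_ratio=odds,
            p_value=p,
            q_value=None if q is None else float(q),
            significant=(p if q is None else q) < alpha,
        )
        for (cat, a, c, odds, p), q in zip(rows, qvals)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.category))


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "count_a": r.count_a,
                "total_a": r.total_a,
                "count_b": r.count_b,
                "total_b": r.total_b,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# per-species report
# ---------------------------------------------------------------------------

@dataclass
class SpeciesNicheReport:
    species: str
    status: str  # "ok" | "insufficient contrast"
    n_marine: int
    n_land: int
    marine_specific: list[str] = field(default_factory=list)
    land_specific: list[str] = field(default_factory=list)
    marine_cog_counts: dict[str, int] = field(default_factory=dict)
    land_cog_counts: dict[str, int] = field(default_factory=dict)
    enrichment: pd.DataFrame | None = None


def _cog_counts(families: Iterable[str], cog_table: pd.Series) -> dict[str, int]:
    cats = pd.Series([cog_table.get(f, "unknown") for f in sorted(families)], dtype=object)
    return {k: int(v) for k, v in sorted(cats.value_counts().items())}


def niche_report(
    matrix: PresenceAbsenceMatrix,
    part: PanPartition,
    cog_table: pd.Series,
    rule: NicheRule | None = None,
    alpha: float = 0.05,
    correction: str | None = None,
) -> dict[str, SpeciesNicheReport]:
    """Per-species marine/land niche-specific gene report.

    For every species in the matrix metadata, applies ``niche_specific``
    in both directions within that species' genomes and tabulates COG
    distributions plus a marine-vs-land enrichment table.  Species with
    fewer than 2 genomes in either niche are reported with status
    "insufficient contrast" and empty gene sets.
    """
    rule = rule or NicheRule()
    if matrix.metadata is None or "niche" not in matrix.metadata.columns:
        raise ValueError("matrix metadata must provide a niche column")
    species_labels = matrix.species_labels() or ["all"]
    reports: dict[str, SpeciesNicheReport] = {}
    for sp in species_labels:
        genomes = (
            matrix.genomes_in_species(sp) if sp != "all" else list(matrix.genomes)
        )
        marine = [g for g in genomes if matrix.niche_of(g) == NICHE_MARINE]
        land = [g for g in genomes if matrix.niche_of(g) == NICHE_LAND]
        if len(marine) < 2 or len(land) < 2:
            reports[sp] = SpeciesNicheReport(
                species=sp, status="insufficient contrast",
                n_marine=len(marine), n_land=len(land),
            )
            continue
        sub = matrix.subset_genomes(genomes)
        marine_set = niche_specific(sub, marine, land, rule)
        land_set = niche_specific(sub, land, marine, rule)
        enr = None
        if marine_set and land_set:
            enr = enrichment_frame(
                cog_enrichment(marine_set, land_set, cog_table, alpha, correction)
            )
        reports[sp] = SpeciesNicheReport(
            species=sp,
            status="ok",
            n_marine=len(marine),
            n_land=len(land),
            marine_specific=sorted(marine_set),
            land_specific=sorted(land_set),
            marine_cog_counts=_cog_counts(marine_set, cog_table),
            land_cog_counts=_cog_counts(land_set, cog_table),
            enrichment=enr,
        )
    return reports
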