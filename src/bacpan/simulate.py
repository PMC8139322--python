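"""Synthetic pan-genome generator.

Emulates a clade of closely related *Bacillus*-like genomes with a known
pan-genome structure so that every downstream stage (ortholog clustering,
partitioning, rarefaction, niche contrasts, enrichment) can be tested
against planted truth.  The generative model is a deliberately simple
stand-in, not a fitted evolutionary model:

* a random-coalescent (or balanced) genome tree;
* a fixed set of core families present in every genome;
* accessory families gained once at a uniform point on a branch
  (infinitely-many-genes style) and lost independently on descendant
  branches with probability ``1 - exp(-loss_rate * branch_length)``;
* optional planted niche-specific families (present in a stated fraction
  of one niche, absent from the other) and COG category labels drawn from
  a configurable weight vector.

Default parameters are chosen so that a 52-genome simulation has ~2,370
core families and ~3,700 total families per genome, the scale of the
*Bacillus pumilus* species group this package targets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .matrix import NICHE_LAND, NICHE_MARINE, PresenceAbsenceMatrix

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: The 23 single-letter COG functional categories used throughout the
#: package (standard letters minus the rare A/B/X classes), plus "unknown"
#: for families without a functional assignment.
COG_CATEGORIES = (
    "J", "K", "L", "D", "Y", "V", "T", "M", "N", "Z", "W", "U",
    "O", "C", "G", "E", "F", "H", "I", "P", "Q", "R", "S",
)
COG_UNKNOWN = "unknown"

#: Default category weights, loosely shaped like a bacterial COG profile
#: (information storage + metabolism heavy, ~17% unannotated).
DEFAULT_COG_WEIGHTS: dict[str, float] = {
    "J": 0.045, "K": 0.070, "L": 0.040, "D": 0.010, "Y": 0.002,
    "V": 0.020, "T": 0.030, "M": 0.050, "N": 0.020, "Z": 0.003,
    "W": 0.005, "U": 0.015, "O": 0.030, "C": 0.045, "G": 0.060,
    "E": 0.070, "F": 0.020, "H": 0.035, "I": 0.030, "P": 0.055,
    "Q": 0.020, "R": 0.085, "S": 0.075, COG_UNKNOWN: 0.165,
}

#: Default gain/loss rates (events per unit branch length on the coalescent
#: time scale), calibrated by simulation so the default 52-genome,
#: 2,370-core configuration averages ~3,700 families per genome with an
#: open pan-genome.  See docs/methods.md.
DEFAULT_GAIN_RATE = 1655.0
DEFAULT_LOSS_RATE = 1.0


@dataclass
class SimConfig:
    """Parameters of the synthetic pan-genome.

    Defaults emulate the published *B. pumilus* group study conditions:
    52 genomes (20 marine / 32 terrestrial isolates, 3 species),
    ~2,370 core families and ~3,700 genes per genome.
    """

    n_genomes: int = 52
    core_size: int = 2370
    accessory_pool: int = 20000
    gain_rate: float = DEFAULT_GAIN_RATE
    loss_rate: float = DEFAULT_LOSS_RATE
    tree_shape: str = "coalescent"  # "coalescent" | "balanced"
    n_marine: int = 20
    niche_mode: str = "clade"  # "clade" | "shuffled"
    niche_labels: Mapping[str, str] | None = None  # explicit genome -> niche
    n_species: int = 3
    planted_per_niche: int = 20
    planted_presence_fraction: float = 0.5
    cog_category_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COG_WEIGHTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if self.core_size < 0:
            raise ValueError("core_size must be >= 0")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("gain/loss rates must be >= 0")
        if self.tree_shape not in ("coalescent", "balanced"):
            raise ValueError(f"unknown tree_shape {self.tree_shape!r}")
        if self.niche_mode not in ("clade", "shuffled"):
            raise ValueError(f"unknown niche_mode {self.niche_mode!r}")
        if self.niche_labels is None and not 0 <= self.n_marine <= self.n_genomes:
            raise ValueError("n_marine must lie in [0, n_genomes]")
        if not 0 < self.planted_presence_fraction <= 1:
            raise ValueError("planted_presence_fraction must be in (0, 1]")
        total = float(sum(self.cog_category_weights.values()))
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"COG category weights must sum to 1 (got {total})")
        unknown = set(self.cog_category_weights) - set(COG_CATEGORIES) - {COG_UNKNOWN}
        if unknown:
            raise ValueError(f"unknown COG categories in weights: {sorted(unknown)}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated matrix."""

    family_class: dict[str, str]  # family -> core | dispensable | unique
    planted: dict[str, list[str]]  # niche -> planted family ids
    tree_newick: str
    niche: dict[str, str]  # genome -> niche
    species: dict[str, str]  # genome -> species label
    per_genome_gene_counts: dict[str, int]

    def families_in_class(self, cls: str) -> set[str]:
        return {f for f, c in self.family_class.items() if c == cls}

    def class_counts(self) -> dict[str, int]:
        counts = {"core": 0, "dispensable": 0, "unique": 0}
        for c in self.family_class.values():
            counts[c] += 1
        return counts


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def _genome_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def simulate_tree(n_genomes: int, shape: str = "coalescent", seed: int = 0) -> TreeNode:
    """Simulate a rooted binary genome tree with positive branch lengths.

    ``shape="coalescent"`` draws a Kingman coalescent (pairs merge uniformly
    at random, exponential waiting times with rate k(k-1)/2).
    ``shape="balanced"`` builds a deterministic balanced topology with equal
    branch lengths summing to ~1 from root to tip.
    """
    if n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    names = _genome_names(n_genomes)
    if shape == "balanced":
        depth = max(1, math.ceil(math.log2(n_genomes)))
        edge = 1.0 / depth

        def build(leaves: list[str]) -> TreeNode:
            if len(leaves) == 1:
                return TreeNode(name=leaves[0], length=edge)
            half = (len(leaves) + 1) // 2
            node = TreeNode(length=edge, children=[build(leaves[:half]), build(leaves[half:])])
            return node

        root = build(names)
        root.length = None
        return root
    if shape != "coalescent":
        raise ValueError(f"unknown tree shape {shape!r}")

    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=nm) for nm in names]
    heights = [0.0] * n_genomes
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = t - heights[i]
        b.length = t - heights[j]
        parent = TreeNode(children=[a, b])
        nodes = [nd for m, nd in enumerate(nodes) if m not in (i, j)] + [parent]
        heights = [h for m, h in enumerate(heights) if m not in (i, j)] + [t]
    root = nodes[0]
    root.length = None
    return root


def _tip_names(tree: TreeNode) -> list[str]:
    if tree.is_tip():
        return [tree.name]
    return [t.name for t in tree.tips()]


def _split_into_clades(tree: TreeNode, k: int) -> list[list[str]]:
    """Partition the tips into k clades by splitting the largest clade first."""
    groups: list[TreeNode] = [tree]
    while len(groups) < k:
        splittable = [g for g in groups if g.children]
        if not splittable:
            break
        biggest = max(splittable, key=lambda g: (g.count(tips=True), _tip_names(g)[0]))
        groups.remove(biggest)
        groups.extend(biggest.children)
    return [_tip_names(g) for g in groups]


# ---------------------------------------------------------------------------
# gene content
# ---------------------------------------------------------------------------

def _gain_survivors(
    node: TreeNode, residual: float, loss_rate: float, rng: np.random.Generator
) -> list[str]:
    """Leaves that retain a family gained ``residual`` branch units above
    the bottom of ``node``'s branch, with independent exponential loss on
    every descendant branch segment."""
    if loss_rate > 0 and rng.random() < 1.0 - math.exp(-loss_rate * residual):
        return []
    if node.is_tip():
        return [node.name]
    present: list[str] = []
    for child in node.children:
        present.extend(_gain_survivors(child, child.length, loss_rate, rng))
    return present


def _assign_niches(
    tips: list[str], config: SimConfig, rng: np.random.Generator
) -> dict[str, str]:
    if config.niche_labels is not None:
        labels = {str(g): str(v) for g, v in config.niche_labels.items()}
        missing = set(tips) - set(labels)
        if missing:
            raise ValueError(f"niche labels missing genomes: {sorted(missing)[:5]}")
        return {g: labels[g] for g in tips}
    if config.niche_mode == "clade":
        marine = set(tips[: config.n_marine])
    else:  # shuffled null mode
        marine = set(rng.choice(tips, size=config.n_marine, replace=False))
    return {g: (NICHE_MARINE if g in marine else NICHE_LAND) for g in tips}


def simulate_gene_content(
    tree: TreeNode, config: SimConfig
) -> tuple[PresenceAbsenceMatrix, SimTruth]:
    """Evolve gene content along ``tree`` under the single-gain/exponential-
    loss model and plant niche-specific families.

    Returns the presence/absence matrix (with niche and species metadata)
    and the generating truth.  Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_content, rng_niche, rng_plant = [np.random.default_rng(s) for s in ss.spawn(3)]

    tips = _tip_names(tree)
    if config.niche_labels is None and len(tips) != config.n_genomes:
        raise ValueError(
            f"tree has {len(tips)} tips but config.n_genomes={config.n_genomes}"
        )
    niche = _assign_niches(tips, config, rng_niche)
    clades = _split_into_clades(tree, config.n_species)
    species = {}
    for i, clade in enumerate(sorted(clades, key=lambda c: c[0])):
        for g in clade:
            species[g] = f"species_{i + 1}"

    tip_index = {g: i for i, g in enumerate(tips)}
    rows: list[np.ndarray] = []
    fam_ids: list[str] = []

    def add_family(fam: str, present: Sequence[str]) -> None:
        row = np.zeros(len(tips), dtype=int)
        for g in present:
            row[tip_index[g]] = 1
        rows.append(row)
        fam_ids.append(fam)

    core_width = max(5, len(str(config.core_size)))
    for i in range(config.core_size):
        add_family(f"core_{i + 1:0{core_width}d}", tips)

    # accessory gains: preorder over branches, Poisson events per branch
    n_acc = 0
    for node in tree.preorder():
        if node.is_root() or node.length is None:
            continue
        n_events = rng_content.poisson(config.gain_rate * node.length)
        positions = np.sort(rng_content.uniform(0.0, node.length, size=n_events))
        for u in positions:
            if n_acc >= config.accessory_pool:
                break
            present = _gain_survivors(node, node.length - u, config.loss_rate, rng_content)
            if not present:
                continue  # gained then lost before being observed anywhere
            n_acc += 1
            add_family(f"acc_{n_acc:05d}", present)

    # planted niche-specific families
    planted: dict[str, list[str]] = {NICHE_MARINE: [], NICHE_LAND: []}
    for focal in (NICHE_MARINE, NICHE_LAND):
        group = [g for g in tips if niche[g] == focal]
        if not group or config.planted_per_niche == 0:
            continue
        n_present = max(1, math.ceil(config.planted_presence_fraction * len(group)))
        for i in range(config.planted_per_niche):
            fam = f"planted_{focal}_{i + 1:03d}"
            present = sorted(rng_plant.choice(group, size=n_present, replace=False))
            add_family(fam, present)
            planted[focal].append(fam)

    counts = pd.DataFrame(np.vstack(rows), index=fam_ids, columns=tips)
    metadata = pd.DataFrame(
        {"niche": [niche[g] for g in tips], "species": [species[g] for g in tips]},
        index=tips,
    )
    matrix = PresenceAbsenceMatrix(counts, metadata)

    occ = matrix.occupancy()
    n = len(tips)
    family_class = {}
    for fam, k in occ.items():
        if k == n:
            family_class[fam] = "core"  # precedence core > unique when n == 1
        elif k == 1:
            family_class[fam] = "unique"
        else:
            family_class[fam] = "dispensable"

    truth = SimTruth(
        family_class=family_class,
        planted=planted,
        tree_newick=tree_to_newick(tree),
        niche=niche,
        species=species,
        per_genome_gene_counts=matrix.genome_sizes().to_dict(),
    )
    return matrix, truth


def tree_to_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# proteomes
# ---------------------------------------------------------------------------

def emit_proteomes(
    matrix: PresenceAbsenceMatrix,
    identity_within_family: float = 0.9,
    seed: int = 0,
    length_range: tuple[int, int] = (100, 400),
) -> dict[str, dict[str, str]]:
    """Emit per-genome protein sequences with controlled family structure.

    Each family gets a random ancestral sequence (length uniform in
    ``length_range``); each member genome receives an independently
    point-mutated copy.  The per-site mutation probability is
    ``1 - sqrt(identity_within_family)`` so the *expected pairwise*
    identity between two members equals ``identity_within_family``.
    Distinct families use independent random ancestors, so inter-family
    identity stays at random-sequence background (<30%).

    Returns ``{genome: {gene_id: sequence}}``; gene ids are
    ``<family>_<genome>`` (with a ``_copyN`` suffix for copy number > 1).
    """
    if not 0.0 < identity_within_family <= 1.0:
        raise ValueError("identity_within_family must be in (0, 1]")
    if identity_within_family <= 0.5:
        warnings.warn(
            "identity_within_family <= 0.5 is below the default clustering "
            "threshold; families will fragment by design",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    q = 1.0 - math.sqrt(identity_within_family)
    proteomes: dict[str, dict[str, str]] = {g: {} for g in matrix.genomes}
    for fam in matrix.families:
        length = int(rng.integers(lo, hi + 1))
        ancestor = rng.choice(aa, size=length)
        for genome in matrix.genomes:
            copies = int(matrix.counts.at[fam, genome])
            for c in range(copies):
                seq = ancestor.copy()
                if q > 0:
                    mutate = rng.random(length) < q
                    n_mut = int(mutate.sum())
                    if n_mut:
                        # shift by 1..19 positions in the alphabet: always a
                        # different residue, uniform over the other 19
                        idx = np.searchsorted(aa, seq[mutate])
                        shift = rng.integers(1, len(aa), size=n_mut)
                        seq[mutate] = aa[(idx + shift) % len(aa)]
                gene = f"{fam}_{genome}" if copies == 1 else f"{fam}_{genome}_copy{c + 1}"
                proteomes[genome][gene] = seq.tobytes().decode()
    return proteomes


# ---------------------------------------------------------------------------
# COG labels
# ---------------------------------------------------------------------------

def emit_cog_labels(
    matrix: PresenceAbsenceMatrix,
    cog_category_weights: Mapping[str, float] | None = None,
    seed: int = 0,
    skew_families: Sequence[str] | None = None,
    skew_categories: Sequence[str] = ("K",),
    skew_factor: float = 1.0,
) -> pd.Series:
    """Assign one COG category (or "unknown") to every family.

    ``skew_families`` (typically the planted niche-specific set) can be
    labelled from a reweighted distribution in which ``skew_categories``
    weights are multiplied by ``skew_factor`` before renormalisation.
    """
    weights = dict(cog_category_weights or DEFAULT_COG_WEIGHTS)
    cats = list(weights)
    p = np.array([weights[c] for c in cats], dtype=float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    fams = matrix.families
    labels = pd.Series(rng.choice(cats, size=len(fams), p=p), index=fams, name="category")
    if skew_families is not None and skew_factor != 1.0:
        p_skew = np.array(
            [weights[c] * (skew_factor if c in set(skew_categories) else 1.0) for c in cats]
        )
        p_skew = p_skew / p_skew.sum()
        skew_families = [f for f in skew_families if f in labels.index]
        labels.loc[skew_families] = rng.choice(cats, size=len(skew_families), p=p_skew)
    return labels


# ---------------------------------------------------------------------------
# convenience drivers
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    tree: TreeNode
    matrix: PresenceAbsenceMatrix
    truth: SimTruth
    cog_labels: pd.Series


def simulate(config: SimConfig | None = None, with_cog: bool = True) -> SimResult:
    """Run the full generator: tree, gene content, and COG labels."""
    config = config or SimConfig()
    tree = simulate_tree(config.n_genomes, config.tree_shape, config.seed)
    matrix, truth = simulate_gene_content(tree, config)
    cog = (
        emit_cog_labels(matrix, config.cog_category_weights, seed=config.seed + 1)
        if with_cog
        else pd.Series(dtype=object)
    )
    return SimResult(tree=tree, matrix=matrix, truth=truth, cog_labels=cog)


def simulate_ani_matrix(
    species: Mapping[str, str],
    within: float = 97.5,
    between: float = 89.0,
    jitter: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthesize a symmetric ANI matrix from species labels.

    Same-species pairs get ANI ~ ``within``, cross-species pairs
    ~ ``between``, each perturbed by uniform noise of half-width
    ``jitter``; the diagonal is 100.  A convenience stand-in for a real
    ANI computation when exercising species delineation.
    """
    genomes = sorted(species)
    n = len(genomes)
    rng = np.random.default_rng(seed)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            base = within if species[genomes[i]] == species[genomes[j]] else between
            v = base + rng.uniform(-jitter, jitter)
            values[i, j] = values[j, i] = v
    return pd.DataFrame(values, index=genomes, columns=genomes)
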