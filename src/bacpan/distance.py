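"""Genome distances and species delineation.

Implements bottom-s MinHash sketching of canonical nucleotide k-mers with
the Mash distance d = -ln(2j / (1 + j)) / k, Pearson-correlation analysis
of ANI profiles, >= 95%-ANI connected-component species assignment, and
dendrogram/neighbor-joining tree construction.

The k-mer hash is BLAKE2b truncated to 64 bits, keyed with the sketch
seed, so sketches are bit-exact across platforms and Python processes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.cluster import hierarchy
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix as _SkbioDistanceMatrix
from skbio.tree import nj as _skbio_nj

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_NT = frozenset("ACGT")


@dataclass
class Sketch:
    """Bottom-s MinHash sketch of a genome's canonical k-mers."""

    genome_id: str
    k: int
    s: int
    hashes: np.ndarray  # sorted ascending, unique, uint64
    seed: int = 42

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)


@dataclass
class DistanceMatrix:
    """Symmetric genome x genome distance or similarity matrix.

    ``kind`` is one of ``mash`` (distance, zero diagonal), ``ani``
    (percent similarity, 100 diagonal) or ``pearson-corr`` (correlation,
    1.0 diagonal).
    """

    ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def as_distance(self) -> "DistanceMatrix":
        """Convert similarity kinds to a distance in [0, 1]."""
        if self.kind == "mash":
            return self
        if self.kind == "ani":
            return DistanceMatrix(self.ids, (100.0 - self.values) / 100.0, "mash")
        if self.kind == "pearson-corr":
            return DistanceMatrix(self.ids, 1.0 - self.values, "mash")
        raise ValueError(f"unknown kind {self.kind!r}")


def _hash_kmer(kmer: bytes, seed: int) -> int:
    h = hashlib.blake2b(kmer, digest_size=8, key=seed.to_bytes(8, "little"))
    return int.from_bytes(h.digest(), "little")


def _canonical_kmers(sequences: list[str], k: int):
    """Yield canonical (lexicographic strand-min) k-mers, skipping any
    window containing a non-ACGT character."""
    for seq in sequences:
        seq = seq.upper()
        rc = seq.translate(_COMPLEMENT)[::-1]
        L = len(seq)
        for i in range(L - k + 1):
            fwd = seq[i : i + k]
            if not _VALID_NT.issuperset(fwd):
                continue
            rev = rc[L - k - i : L - i]
            yield fwd if fwd <= rev else rev


def _load_sequences(genome) -> tuple[str, list[str]]:
    def _is_path(x) -> bool:
        try:
            return Path(x).exists()
        except OSError:
            return False

    if isinstance(genome, Path) or (isinstance(genome, str) and _is_path(genome)):
        records = list(SeqIO.parse(str(genome), "fasta"))
        return Path(str(genome)).stem, [str(r.seq) for r in records]
    if isinstance(genome, str):
        return "genome", [genome]
    return "genome", [str(s) for s in genome]


def sketch_genome(genome, k: int = 21, s: int = 1000, seed: int = 42,
                  genome_id: str | None = None) -> Sketch:
    """Sketch a genome (sequence string, list of contigs, or FASTA path).

    Keeps the ``s`` smallest distinct 64-bit hashes of the canonical
    k-mers.  Deterministic given ``seed``.
    """
    inferred_id, sequences = _load_sequences(genome)
    if not sequences or max(len(x) for x in sequences) < k:
        raise ValueError(f"sequence shorter than k={k}")
    hashes = {_hash_kmer(km.encode(), seed) for km in _canonical_kmers(sequences, k)}
    if not hashes:
        raise ValueError("no valid k-mers (non-ACGT content?)")
    bottom = np.sort(np.fromiter(hashes, dtype=np.uint64))[:s]
    return Sketch(genome_id or inferred_id, k=k, s=s, hashes=bottom, seed=seed)


def sketch_jaccard(sk1: Sketch, sk2: Sketch) -> float:
    """MinHash Jaccard estimate from the merged bottom-s sketch."""
    if sk1.k != sk2.k:
        raise ValueError(f"mismatched k: {sk1.k} vs {sk2.k}")
    if sk1.seed != sk2.seed:
        raise ValueError("sketches built with different hash seeds")
    s = min(sk1.s, sk2.s)
    union = np.union1d(sk1.hashes, sk2.hashes)[:s]
    if len(union) == 0:
        return 0.0
    shared = np.intersect1d(
        np.intersect1d(union, sk1.hashes, assume_unique=True),
        sk2.hashes,
        assume_unique=True,
    )
    return len(shared) / len(union)


def mash_distance(sk1: Sketch, sk2: Sketch) -> float:
    """Mash distance d = -ln(2j/(1+j))/k; capped at 1 when j = 0."""
    j = sketch_jaccard(sk1, sk2)
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    d = -np.log(2.0 * j / (1.0 + j)) / sk1.k
    return float(min(d, 1.0))


def mash_distance_matrix(sketches: list[Sketch]) -> DistanceMatrix:
    ids = [sk.genome_id for sk in sketches]
    n = len(sketches)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = mash_distance(sketches[i], sketches[j])
    return DistanceMatrix(ids, values, "mash")


# ---------------------------------------------------------------------------
# ANI analyses
# ---------------------------------------------------------------------------

def _validate_ani(ani: pd.DataFrame) -> pd.DataFrame:
    if ani.shape[0] != ani.shape[1]:
        raise ValueError("ANI matrix must be square")
    if list(ani.index) != list(ani.columns):
        raise ValueError("ANI matrix row and column labels differ")
    if ani.isna().to_numpy().any():
        raise ValueError("ANI matrix contains NaN entries")
    values = ani.to_numpy(dtype=float)
    if not np.allclose(values, values.T):
        raise ValueError("ANI matrix is not symmetric")
    ani = ani.astype(float).copy()
    np.fill_diagonal(ani.values, 100.0)
    return ani


def ani_correlation(ani: pd.DataFrame) -> DistanceMatrix:
    """Pearson correlation between genomes' ANI profiles (matrix rows).

    Rows are correlated in full, with self-entries fixed at 100, the
    common corrplot convention.
    """
    ani = _validate_ani(ani)
    corr = np.corrcoef(ani.to_numpy())
    return DistanceMatrix(list(ani.index), corr, "pearson-corr")


@dataclass
class SpeciesAssignment:
    """Genome -> species cluster from ANI connected components."""

    assignments: dict[str, str]
    threshold: float

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, sp in self.assignments.items():
            out.setdefault(sp, []).append(g)
        return {sp: sorted(gs) for sp, gs in out.items()}

    @property
    def n_species(self) -> int:
        return len(set(self.assignments.values()))


def assign_species(ani: pd.DataFrame, threshold: float = 95.0) -> SpeciesAssignment:
    """Species = connected components of the graph with edges ANI >= threshold.

    Transitive: a chain A-B, B-C above threshold joins A and C even if
    their direct ANI falls below it.  Cluster labels are ``species_i``
    numbered by each component's lexicographically smallest genome.
    """
    ani = _validate_ani(ani)
    genomes = [str(g) for g in ani.index]
    adj = csr_matrix((ani.to_numpy() >= threshold).astype(int))
    n_comp, labels = connected_components(adj, directed=False)
    comps: dict[int, list[str]] = {}
    for g, lab in zip(genomes, labels):
        comps.setdefault(int(lab), []).append(g)
    ordered = sorted(comps.values(), key=lambda gs: min(gs))
    assignments = {}
    for i, gs in enumerate(ordered):
        for g in gs:
            assignments[g] = f"species_{i + 1}"
    return SpeciesAssignment(assignments, threshold)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def _linkage_to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _linkage_to_newick(node.get_left(), labels)
    right = _linkage_to_newick(node.get_right(), labels)
    h = node.dist / 2.0
    lh = node.get_left().dist / 2.0
    rh = node.get_right().dist / 2.0
    return f"({left}:{h - lh:.10g},{right}:{h - rh:.10g})"


def hierarchical_tree(dm: DistanceMatrix, linkage: str = "average") -> str:
    """Agglomerative dendrogram (UPGMA for ``average`` linkage) in newick.

    Similarity kinds are converted to distances first.  Labels are sorted
    before clustering so the result is invariant to input ordering; branch
    lengths are merge-height differences (heights = half the cophenetic
    distance), so an ultrametric input is reproduced exactly.
    """
    dist = dm.as_distance()
    if np.isnan(dist.values).any():
        raise ValueError("distance matrix contains NaN")
    order = np.argsort(dist.ids)
    labels = [dist.ids[i] for i in order]
    values = dist.values[np.ix_(order, order)].copy()
    np.fill_diagonal(values, 0.0)
    condensed = squareform(values, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    root = hierarchy.to_tree(Z)
    return _linkage_to_newick(root, labels) + ";"


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree (newick); negative branch lengths clamped to 0."""
    dist = dm.as_distance()
    if len(dist.ids) < 3:
        raise ValueError("need at least 3 genomes for a tree")
    if np.isnan(dist.values).any():
        raise ValueError("distance matrix contains NaN")
    values = dist.values.copy()
    np.fill_diagonal(values, 0.0)
    tree = _skbio_nj(_SkbioDistanceMatrix(values, ids=dist.ids), neg_as_zero=True)
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
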