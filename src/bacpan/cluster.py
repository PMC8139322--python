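"""Ortholog family construction from proteomes.

Gene families are built the classic way: all-against-all protein alignment,
edges for inter-genome bidirectional best hits (BBH) and intra-genome
in-paralog hits that pass a 50% identity / 50% coverage regime, then
connected components of the hit graph.  Alignments are semi-global
(free end gaps) with BLOSUM62 scores and affine gaps (open 11, extend 1);
identity is computed over aligned columns excluding end gaps, and coverage
is the aligned span divided by each sequence's full length, both sequences
having to pass the coverage floor.

An optional shared k-mer prefilter skips clearly unrelated pairs; it is
validated in the test suite against exhaustive alignment so that no pair
that would pass the default thresholds is ever skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from skbio import DistanceMatrix as _SkbioDistanceMatrix
from skbio.tree import nj as _skbio_nj

from .matrix import PresenceAbsenceMatrix, from_membership

_VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class ClusterParams:
    """Similarity thresholds for family construction.

    ``score_min`` is a raw-alignment-score floor standing in for a
    database-size-dependent E-value cut-off; the default of 0 accepts any
    pair that clears the identity and coverage floors.
    ``prefilter_k``/``prefilter_min_shared``: a candidate pair is aligned
    only if the two sequences share at least ``prefilter_min_shared``
    k-mers (set ``prefilter_k`` to ``None`` to align every pair).
    """

    identity_min: float = 0.50
    coverage_min: float = 0.50
    score_min: float = 0.0
    prefilter_k: int | None = 4
    prefilter_min_shared: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.identity_min <= 1:
            raise ValueError("identity_min must be in (0, 1]")
        if not 0 < self.coverage_min <= 1:
            raise ValueError("coverage_min must be in (0, 1]")


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    identity: float
    query_coverage: float
    subject_coverage: float
    score: float


@dataclass
class GeneFamily:
    """An orthologous cluster: genome id -> member gene ids."""

    family_id: str
    members: dict[str, list[str]]
    cog_category: str | None = None

    @property
    def genomes(self) -> list[str]:
        return sorted(self.members)

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.members.values())

    def copy_number(self, genome: str) -> int:
        return len(self.members.get(genome, []))

    def is_single_copy_in(self, genomes) -> bool:
        return all(self.copy_number(g) == 1 for g in genomes)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # free end gaps -> semi-global ("glocal") alignment
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def _validate_protein(seq: str, label: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{label} is empty")
    bad = set(seq) - _VALID_AA
    if bad:
        raise ValueError(f"{label} contains non-amino-acid characters: {sorted(bad)}")


def _align_stats(a: str, b: str) -> tuple[float, float, float, float, int] | None:
    """Best semi-global alignment of a (target) vs b (query).

    Returns (identity, coverage_a, coverage_b, score, aligned_columns)
    computed over the aligned span (end gaps excluded), or None for an
    empty alignment.
    """
    aln = _ALIGNER.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return None
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    diag = 0
    matches = 0
    for (s_a, e_a), (s_b, e_b) in zip(blocks_a, blocks_b):
        diag += e_a - s_a
        for x, y in zip(a[s_a:e_a], b[s_b:e_b]):
            if x == y:
                matches += 1
    columns = span_a + span_b - diag
    identity = matches / columns
    return identity, span_a / len(a), span_b / len(b), float(aln.score), columns


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def pairwise_similarity(a: str, b: str, params: ClusterParams | None = None) -> SimilarityHit | None:
    """Align two protein sequences; return a hit if it passes thresholds.

    The hit is returned only if identity >= ``identity_min``, both
    coverages >= ``coverage_min`` and score >= ``score_min``; otherwise
    ``None``.  The computation is symmetric: the pair is canonically
    ordered internally, so (a, b) and (b, a) agree on identity/score with
    coverages swapped.
    """
    params = params or ClusterParams()
    _validate_protein(a, "first sequence")
    _validate_protein(b, "second sequence")
    swapped = (len(b), b) < (len(a), a)
    first, second = (b, a) if swapped else (a, b)
    stats = _align_stats(first, second)
    if stats is None:
        return None
    identity, cov_1, cov_2, score, _ = stats
    if swapped:
        cov_1, cov_2 = cov_2, cov_1
    if identity < params.identity_min:
        return None
    if min(cov_1, cov_2) < params.coverage_min:
        return None
    if score < params.score_min:
        return None
    return SimilarityHit("query", "subject", identity, cov_1, cov_2, score)


def _all_hits(
    proteomes: Mapping[str, Mapping[str, str]], params: ClusterParams
) -> dict[tuple[tuple[str, str], tuple[str, str]], SimilarityHit]:
    """All passing pairwise hits, keyed by ((genome, gene), (genome, gene))."""
    genes: list[tuple[str, str, str]] = []  # (genome, gene, seq)
    for genome in sorted(proteomes):
        prot = proteomes[genome]
        if not prot:
            raise ValueError(f"empty proteome for genome {genome!r}")
        for gene in sorted(prot):
            seq = prot[gene]
            _validate_protein(seq, f"{genome}|{gene}")
            genes.append((genome, gene, seq))

    use_filter = params.prefilter_k is not None
    kmers = (
        [_kmer_set(seq, params.prefilter_k) for _, _, seq in genes] if use_filter else None
    )
    hits: dict[tuple[tuple[str, str], tuple[str, str]], SimilarityHit] = {}
    for i in range(len(genes)):
        gi, ni, si = genes[i]
        for j in range(i + 1, len(genes)):
            gj, nj_, sj = genes[j]
            if use_filter and min(len(si), len(sj)) > 4 * params.prefilter_k:
                shared = len(kmers[i] & kmers[j])
                if shared < params.prefilter_min_shared:
                    continue
            hit = pairwise_similarity(si, sj, params)
            if hit is not None:
                hits[((gi, ni), (gj, nj_))] = hit
    return hits


def build_families(
    proteomes: Mapping[str, Mapping[str, str]], params: ClusterParams | None = None
) -> tuple[list[GeneFamily], PresenceAbsenceMatrix]:
    """Cluster genes into families over >= 2 genomes.

    Edges of the clustering graph are (a) inter-genome bidirectional best
    hits among passing hits (ties on best score all kept) and (b)
    intra-genome passing hits (in-paralogs).  Families are the connected
    components; unmatched genes become singleton families.  Family ids are
    assigned in lexicographic order of (smallest genome id, smallest gene
    id) for reproducibility.
    """
    params = params or ClusterParams()
    if len(proteomes) < 2:
        raise ValueError("need at least 2 genomes")
    hits = _all_hits(proteomes, params)

    # best inter-genome score per (gene, other genome)
    best: dict[tuple[tuple[str, str], str], float] = {}
    for ((g1, n1), (g2, n2)), hit in hits.items():
        if g1 == g2:
            continue
        a, b = (g1, n1), (g2, n2)
        best[(a, g2)] = max(best.get((a, g2), -np.inf), hit.score)
        best[(b, g1)] = max(best.get((b, g1), -np.inf), hit.score)

    graph = nx.Graph()
    for genome in proteomes:
        for gene in proteomes[genome]:
            graph.add_node((genome, gene))
    for ((g1, n1), (g2, n2)), hit in hits.items():
        a, b = (g1, n1), (g2, n2)
        if g1 == g2:
            graph.add_edge(a, b)  # in-paralogs
        elif hit.score >= best[(a, g2)] and hit.score >= best[(b, g1)]:
            graph.add_edge(a, b)  # bidirectional best hit (ties kept)

    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    width = max(5, len(str(len(components))))
    families = []
    for idx, comp in enumerate(components):
        members: dict[str, list[str]] = {}
        for genome, gene in sorted(comp):
            members.setdefault(genome, []).append(gene)
        families.append(GeneFamily(f"fam_{idx + 1:0{width}d}", members))
    matrix = from_membership(
        {f.family_id: {g: f.copy_number(g) for g in f.members} for f in families},
        genomes=sorted(proteomes),
    )
    return families, matrix


def single_copy_core(families: list[GeneFamily], genome_list: list[str]) -> list[GeneFamily]:
    """Families with exactly one member in every genome of ``genome_list``."""
    return [f for f in families if f.is_single_copy_in(genome_list)]


def concat_distance_tree(
    families: list[GeneFamily], proteomes: Mapping[str, Mapping[str, str]]
) -> str:
    """Neighbor-joining tree from concatenated single-copy core families.

    The distance between two genomes is the pooled per-site mismatch
    fraction over the aligned columns of their members across all
    families (a p-distance on the concatenated alignment).  Stands in for
    a maximum-likelihood phylogeny.  Returns a newick string.
    """
    genomes = sorted(proteomes)
    if len(genomes) < 3:
        raise ValueError("need at least 3 genomes for a tree")
    core = single_copy_core(families, genomes)
    if not core:
        raise ValueError("no single-copy core families")
    n = len(genomes)
    mism = np.zeros((n, n))
    cols = np.zeros((n, n))
    for fam in core:
        seqs = [proteomes[g][fam.members[g][0]] for g in genomes]
        for i in range(n):
            for j in range(i + 1, n):
                stats = _align_stats(seqs[i], seqs[j])
                if stats is None:
                    continue
                identity, _, _, _, ncol = stats
                mism[i, j] += (1.0 - identity) * ncol
                cols[i, j] += ncol
    with np.errstate(invalid="ignore"):
        dist = np.where(cols > 0, mism / np.maximum(cols, 1), 0.0)
    dist = dist + dist.T
    dm = _SkbioDistanceMatrix(dist, ids=genomes)
    tree = _skbio_nj(dm, neg_as_zero=True)
    from io import StringIO

    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
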