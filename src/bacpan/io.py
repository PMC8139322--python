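"""Readers and writers for the interchange formats.

All tabular formats are plain text.  Writers can prepend ``#``-prefixed
provenance comment lines (seed and configuration hash); readers skip
them, so every writer/reader pair round-trips losslessly.

Presence/absence dialects:

* ``binary-tsv`` — rows are families, columns genomes, integer copy
  numbers (0 = absent).
* ``roary-csv`` — a gene_presence_absence.csv-style table: a ``Gene``
  column, descriptive columns, then one column per genome whose cells
  hold comma-separated member gene ids (copy number = member count).
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .matrix import PresenceAbsenceMatrix
from .profile import CurveFit, PanPartition, PanProfile
from .simulate import SimTruth

_ROARY_META_COLUMNS = [
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
]


def _strip_comments(path: Path) -> list[tuple[int, str]]:
    """Non-comment lines of a file as (line_number, text) pairs."""
    lines = Path(path).read_text().splitlines()
    return [(i + 1, ln) for i, ln in enumerate(lines) if ln and not ln.startswith("#")]


def _provenance_lines(provenance: Mapping | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in provenance.items())


# ---------------------------------------------------------------------------
# presence/absence
# ---------------------------------------------------------------------------

def read_presence_absence(
    path, dialect: str = "binary-tsv", metadata: pd.DataFrame | None = None
) -> PresenceAbsenceMatrix:
    """Read a presence/absence matrix in ``binary-tsv`` or ``roary-csv``."""
    path = Path(path)
    if dialect == "binary-tsv":
        return _read_binary_tsv(path, metadata)
    if dialect == "roary-csv":
        return _read_roary_csv(path, metadata)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_binary_tsv(path: Path, metadata) -> PresenceAbsenceMatrix:
    rows = _strip_comments(path)
    if not rows:
        raise ValueError(f"{path}: empty file")
    header_no, header = rows[0]
    cols = header.split("\t")
    if cols[0] not in ("family", "Gene", ""):
        raise ValueError(f"{path}:{header_no}: first header cell must be 'family'")
    genomes = cols[1:]
    fam_ids, data = [], []
    for lineno, line in rows[1:]:
        cells = line.split("\t")
        if len(cells) != len(cols):
            raise ValueError(
                f"{path}:{lineno}: expected {len(cols)} columns, got {len(cells)}"
            )
        fam_ids.append(cells[0])
        try:
            data.append([int(c) for c in cells[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer cell ({exc})") from None
    counts = pd.DataFrame(data, index=fam_ids, columns=genomes, dtype=int)
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        lineno = fam_ids.index(dup) + 2
        raise ValueError(f"{path}: duplicate family id {dup!r} (line ~{lineno})")
    return PresenceAbsenceMatrix(counts, metadata)


def write_presence_absence(
    matrix: PresenceAbsenceMatrix,
    path,
    dialect: str = "binary-tsv",
    provenance: Mapping | None = None,
) -> None:
    path = Path(path)
    if dialect == "binary-tsv":
        with open(path, "w") as fh:
            fh.write(_provenance_lines(provenance))
            fh.write("family\t" + "\t".join(matrix.genomes) + "\n")
            for fam in matrix.families:
                row = matrix.counts.loc[fam]
                fh.write(fam + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
        return
    if dialect == "roary-csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_ROARY_META_COLUMNS + matrix.genomes)
            for fam in matrix.families:
                row = matrix.counts.loc[fam]
                n_iso = int((row > 0).sum())
                n_seq = int(row.sum())
                avg = n_seq / n_iso if n_iso else 0.0
                cells = [
                    ",".join(f"{fam}_{g}_{i + 1}" for i in range(int(row[g])))
                    for g in matrix.genomes
                ]
                writer.writerow([fam, "", "", n_iso, n_seq, f"{avg:.2f}"] + cells)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_roary_csv(path: Path, metadata) -> PresenceAbsenceMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(ln for ln in fh if not ln.startswith("#"))
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if header[0] != "Gene":
            raise ValueError(f"{path}:1: Roary dialect requires a 'Gene' first column")
        meta_cols = [c for c in header if c in _ROARY_META_COLUMNS]
        genomes = header[len(meta_cols):]
        fam_ids, data = [], []
        for lineno, cells in enumerate(reader, start=2):
            if len(cells) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            fam_ids.append(cells[0])
            data.append(
                [len([m for m in cell.split(",") if m.strip()]) if cell.strip() else 0
                 for cell in cells[len(meta_cols):]]
            )
    counts = pd.DataFrame(data, index=fam_ids, columns=genomes, dtype=int)
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate family id {dup!r}")
    return PresenceAbsenceMatrix(counts, metadata)


# ---------------------------------------------------------------------------
# simple tables
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Genome metadata TSV with columns genome, niche[, species]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "genome" not in df.columns:
        raise ValueError(f"{path}: metadata must have a 'genome' column")
    if df["genome"].duplicated().any():
        dup = df["genome"][df["genome"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate genome id {dup!r}")
    return df.set_index("genome")


def write_metadata(meta: pd.DataFrame, path, provenance: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        meta.rename_axis("genome").to_csv(fh, sep="\t")


def read_cog_table(path) -> pd.Series:
    """Family -> COG category TSV (columns family, category)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["family", "category"]:
        raise ValueError(f"{path}: expected columns 'family', 'category'")
    if df["family"].duplicated().any():
        raise ValueError(f"{path}: duplicate family ids")
    return df.set_index("family")["category"]


def write_cog_table(cog: pd.Series, path, provenance: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        cog.rename("category").rename_axis("family").to_csv(fh, sep="\t")


def read_ani_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_ani_matrix(ani: pd.DataFrame, path, provenance: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        ani.to_csv(fh, sep="\t")


def write_proteomes(proteomes: Mapping[str, Mapping[str, str]], out_dir) -> list[Path]:
    """One protein FASTA per genome; headers are ``<genome>|<gene>``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for genome in sorted(proteomes):
        path = out_dir / f"{genome}.faa"
        with open(path, "w") as fh:
            for gene in sorted(proteomes[genome]):
                seq = proteomes[genome][gene]
                fh.write(f">{genome}|{gene}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        paths.append(path)
    return paths


def read_proteomes(directory, pattern: str = "*.faa") -> dict[str, dict[str, str]]:
    """Load per-genome protein FASTAs from a directory.

    The genome id is the file stem; gene ids are the header text after a
    ``<genome>|`` prefix (or the full header if no prefix).
    """
    from Bio import SeqIO

    directory = Path(directory)
    proteomes: dict[str, dict[str, str]] = {}
    for path in sorted(directory.glob(pattern)):
        genome = path.stem
        genes = {}
        for record in SeqIO.parse(str(path), "fasta"):
            name = record.id
            if name.startswith(f"{genome}|"):
                name = name[len(genome) + 1 :]
            genes[name] = str(record.seq)
        if not genes:
            raise ValueError(f"empty proteome file for genome {genome!r}: {path}")
        proteomes[genome] = genes
    if not proteomes:
        raise ValueError(f"no proteome files matching {pattern!r} in {directory}")
    return proteomes


# ---------------------------------------------------------------------------
# JSON artifacts
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(payload: dict, path, provenance: Mapping | None = None) -> None:
    payload = dict(payload)
    if provenance:
        payload["_provenance"] = dict(provenance)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonable) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def truth_to_json(truth: SimTruth) -> dict:
    return dataclasses.asdict(truth)


def truth_from_json(payload: dict) -> SimTruth:
    return SimTruth(**{k: payload[k] for k in (
        "family_class", "planted", "tree_newick", "niche", "species",
        "per_genome_gene_counts")})


def profile_to_json(profile: PanProfile) -> dict:
    return {
        "n": profile.n.tolist(),
        "pan": profile.pan.tolist(),
        "core": profile.core.tolist(),
        "new": profile.new.tolist(),
        "mean_pan": profile.mean_pan.tolist(),
        "mean_core": profile.mean_core.tolist(),
        "mean_new": profile.mean_new.tolist(),
        "n_permutations": profile.n_permutations,
        "seed": profile.seed,
        "summary": profile.summary,
    }


def profile_from_json(payload: dict) -> PanProfile:
    return PanProfile(
        n=np.asarray(payload["n"]),
        pan=np.asarray(payload["pan"]),
        core=np.asarray(payload["core"]),
        new=np.asarray(payload["new"]),
        n_permutations=payload["n_permutations"],
        seed=payload["seed"],
        summary=payload.get("summary", "mean"),
    )


def curvefit_to_json(fit: CurveFit) -> dict:
    return {
        "model": fit.model,
        "params": fit.params,
        "r_squared": fit.r_squared,
        "success": fit.success,
        "message": fit.message,
        "is_open": fit.is_open,
    }


def partition_to_json(part: PanPartition) -> dict:
    return {
        "n_genomes": part.n_genomes,
        "pan": part.pan,
        "core": part.core,
        "dispensable": part.dispensable,
        "unique": part.unique,
        "fractions_percent": part.fractions_percent(),
        "family_class": part.family_class,
    }


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and parameters of a CLI run; see the config YAML format."""

    proteomes_dir: str | None = None
    matrix_path: str | None = None
    matrix_dialect: str = "binary-tsv"
    metadata_path: str | None = None
    cog_table_path: str | None = None
    ani_matrix_path: str | None = None
    output_dir: str = "bacpan_out"
    identity_min: float = 0.50
    coverage_min: float = 0.50
    min_presence_fraction: float = 1.0 / 3.0
    max_background_presence: int = 0
    permutations: int = 100
    sketch_k: int = 21
    sketch_s: int = 1000
    ani_threshold: float = 95.0
    seed: int = 0
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in payload.items() if k in known}
        extras = {k: v for k, v in payload.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extras = extras
        return cfg

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"seed": self.seed, "config_hash": self.config_hash()}

    def validate_paths(self) -> None:
        for name in ("proteomes_dir", "matrix_path", "metadata_path",
                     "cog_table_path", "ani_matrix_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value} does not exist")
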