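"""Pan-genome partitioning, rarefaction and curve models.

Families are partitioned by occupancy: present in all genomes -> core,
in exactly one -> strain-unique, otherwise dispensable.  Rarefaction adds
genomes in random orders and records the cumulative pan (union), core
(intersection) and new-gene (pan increment) trajectories; their means are
fitted with the standard empirical models

* pan genome:   y(n) = A * n**gamma + C        (Heaps-like power law)
* core genome:  c(n) = A' * exp(-k * n) + Omega (exponential decay)
* new genes:    same exponential-decay form on pan increments.

A positive power-law exponent gamma marks an open pan-genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .matrix import PresenceAbsenceMatrix

#: gamma values below this are treated as numerically zero when calling
#: a pan-genome open.
OPENNESS_GAMMA_TOL = 0.01

CLASS_CORE = "core"
CLASS_DISPENSABLE = "dispensable"
CLASS_UNIQUE = "unique"


@dataclass
class PanPartition:
    """Core / dispensable / strain-unique split of a family set."""

    family_class: dict[str, str]
    n_genomes: int
    core: int
    dispensable: int
    unique: int
    per_genome_core_proportion: pd.Series | None = None
    per_genome_unique_count: pd.Series | None = None

    @property
    def pan(self) -> int:
        return self.core + self.dispensable + self.unique

    def families_in_class(self, cls: str) -> set[str]:
        return {f for f, c in self.family_class.items() if c == cls}

    def fractions_percent(self, decimals: int = 1) -> dict[str, float]:
        """Class fractions as percentages of the pan-genome."""
        pan = self.pan
        if pan == 0:
            return {CLASS_CORE: 0.0, CLASS_DISPENSABLE: 0.0, CLASS_UNIQUE: 0.0}
        return {
            CLASS_CORE: round(100.0 * self.core / pan, decimals),
            CLASS_DISPENSABLE: round(100.0 * self.dispensable / pan, decimals),
            CLASS_UNIQUE: round(100.0 * self.unique / pan, decimals),
        }

    @classmethod
    def from_counts(cls, pan: int, core: int, dispensable: int) -> "PanPartition":
        """Arithmetic-only partition from printed totals (no family ids)."""
        unique = pan - core - dispensable
        if unique < 0:
            raise ValueError("core + dispensable exceed pan size")
        return cls({}, n_genomes=0, core=core, dispensable=dispensable, unique=unique)


def partition(matrix: PresenceAbsenceMatrix) -> PanPartition:
    """Classify every family by occupancy.

    With a single genome every family is simultaneously "in all genomes"
    and "in exactly one"; the core class takes precedence.  A genome with
    zero families is rejected.
    """
    if matrix.n_families == 0:
        raise ValueError("empty matrix")
    sizes = matrix.genome_sizes()
    empty = sizes[sizes == 0]
    if len(empty):
        raise ValueError(f"genome(s) with zero genes: {list(empty.index)[:5]}")
    occ = matrix.occupancy()
    n = matrix.n_genomes
    fam_class = {}
    for fam, k in occ.items():
        if k == n:
            fam_class[fam] = CLASS_CORE
        elif k == 1:
            fam_class[fam] = CLASS_UNIQUE
        else:
            fam_class[fam] = CLASS_DISPENSABLE
    counts = {c: 0 for c in (CLASS_CORE, CLASS_DISPENSABLE, CLASS_UNIQUE)}
    for c in fam_class.values():
        counts[c] += 1
    presence = matrix.presence
    core_fams = [f for f, c in fam_class.items() if c == CLASS_CORE]
    unique_fams = [f for f, c in fam_class.items() if c == CLASS_UNIQUE]
    core_prop = presence.loc[core_fams].sum(axis=0) / sizes
    unique_count = presence.loc[unique_fams].sum(axis=0)
    return PanPartition(
        family_class=fam_class,
        n_genomes=n,
        core=counts[CLASS_CORE],
        dispensable=counts[CLASS_DISPENSABLE],
        unique=counts[CLASS_UNIQUE],
        per_genome_core_proportion=core_prop,
        per_genome_unique_count=unique_count,
    )


@dataclass
class PanProfile:
    """Rarefaction trajectories over random genome addition orders.

    ``pan``, ``core`` and ``new`` are (n_permutations x N) arrays; row p
    holds the trajectory of permutation p over n = 1..N.  ``new`` is the
    pan increment, with new(1) = pan(1).
    """

    n: np.ndarray
    pan: np.ndarray
    core: np.ndarray
    new: np.ndarray
    n_permutations: int
    seed: int
    summary: str = "mean"

    def _summarise(self, arr: np.ndarray) -> np.ndarray:
        if self.summary == "median":
            return np.median(arr, axis=0)
        return arr.mean(axis=0)

    @property
    def mean_pan(self) -> np.ndarray:
        return self._summarise(self.pan)

    @property
    def mean_core(self) -> np.ndarray:
        return self._summarise(self.core)

    @property
    def mean_new(self) -> np.ndarray:
        return self._summarise(self.new)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": self.n, "pan": self.mean_pan, "core": self.mean_core, "new": self.mean_new}
        )


def rarefaction(
    matrix: PresenceAbsenceMatrix, n_permutations: int = 100, seed: int = 0
) -> PanProfile:
    """Cumulative pan/core/new trajectories over random genome orderings."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    presence = matrix.presence.to_numpy().T  # genomes x families, bool
    n_genomes = presence.shape[0]
    rng = np.random.default_rng(seed)
    pan = np.empty((n_permutations, n_genomes), dtype=np.int64)
    core = np.empty_like(pan)
    for p in range(n_permutations):
        order = rng.permutation(n_genomes)
        rows = presence[order]
        pan[p] = np.logical_or.accumulate(rows, axis=0).sum(axis=1)
        core[p] = np.logical_and.accumulate(rows, axis=0).sum(axis=1)
    new = np.diff(pan, axis=1, prepend=0)
    return PanProfile(
        n=np.arange(1, n_genomes + 1),
        pan=pan,
        core=core,
        new=new,
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# curve models
# ---------------------------------------------------------------------------

@dataclass
class CurveFit:
    """Result of a nonlinear least-squares fit of a rarefaction model."""

    model: str  # pan_power | core_expdecay | new_expdecay
    params: dict[str, float]
    r_squared: float
    success: bool = True
    message: str = ""
    is_open: bool | None = None  # pan_power only: gamma > tolerance

    def predict(self, n: np.ndarray) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        p = self.params
        if self.model == "pan_power":
            return p["A"] * n ** p["gamma"] + p["C"]
        return p["A"] * np.exp(-p["k"] * n) + p["Omega"]


def _power_law(n, A, gamma, C):
    return A * np.power(n, gamma) + C


def _exp_decay(n, A, k, Omega):
    return A * np.exp(-k * n) + Omega


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        # zero-variance convention: a perfect fit of a constant is R^2 = 1
        return 1.0 if ss_res < 1e-9 * max(1.0, float(np.mean(y)) ** 2) else float("nan")
    return 1.0 - ss_res / ss_tot


def _fit_with_restarts(fn, n, y, p0, bounds, n_restarts: int = 5):
    """curve_fit with deterministic jittered restarts; returns best params."""
    rng = np.random.default_rng(12345)
    best = None
    best_ss = np.inf
    start = np.asarray(p0, dtype=float)
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            trial = start
        else:
            trial = start * rng.lognormal(0.0, 0.3, size=len(start))
        trial = np.clip(trial, bounds[0], bounds[1])
        try:
            popt, _ = curve_fit(fn, n, y, p0=trial, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((y - fn(n, *popt)) ** 2))
        if ss < best_ss:
            best, best_ss = popt, ss
        if attempt == 0 and best is not None:
            break  # default start converged; no restarts needed
    return best


def _extract_xy(profile, trajectory: str) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profile, PanProfile):
        n = np.asarray(profile.n, dtype=float)
        y = {
            "pan": profile.mean_pan,
            "core": profile.mean_core,
            "new": profile.mean_new,
        }[trajectory]
        return n, np.asarray(y, dtype=float)
    n, y = profile
    return np.asarray(n, dtype=float), np.asarray(y, dtype=float)


def fit_pan_curve(profile: PanProfile | tuple) -> CurveFit:
    """Fit the power-law pan-genome model y(n) = A*n**gamma + C.

    ``profile`` is a PanProfile (the mean pan trajectory is fitted) or an
    ``(n, y)`` pair of arrays.  The openness flag is gamma > 0.01.
    """
    n, y = _extract_xy(profile, "pan")
    if len(np.unique(n)) < 4:
        raise ValueError("need >= 4 distinct n values for a 3-parameter fit")
    span = float(y.max() - y.min())
    if span == 0.0:
        # constant trajectory: the model degenerates to the offset
        return CurveFit(
            "pan_power", {"A": 0.0, "gamma": 0.0, "C": float(y.mean())},
            1.0, is_open=False,
        )
    p0 = (span, 0.5, float(y.min()))
    bounds = ([0.0, 0.0, -np.inf], [np.inf, 2.0, np.inf])
    popt = _fit_with_restarts(_power_law, n, y, p0, bounds)
    if popt is None:
        return CurveFit("pan_power", {}, float("nan"), success=False,
                        message="power-law fit did not converge")
    params = {"A": popt[0], "gamma": popt[1], "C": popt[2]}
    r2 = _r_squared(y, _power_law(n, *popt))
    # a vanishing amplitude carries no growth information -> closed
    is_open = params["gamma"] > OPENNESS_GAMMA_TOL and params["A"] > 1e-8
    return CurveFit("pan_power", params, r2, is_open=bool(is_open))


def _fit_decay(profile, trajectory: str, model_name: str, min_n: int = 1) -> CurveFit:
    n, y = _extract_xy(profile, trajectory)
    keep = n >= min_n
    n, y = n[keep], y[keep]
    if len(np.unique(n)) < 4:
        raise ValueError("need >= 4 distinct n values for a 3-parameter fit")
    span = float(y.max() - y.min())
    if span == 0.0:
        return CurveFit(model_name, {"A": 0.0, "k": 0.0, "Omega": float(y.mean())}, 1.0)
    p0 = (span, 0.1, float(y.min()))
    bounds = ([0.0, 0.0, 0.0], [np.inf, 5.0, np.inf])
    popt = _fit_with_restarts(_exp_decay, n, y, p0, bounds)
    if popt is None:
        return CurveFit(model_name, {}, float("nan"), success=False,
                        message="exponential-decay fit did not converge")
    params = {"A": popt[0], "k": popt[1], "Omega": popt[2]}
    r2 = _r_squared(y, _exp_decay(n, *popt))
    return CurveFit(model_name, params, r2)


def fit_core_curve(profile: PanProfile | tuple) -> CurveFit:
    """Fit the exponential-decay core model c(n) = A'*exp(-k*n) + Omega."""
    return _fit_decay(profile, "core", "core_expdecay")


def fit_new_gene_curve(profile: PanProfile | tuple) -> CurveFit:
    """Fit exponential decay to the new-gene counts for n >= 2."""
    return _fit_decay(profile, "new", "new_expdecay", min_n=2)


# ---------------------------------------------------------------------------
# COG contrast
# ---------------------------------------------------------------------------

def cog_class_contrast(part: PanPartition, cog_table: pd.Series) -> pd.DataFrame:
    """Percent of core vs non-core families per COG category.

    Families missing from ``cog_table`` count as "unknown".  Returns a
    DataFrame indexed by category with core/non-core counts, percentages
    and their core:non-core ratio (inf when a category is absent from the
    non-core side, NaN when absent from both).
    """
    core = sorted(part.families_in_class(CLASS_CORE))
    non_core = sorted(
        part.families_in_class(CLASS_DISPENSABLE) | part.families_in_class(CLASS_UNIQUE)
    )
    if not core and not non_core:
        raise ValueError("partition holds no families")

    def cats(fams: list[str]) -> pd.Series:
        return pd.Series([cog_table.get(f, "unknown") for f in fams], dtype=object)

    core_counts = cats(core).value_counts()
    non_counts = cats(non_core).value_counts()
    categories = sorted(set(core_counts.index) | set(non_counts.index))
    rows = []
    for cat in categories:
        nc = int(core_counts.get(cat, 0))
        nn = int(non_counts.get(cat, 0))
        pc = 100.0 * nc / len(core) if core else 0.0
        pn = 100.0 * nn / len(non_core) if non_core else 0.0
        if pn > 0:
            ratio = pc / pn
        else:
            ratio = float("inf") if pc > 0 else float("nan")
        rows.append((cat, nc, nn, pc, pn, ratio))
    return pd.DataFrame(
        rows,
        columns=["category", "core_count", "noncore_count", "core_pct", "noncore_pct", "ratio"],
    ).set_index("category")
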