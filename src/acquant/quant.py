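"""Label-free quantification post-processing.

Implements the protein-table processing applied after database search in an
AP-MS experiment: contaminant/peptide-count/replicate filtering, log2
transformation, mode-based normalization across samples, left-censored
(downshifted Gaussian) imputation of missing values, replicate-pair ratios,
coefficients of variation, quantified-protein counting, and a
ligand-contamination report built from the most abundant ligand peptides.

Intensities live in a :class:`QuantTable`: a feature x sample matrix with
per-feature annotations. Missing values are encoded as NaN (zeros in input
files are read as missing, matching FragPipe conventions).
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "QuantTable",
    "ImputationParams",
    "NormalizationResult",
    "filter_proteins",
    "pairwise_ratio_modes",
    "solve_normalization_factors",
    "normalize",
    "impute",
    "replicate_pair_ratios",
    "median_ratio",
    "protein_cv",
    "count_quantified",
    "ligand_contamination_report",
    "protein_intensity_from_peptides",
]

META_COLUMNS = ["protein_id", "n_peptides", "is_contaminant", "is_ligand"]
_SAMPLE_RE = re.compile(r"^(?P<condition>.+)_rep(?P<replicate>\d+)$")


def parse_sample_name(name: str) -> tuple[str, int]:
    """Split a sample column name ``<condition>_rep<k>`` into its parts."""
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise ValueError(f"cannot parse sample column {name!r} (expected '<condition>_rep<k>')")
    return m.group("condition"), int(m.group("replicate"))


class QuantTable:
    """Feature x sample intensity matrix with annotations.

    Parameters
    ----------
    meta : DataFrame
        Indexed by feature id, with columns ``protein_id``, ``n_peptides``,
        ``is_contaminant``, ``is_ligand``.
    values : DataFrame
        Same index; one column per sample named ``<condition>_rep<k>``;
        NaN marks a missing measurement.
    level : {"protein", "peptide"}
    is_log2 : bool
        Whether values are log2-transformed (linear intensities otherwise).
    """

    def __init__(self, meta: pd.DataFrame, values: pd.DataFrame,
                 level: str = "protein", is_log2: bool = False):
        if level not in ("protein", "peptide"):
            raise ValueError(f"unknown level {level!r}")
        if not meta.index.equals(values.index):
            raise ValueError("meta and values must share the same feature index")
        if meta.index.has_duplicates:
            dupes = meta.index[meta.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
        if missing_cols:
            raise ValueError(f"meta lacks columns {missing_cols}")
        for col in values.columns:
            parse_sample_name(col)
        if not is_log2 and (values.to_numpy() <= 0).any():
            raise ValueError("linear intensities must be positive where present")
        self.meta = meta[META_COLUMNS].copy()
        self.values = values.astype(float).copy()
        self.level = level
        self.is_log2 = is_log2

    # -- design ----------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for col in self.values.columns:
            seen.setdefault(parse_sample_name(col)[0])
        return list(seen)

    def condition_columns(self, condition: str) -> list[str]:
        return [c for c in self.values.columns if parse_sample_name(c)[0] == condition]

    def select_condition(self, condition: str) -> "QuantTable":
        cols = self.condition_columns(condition)
        if not cols:
            raise KeyError(f"no samples for condition {condition!r}")
        return QuantTable(self.meta, self.values[cols], self.level, self.is_log2)

    # -- transforms ------------------------------------------------------
    def log2(self) -> "QuantTable":
        if self.is_log2:
            return self.copy()
        return QuantTable(self.meta, np.log2(self.values), self.level, is_log2=True)

    def delog(self) -> "QuantTable":
        if not self.is_log2:
            return self.copy()
        return QuantTable(self.meta, np.exp2(self.values), self.level, is_log2=False)

    def copy(self) -> "QuantTable":
        return QuantTable(self.meta, self.values, self.level, self.is_log2)

    def __len__(self) -> int:
        return len(self.meta)

    def __repr__(self) -> str:
        scale = "log2" if self.is_log2 else "linear"
        return (f"<QuantTable level={self.level} features={len(self)} "
                f"samples={len(self.samples)} scale={scale}>")


@dataclass(frozen=True)
class ImputationParams:
    """Downshifted-Gaussian imputation parameters, in units of the per-sample SD.

    Missing values are drawn from Normal(median - downshift*SD, (width*SD)^2),
    the standard left-censored model for intensities missing because they
    fell below the detection limit.
    """

    downshift: float = 1.8
    width: float = 0.3

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


@dataclass
class NormalizationResult:
    """Per-sample additive log2 factors and the pairwise ratio modes behind them."""

    factors: pd.Series
    modes: dict[tuple[str, str], float]
    factor_se: pd.Series | None = None
    residual_sd: float = field(default=float("nan"))

    def mode(self, i: str, j: str) -> float:
        if (i, j) in self.modes:
            return self.modes[(i, j)]
        return -self.modes[(j, i)]


def filter_proteins(table: QuantTable, min_peptides: int = 2,
                    min_replicates: int = 2) -> QuantTable:
    """Keep quantifiable, non-contaminant proteins.

    A protein survives when it is not a contaminant, was identified with at
    least ``min_peptides`` peptides, and was quantified in at least
    ``min_replicates`` replicates of at least one condition. Row order is
    preserved; the operation is idempotent.
    """
    if table.level != "protein":
        raise ValueError("filter_proteins requires a protein-level table")
    observed = table.values.notna()
    enough_reps = pd.Series(False, index=table.meta.index)
    for condition in table.conditions:
        cols = table.condition_columns(condition)
        enough_reps |= observed[cols].sum(axis=1) >= min_replicates
    keep = (~table.meta["is_contaminant"].astype(bool)
            & (table.meta["n_peptides"] >= min_peptides)
            & enough_reps)
    return QuantTable(table.meta.loc[keep], table.values.loc[keep],
                      table.level, table.is_log2)


def _ratio_mode(diffs: np.ndarray, grid_size: int) -> float:
    # A degenerate (constant) ratio distribution has its mode at that constant;
    # gaussian_kde cannot handle zero variance.
    if np.ptp(diffs) < 1e-12:
        return float(diffs[0])
    kde = gaussian_kde(diffs, bw_method="silverman")
    grid = np.linspace(diffs.min(), diffs.max(), grid_size)
    return float(grid[np.argmax(kde(grid))])


def pairwise_ratio_modes(table: QuantTable, grid_size: int = 512,
                         min_shared: int = 10) -> dict[tuple[str, str], float]:
    """Mode of the protein log2-ratio distribution for every sample pair.

    For samples i, j the ratios are {x_pi - x_pj} over proteins observed in
    both. The mode is the argmax of a Gaussian kernel density (Silverman
    bandwidth) on a ``grid_size``-point grid spanning the ratio range. Fewer
    than two shared proteins is an error; fewer than ``min_shared`` earns a
    warning (the mode is then unreliable).
    """
    if not table.is_log2:
        raise ValueError("pairwise_ratio_modes expects a log2-transformed table")
    modes: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(table.samples, 2):
        both = table.values[[i, j]].dropna()
        if len(both) < 2:
            raise ValueError(f"samples {i!r} and {j!r} share only {len(both)} proteins")
        if len(both) < min_shared:
            warnings.warn(f"samples {i!r} and {j!r} share only {len(both)} proteins; "
                          "ratio mode may be unstable", stacklevel=2)
        diffs = (both[i] - both[j]).to_numpy()
        modes[(i, j)] = _ratio_mode(diffs, grid_size)
    return modes


def solve_normalization_factors(modes: dict[tuple[str, str], float],
                                samples: list[str] | None = None) -> NormalizationResult:
    """Per-sample factors from pairwise ratio modes by zero-sum least squares.

    Solves f = argmin sum over pairs (f_i - f_j - m_ij)^2 subject to
    sum(f) = 0; the normalized value of protein p in sample s is x_ps - f_s.
    All pairs enter symmetrically; a disconnected pair graph is an error.
    """
    if samples is None:
        seen: dict[str, None] = {}
        for i, j in modes:
            seen.setdefault(i)
            seen.setdefault(j)
        samples = list(seen)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    index = {s: k for k, s in enumerate(samples)}
    design = np.zeros((len(modes), len(samples)))
    target = np.zeros(len(modes))
    for row, ((i, j), m) in enumerate(modes.items()):
        design[row, index[i]] = 1.0
        design[row, index[j]] = -1.0
        target[row] = m
    rank = np.linalg.matrix_rank(design)
    if rank < len(samples) - 1:
        raise ValueError("pairwise modes do not connect all samples; cannot solve factors")
    # Minimum-norm least-squares solution; the objective is invariant to a
    # constant offset, so recentering enforces the zero-sum constraint exactly.
    solution, *_ = np.linalg.lstsq(design, target, rcond=None)
    solution -= solution.mean()
    factors = pd.Series(solution, index=samples, name="log2_factor")

    residuals = design @ solution - target
    dof = len(modes) - (len(samples) - 1)
    if dof > 0:
        residual_sd = float(np.sqrt(residuals @ residuals / dof))
        cov = np.linalg.pinv(design.T @ design) * residual_sd**2
        factor_se = pd.Series(np.sqrt(np.diag(cov)), index=samples, name="se")
    else:
        residual_sd = float("nan")
        factor_se = pd.Series(np.nan, index=samples, name="se")
    return NormalizationResult(factors=factors, modes=dict(modes),
                               factor_se=factor_se, residual_sd=residual_sd)


def normalize(table: QuantTable, result: NormalizationResult) -> QuantTable:
    """Subtract each sample's log2 factor from its column."""
    if not table.is_log2:
        raise ValueError("normalize expects a log2-transformed table")
    shifted = table.values.sub(result.factors.reindex(table.samples), axis=1)
    return QuantTable(table.meta, shifted, table.level, is_log2=True)


def impute(table: QuantTable, params: ImputationParams | None = None,
           rng: np.random.Generator | None = None) -> QuantTable:
    """Fill missing values with downshifted-Gaussian draws, per sample.

    With med_s and sd_s the median and standard deviation of the observed
    log2 values of sample s, each missing cell receives an independent draw
    from Normal(med_s - downshift*sd_s, (width*sd_s)^2). Observed cells are
    untouched; the result has no missing cells; identical seeds give
    identical draws.
    """
    if not table.is_log2:
        raise ValueError("impute expects a log2-transformed table")
    if params is None:
        params = ImputationParams()
    if rng is None:
        rng = np.random.default_rng()
    filled = table.values.copy()
    for col in filled.columns:
        observed = filled[col].dropna()
        if len(observed) < 3:
            raise ValueError(f"sample {col!r} has only {len(observed)} observed values; "
                             "imputation parameters undefined")
        med = float(np.median(observed))
        sd = float(np.std(observed, ddof=1))
        mask = filled[col].isna()
        n_missing = int(mask.sum())
        if n_missing:
            draws = rng.normal(med - params.downshift * sd, params.width * sd, n_missing)
            filled.loc[mask, col] = draws
    return QuantTable(table.meta, filled, table.level, is_log2=True)


def replicate_pair_ratios(table_a: QuantTable, table_b: QuantTable) -> pd.DataFrame:
    """Per-protein log2 ratios between matching replicates of two tables.

    Replicate k of ``table_a`` is compared with replicate k of ``table_b``
    (ratio = a - b in log2). Tables must either share identical sample
    columns or each hold a single condition with the same replicate
    indices. A pair with a missing member contributes no ratio (NaN).
    """
    if not (table_a.is_log2 and table_b.is_log2):
        raise ValueError("replicate_pair_ratios expects log2-transformed tables")
    cols_a, cols_b = table_a.samples, table_b.samples
    if set(cols_a) == set(cols_b):
        pairs = [(c, c) for c in cols_a]
    else:
        if len(table_a.conditions) != 1 or len(table_b.conditions) != 1:
            raise ValueError("tables with different samples must each hold one condition")
        reps_a = {parse_sample_name(c)[1]: c for c in cols_a}
        reps_b = {parse_sample_name(c)[1]: c for c in cols_b}
        if set(reps_a) != set(reps_b):
            raise ValueError("replicate indices do not match between tables")
        pairs = [(reps_a[k], reps_b[k]) for k in sorted(reps_a)]
    shared = table_a.values.index.intersection(table_b.values.index)
    ratios = pd.DataFrame(index=shared)
    for col_a, col_b in pairs:
        k = parse_sample_name(col_a)[1]
        ratios[f"rep{k}"] = table_a.values.loc[shared, col_a] - table_b.values.loc[shared, col_b]
    return ratios


def median_ratio(ratios: pd.DataFrame, require_all_replicates: bool = False) -> float:
    """Median over proteins of the per-protein mean replicate-pair ratio.

    With ``require_all_replicates`` only proteins quantified in every
    replicate pair enter the median.
    """
    if require_all_replicates:
        ratios = ratios.dropna()
    means = ratios.mean(axis=1, skipna=True).dropna()
    return float(means.median())


def protein_cv(table: QuantTable, condition: str) -> pd.Series:
    """Coefficient of variation across a condition's replicates, per protein.

    CV = SD / mean of linear-scale intensities (log2 values are de-logged
    first). Proteins with fewer than two observed replicates are excluded.
    """
    linear = table.delog()
    sub = linear.values[linear.condition_columns(condition)]
    n_obs = sub.notna().sum(axis=1)
    sub = sub.loc[n_obs >= 2]
    cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    cv.name = f"cv_{condition}"
    return cv


def count_quantified(table: QuantTable, min_reps: int = 2) -> pd.Series:
    """Number of quantified proteins per condition.

    Counts non-ligand, non-contaminant proteins observed in at least
    ``min_reps`` replicates of the condition.
    """
    eligible = (~table.meta["is_contaminant"].astype(bool)
                & ~table.meta["is_ligand"].astype(bool))
    observed = table.values.notna()
    counts = {}
    for condition in table.conditions:
        cols = table.condition_columns(condition)
        counts[condition] = int(((observed[cols].sum(axis=1) >= min_reps) & eligible).sum())
    return pd.Series(counts, name="n_quantified")


def ligand_contamination_report(peptide_table: QuantTable, reference_condition: str,
                                top_n: int = 5) -> pd.Series:
    """Relative ligand-peptide intensity per condition.

    The ``top_n`` ligand peptides most abundant in the reference condition
    (by mean linear intensity across its replicates) are selected once; each
    condition then reports the mean over replicates of their summed
    intensity, relative to the reference condition (reference = 1.0).
    Missing peptides contribute zero signal.
    """
    if peptide_table.level != "peptide":
        raise ValueError("ligand_contamination_report requires a peptide-level table")
    linear = peptide_table.delog()
    ligand = linear.values.loc[linear.meta["is_ligand"].astype(bool)]
    if ligand.empty:
        raise ValueError("table contains no ligand peptides")
    ref_cols = linear.condition_columns(reference_condition)
    if not ref_cols:
        raise KeyError(f"no samples for condition {reference_condition!r}")
    ranking = ligand[ref_cols].fillna(0.0).mean(axis=1).sort_values(ascending=False)
    top = ligand.loc[ranking.index[:top_n]]

    per_condition = {}
    for condition in linear.conditions:
        cols = linear.condition_columns(condition)
        per_condition[condition] = float(top[cols].fillna(0.0).sum(axis=0).mean())
    reference = per_condition[reference_condition]
    if reference == 0:
        raise ValueError("reference condition has zero ligand signal")
    rel = pd.Series({c: v / reference for c, v in per_condition.items()},
                    name="relative_ligand_intensity")
    return rel


def protein_intensity_from_peptides(peptide_table: QuantTable) -> QuantTable:
    """Roll a peptide table up to protein level by summing peptide intensities.

    Raw protein intensity is the sum of the intensities of the peptides
    mapped to that protein. Peptides mapped to several proteins (';'-joined
    ids) are dropped entirely: only unique peptides contribute. A protein
    with no observed peptide in a sample is missing there.
    """
    if peptide_table.level != "peptide":
        raise ValueError("input must be peptide-level")
    linear = peptide_table.delog()
    unique = ~linear.meta["protein_id"].astype(str).str.contains(";")
    meta = linear.meta.loc[unique]
    values = linear.values.loc[unique]

    grouped = values.groupby(meta["protein_id"], sort=False)
    sums = grouped.sum(min_count=1)  # all-NaN stays NaN
    sums.index = sums.index.rename("feature_id")
    n_peptides = meta.groupby(meta["protein_id"], sort=False).size()
    flags = meta.groupby(meta["protein_id"], sort=False)[["is_contaminant", "is_ligand"]].any()
    protein_meta = pd.DataFrame({
        "protein_id": sums.index,
        "n_peptides": n_peptides.reindex(sums.index),
        "is_contaminant": flags["is_contaminant"].reindex(sums.index),
        "is_ligand": flags["is_ligand"].reindex(sums.index),
    }, index=sums.index)
    return QuantTable(protein_meta, sums, level="protein", is_log2=False)
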