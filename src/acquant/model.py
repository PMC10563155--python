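"""Model/Results interface over the LFQ post-processing pipeline.

:class:`LFQModel` is constructed from a protein-level :class:`~acquant.quant.QuantTable`
(or a flat DataFrame / TSV) together with the filtering and imputation
settings; :meth:`LFQModel.fit` runs filtering, log2 transformation,
mode-based normalization, and downshifted imputation, and returns an
:class:`LFQResults` carrying the estimated per-sample normalization factors
with their least-squares standard errors, the processed tables, and the
derived replicate metrics (ratios, CVs, quantified-protein counts).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import quant
from .quant import ImputationParams, NormalizationResult, QuantTable

__all__ = ["LFQModel", "LFQResults"]


class LFQModel:
    """Label-free quantification model for one AP-MS experiment.

    Parameters
    ----------
    table : QuantTable
        Protein-level intensities (linear or log2).
    min_peptides, min_replicates : int
        Protein filter: keep non-contaminants identified with at least
        ``min_peptides`` peptides and quantified in at least
        ``min_replicates`` replicates of some condition.
    imputation : ImputationParams
        Downshift and width of the missing-value distribution, in units of
        the per-sample SD of observed log2 intensities.
    """

    def __init__(self, table: QuantTable, min_peptides: int = 2,
                 min_replicates: int = 2, imputation: ImputationParams | None = None):
        if table.level != "protein":
            raise ValueError("LFQModel requires a protein-level table "
                             "(use quant.protein_intensity_from_peptides first)")
        self.table = table
        self.min_peptides = min_peptides
        self.min_replicates = min_replicates
        self.imputation = imputation if imputation is not None else ImputationParams()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, level: str = "protein", **kwargs) -> "LFQModel":
        """Build from a flat frame in the quant TSV dialect (meta + sample columns)."""
        from .io import quant_table_from_frame
        return cls(quant_table_from_frame(frame, level=level), **kwargs)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "LFQModel":
        from .io import read_quant_tsv
        return cls(read_quant_tsv(path, level="protein"), **kwargs)

    def fit(self, seed: int | None = None,
            rng: np.random.Generator | None = None) -> "LFQResults":
        """Run the pipeline and return results.

        The only stochastic step is imputation; pass ``seed`` (or an
        explicit ``rng``) for reproducible draws.
        """
        if rng is None:
            rng = np.random.default_rng(seed)
        filtered = quant.filter_proteins(self.table, self.min_peptides, self.min_replicates)
        logged = filtered.log2()
        modes = quant.pairwise_ratio_modes(logged)
        norm = quant.solve_normalization_factors(modes, samples=logged.samples)
        normalized = quant.normalize(logged, norm)
        imputed = quant.impute(normalized, self.imputation, rng)
        return LFQResults(self, norm, observed=normalized, imputed=imputed)


class LFQResults:
    """Fitted LFQ pipeline: normalization estimates, tables and metrics.

    Attributes
    ----------
    params : Series
        Per-sample additive log2 normalization factors (zero-sum).
    bse : Series
        Their standard errors from the pairwise-mode least squares.
    observed : QuantTable
        Filtered, log2, normalized table with missingness intact; replicate
        counts and CVs are computed from this table so imputed values never
        masquerade as measurements.
    imputed : QuantTable
        The same table with missing cells drawn from the downshifted
        Gaussian.
    """

    def __init__(self, model: LFQModel, normalization: NormalizationResult,
                 observed: QuantTable, imputed: QuantTable):
        self.model = model
        self.normalization = normalization
        self.observed = observed
        self.imputed = imputed

    @property
    def params(self) -> pd.Series:
        return self.normalization.factors

    @property
    def bse(self) -> pd.Series:
        return self.normalization.factor_se

    @property
    def nobs(self) -> int:
        return len(self.observed)

    # -- derived metrics -------------------------------------------------
    def counts(self, min_reps: int | None = None) -> pd.Series:
        """Quantified non-ligand, non-contaminant proteins per condition."""
        if min_reps is None:
            min_reps = self.model.min_replicates
        return quant.count_quantified(self.observed, min_reps=min_reps)

    def cv(self, condition: str) -> pd.Series:
        """Per-protein coefficient of variation within a condition."""
        return quant.protein_cv(self.observed, condition)

    def condition_ratios(self, condition_a: str, condition_b: str,
                         use_imputed: bool = False) -> pd.DataFrame:
        """Replicate-pair log2 ratios (a - b) between two conditions."""
        table = self.imputed if use_imputed else self.observed
        return quant.replicate_pair_ratios(table.select_condition(condition_a),
                                           table.select_condition(condition_b))

    def median_condition_ratio(self, condition_a: str, condition_b: str,
                               require_all_replicates: bool = True) -> float:
        return quant.median_ratio(self.condition_ratios(condition_a, condition_b),
                                  require_all_replicates=require_all_replicates)

    def protein_report(self) -> pd.DataFrame:
        """Per-protein table: normalized means per condition and CVs."""
        report = self.observed.meta.copy()
        for condition in self.observed.conditions:
            cols = self.observed.condition_columns(condition)
            report[f"mean_log2_{condition}"] = self.observed.values[cols].mean(axis=1)
            report = report.join(self.cv(condition))
        return report

    def summary(self) -> str:
        """Human-readable run summary."""
        lines = []
        lines.append("LFQ pipeline results")
        lines.append("=" * 60)
        lines.append(f"Proteins after filtering: {self.nobs} "
                     f"(of {len(self.model.table)} input)")
        lines.append(f"Filter: >= {self.model.min_peptides} peptides, "
                     f"non-contaminant, quantified in >= {self.model.min_replicates} "
                     "replicates of one condition")
        p = self.model.imputation
        lines.append(f"Imputation: Normal(median - {p.downshift}*SD, ({p.width}*SD)^2) per sample")
        lines.append("")
        lines.append("Normalization factors (additive, log2):")
        header = f"  {'sample':<20}{'factor':>10}{'se':>10}"
        lines.append(header)
        for sample in self.params.index:
            se = self.bse[sample] if self.bse is not None else float("nan")
            lines.append(f"  {sample:<20}{self.params[sample]:>10.4f}{se:>10.4f}")
        rsd = self.normalization.residual_sd
        lines.append(f"  mode-fit residual SD: {rsd:.4f}" if np.isfinite(rsd)
                     else "  mode-fit residual SD: n/a (saturated)")
        lines.append("")
        lines.append("Quantified proteins per condition "
                     f"(>= {self.model.min_replicates} replicates):")
        for condition, n in self.counts().items():
            lines.append(f"  {condition:<20}{n:>10d}")
        missing = int(self.observed.values.isna().sum().sum())
        total = self.observed.values.size
        lines.append("")
        lines.append(f"Missing cells before imputation: {missing}/{total} "
                     f"({100.0 * missing / total:.1f}%)")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"<LFQResults proteins={self.nobs} samples={len(self.params)}>"
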