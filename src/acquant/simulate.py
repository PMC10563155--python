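"""Synthetic AP-MS experiments with known ground truth.

Emulates a nanobody pull-down of a GFP-tagged bait from a yeast lysate,
measured label-free in two conditions (bait-tagged vs untagged) with
replicates, on beads that are either mock-treated or chemically acetylated.
Background protein abundances are log-normal; bait and interactors are
enriched in the tagged condition; the bead-coupled ligand contributes
peptides produced mechanistically by the two-step digestion engine, so its
signal decays with the per-lysine acetylation probability exactly as the
blocked-cleavage model dictates. Per-sample abundance shifts mimic unequal
loading, and cells go missing with a logistic probability in log2 intensity
(left-censored MNAR), the mechanism the downshifted imputation presumes.

Every dataset is emitted together with a :class:`SimTruth` holding the true
shifts, enrichments and ligand signal fractions, sufficient to score
recovery by the quantification pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import quant
from .digestion import ProteinSequence, acetylate, ligand_signal_fraction, two_step_digest
from .quant import QuantTable

__all__ = ["SimConfig", "SimTruth", "default_ligand", "generate_experiment", "simulate_titration"]

# Synthetic nanobody-like ligand (~120 aa, VHH-like lysine/arginine content).
# Stand-in for a real single-domain antibody sequence; not a database entry.
_SYNTHETIC_NANOBODY = (
    "MAQVQLVESGGGLVQAGGSLRLSCAASGRTFSKYAMGWFRQAPGKEREFVAAISWSGGSTYY"
    "ADSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYCAADKGRSSWYDYWGQGTQVTVSSLE"
)


def default_ligand() -> ProteinSequence:
    """Synthetic bead-anchored nanobody-like ligand."""
    return ProteinSequence("ligand_nanobody", _SYNTHETIC_NANOBODY,
                           role="ligand", attachment_index=0)


@dataclass
class SimConfig:
    """Study conditions for one simulated pull-down experiment.

    The defaults describe a mid-size AP-MS experiment: a few hundred
    background proteins, a tagged-vs-untagged design in triplicate, strong
    bait enrichment, modest loading differences between samples, and
    intensity-dependent missingness.

    Attributes
    ----------
    acetylation_p : float
        Per-lysine acetylation probability of the bead arm (0 for mock
        treatment, close to 1 for saturating chemical acetylation).
    bait_enrichment, interactor_enrichment : float
        log2 boost of bait/interactors in the tagged condition.
    sample_shifts : list of float or None
        Per-sample additive log2 offsets (loading differences), summing to
        zero; drawn Normal(0, shift_sd) and centered when None.
    missing_threshold, missing_steepness : float
        Logistic MNAR model: a cell of log2 intensity x is dropped with
        probability sigmoid((threshold - x) / steepness).
    """

    n_background_proteins: int = 300
    n_interactors: int = 20
    n_contaminants: int = 10
    bait_enrichment: float = 3.0
    interactor_enrichment: float = 2.0
    ligand: ProteinSequence = field(default_factory=default_ligand)
    ligand_log2_abundance: float = 26.0
    acetylation_p: float = 0.0
    conditions: tuple[str, str] = ("tagged", "untagged")
    n_replicates: int = 3
    sample_shifts: list[float] | None = None
    shift_sd: float = 0.5
    log2_abundance_mean: float = 23.0
    log2_abundance_sd: float = 2.0
    replicate_sd: float = 0.25
    missing_threshold: float = 18.0
    missing_steepness: float = 1.0
    peptides_per_protein: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0.0 <= self.acetylation_p <= 1.0:
            raise ValueError("acetylation_p must be in [0, 1]")
        if self.peptides_per_protein < 2:
            raise ValueError("peptides_per_protein must be >= 2")
        if self.sample_shifts is not None:
            n_samples = len(self.conditions) * self.n_replicates
            if len(self.sample_shifts) != n_samples:
                raise ValueError(f"sample_shifts must have {n_samples} entries")
            if abs(sum(self.sample_shifts)) > 1e-9:
                raise ValueError("sample_shifts must sum to 0")
        if self.missing_steepness <= 0:
            raise ValueError("missing_steepness must be > 0")
        if self.ligand.role != "ligand":
            raise ValueError("ligand sequence must have role='ligand'")


@dataclass
class SimTruth:
    """Ground truth emitted beside every synthetic dataset."""

    sample_shifts: pd.Series
    enrichments: pd.Series              # log2, per enriched protein (tagged vs untagged)
    ligand_signal_fraction: float       # expected, from the digestion model
    ligand_realized_fraction: pd.Series  # realized per sample (pre-missingness)
    missing_mask: pd.DataFrame          # True where the cell was dropped

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-item view, written next to the dataset."""
        rows = [("sample_shift", k, v) for k, v in self.sample_shifts.items()]
        rows += [("enrichment_log2", k, v) for k, v in self.enrichments.items()]
        rows += [("ligand_signal_fraction", "expected", self.ligand_signal_fraction)]
        rows += [("ligand_realized_fraction", k, v)
                 for k, v in self.ligand_realized_fraction.items()]
        return pd.DataFrame(rows, columns=["item", "key", "value"])


def _sample_names(config: SimConfig) -> list[str]:
    return [f"{cond}_rep{k}" for cond in config.conditions
            for k in range(1, config.n_replicates + 1)]


def _ligand_peptide_rows(config: SimConfig, rng: np.random.Generator,
                         samples: list[str]) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Mechanistic ligand peptides: one acetylation draw per sample.

    Released peptide intensities split the ligand's abundance in proportion
    to released residue length relative to the unmodified protein, so the
    summed ligand signal tracks the blocked-cleavage model.
    """
    ligand = config.ligand
    base_released, _ = two_step_digest(ligand)
    base_length = sum(p.end - p.start for p in base_released)
    if base_length == 0:
        base_length = len(ligand)

    per_sample: dict[str, dict[str, float]] = {}
    realized = {}
    for sample in samples:
        acetyl = acetylate(ligand, config.acetylation_p, rng)
        released, _ = two_step_digest(ligand, acetyl)
        abundance = 2.0 ** (config.ligand_log2_abundance
                            + rng.normal(0.0, config.replicate_sd))
        cells = {}
        for pep in released:
            fid = f"{ligand.id}:{pep.start}-{pep.end}"
            cells[fid] = abundance * (pep.end - pep.start) / base_length
        per_sample[sample] = cells
        realized[sample] = sum(pep.end - pep.start for pep in released) / base_length

    feature_ids = sorted({fid for cells in per_sample.values() for fid in cells},
                         key=lambda f: (int(f.split(":")[1].split("-")[0]), f))
    values = pd.DataFrame(np.nan, index=pd.Index(feature_ids, name="feature_id"),
                          columns=samples)
    for sample, cells in per_sample.items():
        for fid, intensity in cells.items():
            values.loc[fid, sample] = intensity
    meta = pd.DataFrame({
        "protein_id": ligand.id,
        "n_peptides": len(feature_ids),
        "is_contaminant": True,
        "is_ligand": True,
    }, index=values.index)
    return meta, values, pd.Series(realized, name="ligand_realized_fraction")


def generate_experiment(config: SimConfig) -> tuple[QuantTable, QuantTable, SimTruth]:
    """Simulate one pull-down arm; returns (peptide table, protein table, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _sample_names(config)
    n_samples = len(samples)
    tagged_cols = np.array([s.startswith(config.conditions[0] + "_rep") for s in samples])

    if config.sample_shifts is None:
        shifts = rng.normal(0.0, config.shift_sd, n_samples)
        shifts -= shifts.mean()
    else:
        shifts = np.asarray(config.sample_shifts, dtype=float)
    shift_series = pd.Series(shifts, index=samples, name="log2_shift")

    # -- protein roster --------------------------------------------------
    protein_ids, enrichments, contaminant_flags = [], {}, {}
    protein_ids.append("bait")
    enrichments["bait"] = config.bait_enrichment
    for i in range(config.n_interactors):
        pid = f"interactor_{i + 1:03d}"
        protein_ids.append(pid)
        enrichments[pid] = config.interactor_enrichment
    for i in range(config.n_background_proteins):
        protein_ids.append(f"background_{i + 1:04d}")
    for i in range(config.n_contaminants):
        pid = f"contaminant_{i + 1:03d}"
        protein_ids.append(pid)
        contaminant_flags[pid] = True

    base_log2 = rng.normal(config.log2_abundance_mean, config.log2_abundance_sd,
                           len(protein_ids))

    # -- peptide-level intensities --------------------------------------
    k = config.peptides_per_protein
    meta_rows, value_rows, index = [], [], []
    for pid, base in zip(protein_ids, base_log2):
        weights = rng.dirichlet(np.full(k, 2.0))
        enrich = enrichments.get(pid, 0.0)
        for j, w in enumerate(weights):
            index.append(f"{pid}_pep{j + 1}")
            meta_rows.append((pid, k, contaminant_flags.get(pid, False), False))
            cell_log2 = (base + np.log2(w) + shifts
                         + np.where(tagged_cols, enrich, 0.0)
                         + rng.normal(0.0, config.replicate_sd, n_samples))
            value_rows.append(2.0 ** cell_log2)
    meta = pd.DataFrame(meta_rows, index=pd.Index(index, name="feature_id"),
                        columns=["protein_id", "n_peptides", "is_contaminant", "is_ligand"])
    values = pd.DataFrame(value_rows, index=meta.index, columns=samples)

    # -- ligand peptides (mechanistic) ----------------------------------
    lig_meta, lig_values, realized = _ligand_peptide_rows(config, rng, samples)
    lig_values = lig_values.mul(2.0 ** shifts, axis=1)
    meta = pd.concat([meta, lig_meta])
    values = pd.concat([values, lig_values])

    # -- MNAR missingness ------------------------------------------------
    with np.errstate(divide="ignore"):
        log2_values = np.log2(values.to_numpy())
    p_missing = 1.0 / (1.0 + np.exp(-(config.missing_threshold - log2_values)
                                    / config.missing_steepness))
    p_missing = np.where(np.isnan(log2_values), 0.0, p_missing)
    dropped = rng.random(values.shape) < p_missing
    observed_values = values.mask(dropped)
    missing_mask = pd.DataFrame(dropped | values.isna().to_numpy(),
                                index=values.index, columns=values.columns)

    peptide_table = QuantTable(meta, observed_values, level="peptide", is_log2=False)
    protein_table = quant.protein_intensity_from_peptides(peptide_table)

    expected_fraction = (1.0 if config.acetylation_p == 0.0 else
                         ligand_signal_fraction(config.ligand, config.acetylation_p,
                                                n_reps=2000,
                                                rng=np.random.default_rng(config.seed + 1)))
    truth = SimTruth(
        sample_shifts=shift_series,
        enrichments=pd.Series(enrichments, name="enrichment_log2"),
        ligand_signal_fraction=expected_fraction,
        ligand_realized_fraction=realized,
        missing_mask=missing_mask,
    )
    return peptide_table, protein_table, truth


def simulate_titration(config: SimConfig, p_values: list[float],
                       n_replicates: int = 2, top_n: int = 5) -> pd.DataFrame:
    """Ligand signal across an acetylation titration, relative to mock.

    For each acetylation probability p, simulates ``n_replicates`` bead
    preparations of the configured ligand and reports the relative intensity
    of the ``top_n`` ligand peptides most abundant at p = 0, mirroring a
    two-replicate bead-titration readout. The mapping from reagent
    concentration to p is deliberately not modeled; p is the independent
    variable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = list(dict.fromkeys([0.0] + [float(p) for p in p_values]))
    for p in grid:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"acetylation probability {p} outside [0, 1]")
    samples = [f"p{i}_rep{k}" for i in range(len(grid)) for k in range(1, n_replicates + 1)]

    per_sample: dict[str, dict[str, float]] = {s: {} for s in samples}
    ligand = config.ligand
    base_released, _ = two_step_digest(ligand)
    base_length = max(sum(p_.end - p_.start for p_ in base_released), 1)
    for i, p in enumerate(grid):
        for k in range(1, n_replicates + 1):
            sample = f"p{i}_rep{k}"
            acetyl = acetylate(ligand, p, rng)
            released, _ = two_step_digest(ligand, acetyl)
            abundance = 2.0 ** (config.ligand_log2_abundance
                                + rng.normal(0.0, config.replicate_sd))
            for pep in released:
                fid = f"{ligand.id}:{pep.start}-{pep.end}"
                per_sample[sample][fid] = abundance * (pep.end - pep.start) / base_length

    feature_ids = sorted({fid for cells in per_sample.values() for fid in cells})
    values = pd.DataFrame(np.nan, index=pd.Index(feature_ids, name="feature_id"),
                          columns=samples)
    for sample, cells in per_sample.items():
        for fid, intensity in cells.items():
            values.loc[fid, sample] = intensity
    meta = pd.DataFrame({"protein_id": ligand.id, "n_peptides": len(feature_ids),
                         "is_contaminant": True, "is_ligand": True}, index=values.index)
    table = QuantTable(meta, values, level="peptide", is_log2=False)
    report = quant.ligand_contamination_report(table, reference_condition="p0", top_n=top_n)
    rel = [report[f"p{i}"] for i in range(len(grid))]
    return pd.DataFrame({"acetylation_p": grid, "relative_ligand_intensity": rel})
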