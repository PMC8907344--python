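"""Synthetic acetylome experiments with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: log2-normal site and protein intensities, a 4-sample two-arm
design with one run per condition, planted direct targets (acetylation up
under deacetylase knockdown, down under overexpression), indirect targets
(the reverse), protein-level abundance shifts that the normalization must
cancel, and intensity-dependent (left-censored, MNAR) dropout following a
logistic model on the log2 scale.

``noise_sd`` parameterizes the log2 noise of a two-sample ratio — the
quantity every downstream threshold acts on; each individual measurement
receives independent N(0, noise_sd/sqrt(2)).  Intensities are simulated in
log2 space and exponentiated on output, matching the left-censoring
assumption of the downshift imputation.  Protein sequences are i.i.d.
draws from human amino-acid background frequencies with lysines forced at
the planted site positions: sufficient for window and motif machinery, with
no homology structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DEFAULT_DESIGN, StudyDesign
from .errors import ValidationError
from .io import ProteinRecord, SiteRecord

DIRECT = "direct"
INDIRECT = "indirect"
NULL = "null"

#: Human proteome amino-acid frequencies (SwissProt-scale rounding).
AA_FREQUENCIES: dict[str, float] = {
    "A": 0.0702, "R": 0.0564, "N": 0.0359, "D": 0.0473, "C": 0.0230,
    "Q": 0.0477, "E": 0.0710, "G": 0.0657, "H": 0.0263, "I": 0.0433,
    "L": 0.0996, "K": 0.0573, "M": 0.0213, "F": 0.0365, "P": 0.0631,
    "S": 0.0831, "T": 0.0535, "W": 0.0122, "Y": 0.0266, "V": 0.0598,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: ~1414 proteins with ~2 acetyl sites each,
    MaxQuant-like log2 LFQ centered at 25 (sd 2), 5% direct / 15% indirect
    sites with 2-fold planted effects, and MNAR dropout centered two SDs
    below the intensity mean."""

    n_proteins: int = 1414
    sites_per_protein: tuple[float, int] = (2.0, 8)  # (mean, max)
    log2_intensity_mean: float = 25.0
    log2_intensity_sd: float = 2.0
    frac_direct: float = 0.05
    frac_indirect: float = 0.15
    effect_log2: float = 1.0
    protein_change_sd: float = 0.25
    noise_sd: float = 0.2
    protein_noise_sd: float = 0.0
    missingness: tuple[float, float] = (21.0, 1.0)  # (logistic midpoint, slope)
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        mean_sites, max_sites = self.sites_per_protein
        if mean_sites < 1 or max_sites < 1:
            raise ValidationError("sites_per_protein mean and max must be >= 1")
        if not (0 <= self.frac_direct <= 1 and 0 <= self.frac_indirect <= 1):
            raise ValidationError("class fractions must lie in [0, 1]")
        if self.frac_direct + self.frac_indirect > 1:
            raise ValidationError("frac_direct + frac_indirect must be <= 1")
        if self.effect_log2 <= 0:
            raise ValidationError("effect_log2 must be positive")
        for name in ("log2_intensity_sd", "protein_change_sd", "noise_sd",
                     "protein_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_replicates != 1:
            raise ValidationError(
                "the design has one run per condition; n_replicates > 1 is refused "
                "rather than silently averaged"
            )


@dataclass
class SimulatedExperiment:
    """Generator output: proteome, both quant tables, and per-site truth."""

    proteome: dict[str, str]
    proteins: list[ProteinRecord]
    sites: list[SiteRecord]
    truth: pd.DataFrame  # one row per site record: class and coordinates
    config: SimConfig = field(repr=False, default=SimConfig())

    def protein_truth(self) -> pd.Series:
        """Gene -> class under the any-site rule (direct beats indirect)."""
        def consolidate(classes: pd.Series) -> str:
            if (classes == DIRECT).any():
                return DIRECT
            if (classes == INDIRECT).any():
                return INDIRECT
            return NULL

        return self.truth.groupby("gene")["site_class"].agg(consolidate)


def _random_sequences(
    rng: np.random.Generator, lengths: Sequence[int]
) -> list[str]:
    letters = np.array(list(AA_FREQUENCIES), dtype="<U1")
    probabilities = np.array(list(AA_FREQUENCIES.values()))
    probabilities = probabilities / probabilities.sum()
    total = int(np.sum(lengths))
    flat = rng.choice(letters, size=total, p=probabilities)
    out = []
    cursor = 0
    for n in lengths:
        out.append("".join(flat[cursor : cursor + n]))
        cursor += n
    return out


def _dropout_probability(log2_intensity: np.ndarray, midpoint: float, slope: float) -> np.ndarray:
    """P(missing | log2 intensity); slope 0 disables dropout entirely."""
    if slope == 0:
        return np.zeros_like(log2_intensity)
    return 1.0 / (1.0 + np.exp(slope * (log2_intensity - midpoint)))


def generate_experiment(
    config: SimConfig = SimConfig(),
    design: StudyDesign = DEFAULT_DESIGN,
) -> SimulatedExperiment:
    """Generate a complete synthetic experiment, reproducible from the seed.

    Direct sites gain ``+effect_log2`` acetyl intensity in the knockdown
    arm's experimental sample and ``-effect_log2`` in the overexpression
    arm's experimental sample (on top of the protein-level change); indirect
    sites the reverse; null sites carry no systematic acetyl effect.
    Protein LFQ varies per sample by ``protein_change_sd`` independently of
    site class, and the same shift enters the acetyl intensities so that
    protein normalization can cancel it.
    """
    rng = np.random.default_rng(config.seed)
    mean_sites, max_sites = config.sites_per_protein
    samples = design.sample_ids
    kd_exp = design.knockdown[0]
    oe_exp = design.overexpression[0]

    n_sites_per_protein = 1 + rng.poisson(max(mean_sites - 1.0, 0.0), size=config.n_proteins)
    n_sites_per_protein = np.minimum(n_sites_per_protein, max_sites)
    lengths = 150 + 12 * n_sites_per_protein + rng.integers(0, 100, size=config.n_proteins)
    sequences = _random_sequences(rng, lengths)

    proteome: dict[str, str] = {}
    proteins: list[ProteinRecord] = []
    sites: list[SiteRecord] = []
    truth_rows: list[dict] = []

    measurement_sd = config.noise_sd / np.sqrt(2.0)
    protein_measurement_sd = config.protein_noise_sd / np.sqrt(2.0)
    midpoint, slope = config.missingness

    for p_index in range(config.n_proteins):
        accession = f"P{p_index + 1:05d}"
        gene = f"GENE{p_index + 1:05d}"
        n_sites = int(n_sites_per_protein[p_index])
        sequence = sequences[p_index]
        positions = np.sort(
            rng.choice(np.arange(1, len(sequence) + 1), size=n_sites, replace=False)
        )
        chars = list(sequence)
        for pos in positions:
            chars[pos - 1] = "K"
        sequence = "".join(chars)
        proteome[accession] = sequence

        protein_base = rng.normal(config.log2_intensity_mean, config.log2_intensity_sd)
        protein_shift = {s: rng.normal(0.0, config.protein_change_sd) for s in samples}
        lfq_log2 = {
            s: protein_base
            + protein_shift[s]
            + rng.normal(0.0, protein_measurement_sd)
            for s in samples
        }
        lfq = {
            s: _maybe_drop(rng, v, midpoint, slope) for s, v in lfq_log2.items()
        }
        proteins.append(
            ProteinRecord(protein_accession=accession, gene_symbol=gene, lfq=lfq)
        )

        for pos in positions:
            u = rng.random()
            if u < config.frac_direct:
                site_class = DIRECT
            elif u < config.frac_direct + config.frac_indirect:
                site_class = INDIRECT
            else:
                site_class = NULL
            base = rng.normal(config.log2_intensity_mean, config.log2_intensity_sd)
            effect = {s: 0.0 for s in samples}
            if site_class == DIRECT:
                effect[kd_exp] = +config.effect_log2
                effect[oe_exp] = -config.effect_log2
            elif site_class == INDIRECT:
                effect[kd_exp] = -config.effect_log2
                effect[oe_exp] = +config.effect_log2
            log2_values = {
                s: base
                + protein_shift[s]
                + effect[s]
                + rng.normal(0.0, measurement_sd)
                for s in samples
            }
            intensity = {
                s: _maybe_drop(rng, v, midpoint, slope) for s, v in log2_values.items()
            }
            start = max(0, int(pos) - 8)
            peptide = sequence[start : int(pos) + 7]
            record = SiteRecord(
                protein_accession=accession,
                gene_symbol=gene,
                peptide_sequence=peptide,
                site_positions=(int(pos),),
                intensity=intensity,
            )
            sites.append(record)
            truth_rows.append(
                {
                    "record": len(sites) - 1,
                    "peptide_key": record.peptide_key,
                    "accession": accession,
                    "gene": gene,
                    "position": int(pos),
                    "site_class": site_class,
                }
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["record", "peptide_key", "accession", "gene", "position", "site_class"],
    )
    return SimulatedExperiment(
        proteome=proteome, proteins=proteins, sites=sites, truth=truth, config=config
    )


def _maybe_drop(
    rng: np.random.Generator, log2_value: float, midpoint: float, slope: float
) -> float | None:
    p = _dropout_probability(np.asarray(log2_value), midpoint, slope)
    if slope != 0 and rng.random() < float(p):
        return None
    return float(2.0 ** log2_value)


def expected_missing_fraction(config: SimConfig) -> float:
    """Analytic expectation of the dropout fraction: the logistic dropout
    integrated over the Gaussian log2 intensity distribution."""
    from scipy import integrate, stats

    midpoint, slope = config.missingness
    if slope == 0:
        return 0.0
    sd = float(
        np.sqrt(
            config.log2_intensity_sd**2
            + config.protein_change_sd**2
            + (config.noise_sd / np.sqrt(2.0)) ** 2
        )
    )

    def integrand(x: float) -> float:
        return stats.norm.pdf(x, config.log2_intensity_mean, sd) / (
            1.0 + np.exp(slope * (x - midpoint))
        )

    lo = config.log2_intensity_mean - 10 * sd
    hi = config.log2_intensity_mean + 10 * sd
    value, _ = integrate.quad(integrand, lo, hi, limit=200)
    return float(value)


def planted_motif_windows(
    n_fg: int,
    n_bg: int,
    motif: tuple[int, str],
    enrichment: float,
    seed: int = 0,
    half_width: int = 5,
) -> tuple[list[str], dict[str, str]]:
    """Foreground windows carrying a planted (position, residue) motif with
    probability ``enrichment``, plus a random background proteome.

    The background proteome is sized so its K-centered windows number about
    ``n_bg``.  Position 0 is the fixed central K and cannot be planted.
    """
    position, residue = motif
    if position == 0:
        raise ValidationError("position 0 is the fixed central K")
    if not -half_width <= position <= half_width:
        raise ValidationError("motif position must lie within the window")
    if residue not in AA_FREQUENCIES:
        raise ValidationError(f"unknown residue {residue!r}")
    if not 0.0 <= enrichment <= 1.0:
        raise ValidationError("enrichment must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    width = 2 * half_width + 1
    letters = np.array(list(AA_FREQUENCIES), dtype="<U1")
    probabilities = np.array(list(AA_FREQUENCIES.values()))
    probabilities = probabilities / probabilities.sum()

    windows = rng.choice(letters, size=(n_fg, width), p=probabilities)
    windows[:, half_width] = "K"
    planted = rng.random(n_fg) < enrichment
    windows[planted, half_width + position] = residue
    foreground = ["".join(row) for row in windows]

    protein_length = 300
    k_per_protein = protein_length * AA_FREQUENCIES["K"]
    n_proteins = max(1, int(np.ceil(n_bg / k_per_protein)))
    sequences = _random_sequences(rng, [protein_length] * n_proteins)
    proteome = {f"BG{i + 1:05d}": seq for i, seq in enumerate(sequences)}
    return foreground, proteome
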