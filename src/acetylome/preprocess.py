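"""Missing-value imputation and protein-level normalization of acetyl sites.

Label-free acetylome data are missing-not-at-random: a value is usually
absent because the peptide fell below the detection limit.  Missing cells
are therefore imputed from a *down-shifted* Gaussian: with population mean
mu and standard deviation sigma computed over all unimputed log2 values of
the table, draws come from N(mu - 1.8 sigma, sigma^2) truncated to
mu - 1.8 sigma +/- 0.3 sigma.  Imputation and all population statistics
operate in log2 space (a downshift is only meaningful on log intensities);
ratios are reported on the linear scale because the downstream fold-change
threshold is stated as 1.5-fold.

A comparison is only trusted when at most one of its measurements was
imputed, for the acetyl pair and for the protein pair independently; a
protein never quantified in an arm excludes every peptide of that protein
from that arm ("protein_unquantified").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import ARMS, Contrast, StudyDesign
from .errors import ValidationError
from .io import ProteinRecord, SiteRecord, copy_records

BOTH_MISSING = "both_missing"
PROTEIN_UNQUANTIFIED = "protein_unquantified"


@dataclass(frozen=True)
class ImputationParams:
    """Downshifted-Gaussian imputation parameters, in multiples of the
    population SD: the draw distribution is
    N(mu - downshift*sigma, sigma^2) truncated to +/- halfwidth*sigma."""

    downshift: float = 1.8
    halfwidth: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.downshift <= 0:
            raise ValidationError("downshift must be > 0")
        if self.halfwidth < 0:
            raise ValidationError("halfwidth must be >= 0")


@dataclass(frozen=True)
class ArmChange:
    """Raw and protein-normalized fold change of one site in one comparison."""

    raw_ratio: float | None
    protein_ratio: float | None
    normalized_ratio: float | None
    n_imputed_acetyl: int
    n_imputed_protein: int
    excluded: bool
    reason: str | None


def _values_of(record: SiteRecord | ProteinRecord) -> dict[str, float | None]:
    return record.intensity if isinstance(record, SiteRecord) else record.lfq


def population_stats(records: Iterable[SiteRecord | ProteinRecord]) -> tuple[float, float]:
    """Mean and SD of all unimputed log2 values of a whole table."""
    observed = [
        math.log2(v)
        for r in records
        for s, v in _values_of(r).items()
        if v is not None and not r.imputed.get(s, False)
    ]
    if len(observed) < 2:
        raise ValidationError("need >= 2 unimputed values to define population statistics")
    mu = float(np.mean(observed))
    sigma = float(np.std(observed, ddof=0))
    if sigma == 0.0:
        raise ValidationError("degenerate population: all unimputed values identical")
    return mu, sigma


def impute(
    records: Sequence[SiteRecord] | Sequence[ProteinRecord],
    params: ImputationParams = ImputationParams(),
    design: StudyDesign | None = None,
) -> list:
    """Impute missing values by Gaussian downshift; observed values are never touched.

    With a design, a missing cell is eligible only if the other measurement
    of its arm was observed (one of two allowed missing); a fully missing
    pair stays missing and its comparisons are excluded downstream.  Without
    a design every missing cell is imputed.  Returns new records with
    ``imputed`` flags set; draws are reproducible from ``params.seed``.
    """
    out = copy_records(records)
    mu, sigma = population_stats(out)
    eligible: list[tuple[int, str]] = []
    for index, record in enumerate(out):
        values = _values_of(record)
        if design is None:
            eligible.extend((index, s) for s, v in values.items() if v is None)
        else:
            for exp, ctl in design.arms.values():
                pair = [(s, values.get(s)) for s in (exp, ctl)]
                missing = [s for s, v in pair if v is None]
                if len(missing) == 1:
                    eligible.append((index, missing[0]))
    if not eligible:
        return out
    rng = np.random.default_rng(params.seed)
    if params.halfwidth == 0:
        draws = np.full(len(eligible), mu - params.downshift * sigma)
    else:
        draws = stats.truncnorm.rvs(
            -params.halfwidth,
            params.halfwidth,
            loc=mu - params.downshift * sigma,
            scale=sigma,
            size=len(eligible),
            random_state=rng,
        )
    for (index, sample), log2_value in zip(eligible, draws):
        values = _values_of(out[index])
        values[sample] = float(2.0 ** log2_value)
        out[index].imputed[sample] = True
    return out


def _contrast_terms(
    record: SiteRecord | ProteinRecord, contrast: Contrast
) -> tuple[float | None, int]:
    """(log2 contrast value or None if under-observed, n imputed measurements)."""
    values = _values_of(record)
    total = 0.0
    n_imputed = 0
    for sample, coefficient in contrast.items():
        v = values.get(sample)
        if v is None:
            return None, n_imputed
        if record.imputed.get(sample, False):
            n_imputed += 1
        total += coefficient * math.log2(v)
    return total, n_imputed


def pair_filter(
    site: SiteRecord,
    protein: ProteinRecord | None,
    arm: tuple[str, str],
) -> tuple[bool, str | None]:
    """Keep/exclude decision for one site-arm pair (total function).

    Retained iff <=1 of the 2 acetyl measurements was imputed, <=1 of the
    protein's 2 LFQ measurements was imputed, and the protein is quantified
    at all.  The exclusion reason is recorded.
    """
    exp, ctl = arm
    acetyl = [site.intensity.get(s) for s in (exp, ctl)]
    if any(v is None for v in acetyl):
        return False, BOTH_MISSING
    if sum(site.imputed.get(s, False) for s in (exp, ctl)) > 1:
        return False, BOTH_MISSING
    if protein is None:
        return False, PROTEIN_UNQUANTIFIED
    lfq = [protein.lfq.get(s) for s in (exp, ctl)]
    if any(v is None for v in lfq):
        return False, PROTEIN_UNQUANTIFIED
    if sum(protein.imputed.get(s, False) for s in (exp, ctl)) > 1:
        return False, PROTEIN_UNQUANTIFIED
    return True, None


def compute_changes(
    sites: Sequence[SiteRecord],
    proteins: Sequence[ProteinRecord],
    design: StudyDesign,
    contrasts: Mapping[str, Contrast] | None = None,
) -> pd.DataFrame:
    """Per-(site, comparison) fold changes, raw and protein-normalized.

    Returns one row per site x comparison with linear-scale ratios
    (raw = experimental/control acetyl intensity, protein = the parent
    protein's LFQ ratio, normalized = raw/protein) and the exclusion
    bookkeeping of the pair filter.  ``contrasts`` defaults to the design's
    two arms; the scrambled validation schemes pass composite contrasts,
    for which the <=1-imputed rule applies over the contrast's samples.
    """
    if contrasts is None:
        contrasts = design.contrasts()
    protein_by_accession = {p.protein_accession: p for p in proteins}
    multi_parent = sum(";" in s.protein_accession for s in sites)
    if multi_parent:
        warnings.warn(
            f"{multi_parent} site record(s) list multiple accessions; "
            "the first accession is used as the normalization parent",
            stacklevel=2,
        )
    rows = []
    for record_index, site in enumerate(sites):
        protein = protein_by_accession.get(site.parent_accession)
        for arm_label, contrast in contrasts.items():
            site_log2, n_imputed_acetyl = _contrast_terms(site, contrast)
            excluded, reason = False, None
            raw = protein_ratio = normalized = None
            n_imputed_protein = 0
            if site_log2 is None or n_imputed_acetyl > 1:
                excluded, reason = True, BOTH_MISSING
            elif protein is None:
                excluded, reason = True, PROTEIN_UNQUANTIFIED
            else:
                protein_log2, n_imputed_protein = _contrast_terms(protein, contrast)
                if protein_log2 is None or n_imputed_protein > 1:
                    excluded, reason = True, PROTEIN_UNQUANTIFIED
                else:
                    raw = float(2.0 ** site_log2)
                    protein_ratio = float(2.0 ** protein_log2)
                    normalized = float(2.0 ** (site_log2 - protein_log2))
            rows.append(
                {
                    "record": record_index,
                    "accession": site.parent_accession,
                    "gene": site.gene_symbol or site.parent_accession,
                    "peptide_key": site.peptide_key,
                    "sites": site.site_positions,
                    "arm": arm_label,
                    "raw_ratio": raw,
                    "protein_ratio": protein_ratio,
                    "normalized_ratio": normalized,
                    "n_imputed_acetyl": n_imputed_acetyl,
                    "n_imputed_protein": n_imputed_protein,
                    "excluded": excluded,
                    "reason": reason,
                }
            )
    columns = [
        "record", "accession", "gene", "peptide_key", "sites", "arm",
        "raw_ratio", "protein_ratio", "normalized_ratio",
        "n_imputed_acetyl", "n_imputed_protein", "excluded", "reason",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    frame["arm"] = pd.Categorical(frame["arm"], categories=list(contrasts))
    return frame


def write_changes_table(frame: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write the normalized-change table as UTF-8 TSV (one row per site x arm)."""
    with open(path, "w", encoding="utf-8") as handle:
        if comment:
            handle.write(f"# {comment}\n")
        out = frame.copy()
        out["sites"] = out["sites"].map(lambda t: ";".join(map(str, t)))
        out.to_csv(handle, sep="\t", index=False)


__all__ = [
    "ARMS",
    "ArmChange",
    "BOTH_MISSING",
    "PROTEIN_UNQUANTIFIED",
    "ImputationParams",
    "compute_changes",
    "impute",
    "pair_filter",
    "population_stats",
    "write_changes_table",
]
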