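"""Sliding-threshold false-positive-rate estimation with scrambled nulls.

With a deacetylase manipulated in opposite directions in the two arms, a
site that *decreases* in both comparisons (the -/- sign pattern) is
biologically implausible and is counted as a false positive; every other
two-comparison change beyond the threshold (+/-, -/+, +/+; at least one
comparison increasing) is a potential true positive.  FPR = fp/tp is swept
over a grid of fold thresholds.  Only items with at most one imputed
measurement per comparison are counted.

Two "scrambled" schemes re-run the estimator on pseudo-comparisons that
carry no treatment contrast, as negative controls:

* ``scrambled1`` pairs like samples: control vs. control and experimental
  vs. experimental.
* ``scrambled2a`` / ``scrambled2b`` are second-order contrasts — the
  difference and the sum of the two nonsense log-ratios (``a`` builds them
  from the like-sample pairs, ``b`` from the cross-arm pairs).  Differencing
  is what makes them valid nulls: a plain cross-arm ratio such as
  exp_KD/ctrl_OE still carries the full treatment effect (the two controls
  are exchangeable), so it would reproduce the real scheme rather than
  control it.  Each scrambled scheme either zeroes the treatment loading in
  one pseudo-comparison (scrambled1, scrambled2b) or folds the
  anti-correlated effect into the concordant-decrease false-positive
  quadrant (scrambled2a); none reproduces the real (+, -) pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import KNOCKDOWN, OVEREXPRESSION, Contrast, StudyDesign
from .errors import ValidationError
from .io import ProteinRecord, SiteRecord
from .preprocess import compute_changes

REAL = "real"
SCRAMBLED1 = "scrambled1"
SCRAMBLED2A = "scrambled2a"
SCRAMBLED2B = "scrambled2b"
SCHEMES = (REAL, SCRAMBLED1, SCRAMBLED2A, SCRAMBLED2B)

PEPTIDE = "peptide"
PROTEIN = "protein"

DEFAULT_GRID = np.round(np.arange(1.0, 1.5 + 1e-9, 0.01), 10)


def scrambled_contrasts(design: StudyDesign, scheme: str) -> dict[str, Contrast]:
    """Log2-space pseudo-comparisons for a scrambled scheme.

    Sample roles: kd_exp/kd_ctl are the knockdown arm, oe_exp/oe_ctl the
    overexpression arm.  The returned mapping reuses the two arm labels so
    the downstream machinery is unchanged.
    """
    kd_exp, kd_ctl = design.knockdown
    oe_exp, oe_ctl = design.overexpression
    if scheme == SCRAMBLED1:
        # pairs of like samples: no treatment contrast in either comparison
        return {
            KNOCKDOWN: {oe_ctl: +1.0, kd_ctl: -1.0},
            OVEREXPRESSION: {oe_exp: +1.0, kd_exp: -1.0},
        }
    if scheme == SCRAMBLED2A:
        # difference and sum of the like-pair nonsense ratios
        # (oe_exp/kd_exp) and (oe_ctl/kd_ctl)
        return {
            KNOCKDOWN: {oe_exp: +1.0, kd_exp: -1.0, oe_ctl: -1.0, kd_ctl: +1.0},
            OVEREXPRESSION: {oe_exp: +1.0, kd_exp: -1.0, oe_ctl: +1.0, kd_ctl: -1.0},
        }
    if scheme == SCRAMBLED2B:
        # difference and sum of the cross-pair nonsense ratios
        # (kd_exp/oe_ctl) and (oe_exp/kd_ctl)
        return {
            KNOCKDOWN: {kd_exp: +1.0, oe_ctl: -1.0, oe_exp: -1.0, kd_ctl: +1.0},
            OVEREXPRESSION: {kd_exp: +1.0, oe_ctl: -1.0, oe_exp: +1.0, kd_ctl: -1.0},
        }
    raise ValidationError(f"unknown scrambled scheme {scheme!r}; choose from {SCHEMES[1:]}")


def scrambled_changes(
    sites: Sequence[SiteRecord],
    proteins: Sequence[ProteinRecord],
    design: StudyDesign,
    scheme: str,
) -> pd.DataFrame:
    """Normalized changes under a scrambled pseudo-design (same table layout
    as :func:`acetylome.preprocess.compute_changes`)."""
    return compute_changes(
        sites, proteins, design, contrasts=scrambled_contrasts(design, scheme)
    )


@dataclass
class FprCurve:
    """FP/TP counts and their ratio over an ascending fold-threshold grid."""

    thresholds: np.ndarray
    fp: np.ndarray
    tp: np.ndarray
    scheme: str = REAL
    level: str = PEPTIDE

    @property
    def fpr(self) -> np.ndarray:
        """fp/tp per threshold; NaN where tp = 0 (undefined, never 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(self.tp > 0, self.fp / np.where(self.tp > 0, self.tp, 1), np.nan)
        return out

    def at(self, threshold: float) -> tuple[int, int, float]:
        """(fp, tp, fpr) at the grid point closest to ``threshold``."""
        index = int(np.argmin(np.abs(self.thresholds - threshold)))
        return int(self.fp[index]), int(self.tp[index]), float(self.fpr[index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "fp": self.fp,
                "tp": self.tp,
                "fpr": self.fpr,
                "scheme": self.scheme,
                "level": self.level,
            }
        )


def _arm_log2(changes: pd.DataFrame) -> pd.DataFrame:
    """Wide table of log2 normalized ratios per item, both arms retained."""
    kept = changes[~changes["excluded"]].copy()
    kept["log2_norm"] = np.log2(kept["normalized_ratio"].astype(float))
    wide = kept.pivot_table(
        index="record", columns="arm", values="log2_norm", aggfunc="first",
        observed=True,
    )
    if KNOCKDOWN not in wide.columns or OVEREXPRESSION not in wide.columns:
        return pd.DataFrame(columns=[KNOCKDOWN, OVEREXPRESSION, "gene"])
    wide = wide.dropna(subset=[KNOCKDOWN, OVEREXPRESSION])
    genes = changes.groupby("record")["gene"].first().str.upper()
    wide["gene"] = genes.reindex(wide.index)
    return wide


def fpr_curve(
    changes: pd.DataFrame,
    thresholds: Sequence[float] | np.ndarray = DEFAULT_GRID,
    level: str = PEPTIDE,
    scheme: str = REAL,
) -> FprCurve:
    """Sweep the fold threshold and count -/- (fp) vs. +/-, -/+, +/+ (tp).

    An item qualifies at threshold t when its |change| exceeds t-fold in
    BOTH comparisons (strict) and its comparisons passed the imputation
    filter.  At the protein level a pattern qualifies via the any-site rule:
    the protein qualifies when each arm has some site beyond t, and it is a
    false positive when no qualifying site increases in either arm.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or len(thresholds) == 0:
        raise ValidationError("threshold grid must be a non-empty 1-D array")
    if np.any(np.diff(thresholds) <= 0):
        raise ValidationError("threshold grid must be strictly ascending")
    if np.any(thresholds < 1.0):
        raise ValidationError("fold thresholds must be >= 1")
    if level not in (PEPTIDE, PROTEIN):
        raise ValidationError(f"level must be {PEPTIDE!r} or {PROTEIN!r}")

    wide = _arm_log2(changes)
    kd = wide[KNOCKDOWN].to_numpy(dtype=float)
    oe = wide[OVEREXPRESSION].to_numpy(dtype=float)
    log_t = np.log2(thresholds)

    fp = np.zeros(len(thresholds), dtype=int)
    tp = np.zeros(len(thresholds), dtype=int)
    if level == PEPTIDE:
        for i, lt in enumerate(log_t):
            beyond = (np.abs(kd) > lt) & (np.abs(oe) > lt)
            both_down = beyond & (kd < -lt) & (oe < -lt)
            fp[i] = int(both_down.sum())
            tp[i] = int(beyond.sum() - both_down.sum())
    else:
        groups = wide.groupby("gene")
        max_abs_kd = groups[KNOCKDOWN].agg(lambda s: np.max(np.abs(s))).to_numpy()
        max_abs_oe = groups[OVEREXPRESSION].agg(lambda s: np.max(np.abs(s))).to_numpy()
        max_kd = groups[KNOCKDOWN].max().to_numpy()
        max_oe = groups[OVEREXPRESSION].max().to_numpy()
        for i, lt in enumerate(log_t):
            qualifies = (max_abs_kd > lt) & (max_abs_oe > lt)
            has_up = (max_kd > lt) | (max_oe > lt)
            fp[i] = int((qualifies & ~has_up).sum())
            tp[i] = int((qualifies & has_up).sum())
    return FprCurve(thresholds=thresholds, fp=fp, tp=tp, scheme=scheme, level=level)
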