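"""Fisher-exact over-representation analysis against gene-set collections.

The background universe is the set of proteins quantified in the
experiment (not the whole proteome): enrichment asks whether a hit list
over-represents a gene set *among what was measurable*.  The test is
one-sided (over-representation only); Benjamini-Hochberg q-values are
provided as standard multiple-testing hygiene over all tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import GeneSetCollection


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation evidence."""

    term_id: str
    description: str
    k: int  # overlap of hits with the term, within the background
    n: int  # hit-list size
    K: int  # term size within the background
    N: int  # background size
    fold: float  # (k/n) / (K/N)
    p: float  # one-sided Fisher exact (hypergeometric upper tail)
    q: float  # Benjamini-Hochberg adjusted


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonicity enforced)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrich(
    hits: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of a hit list in each gene set, vs. the
    experiment-wide background.

    Set members are intersected with the background before testing; terms
    with zero overlap are excluded (their p would be 1).  Returns one row
    per tested term, sorted by p, with a ``significant`` flag at ``alpha``
    on the raw p-value.
    """
    background_set = {g.upper() for g in background}
    if not background_set:
        raise ValidationError("the background universe must be non-empty")
    hit_set = {g.upper() for g in hits}
    offenders = sorted(hit_set - background_set)
    if offenders:
        raise ValidationError(
            "hits must be a subset of the background; offenders: " + ", ".join(offenders)
        )
    N = len(background_set)
    n = len(hit_set)
    rows = []
    for gene_set in sets:
        members = {m for m in gene_set.members if m in background_set}
        K = len(members)
        if K == 0:
            continue
        k = len(members & hit_set)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n else float("nan")
        rows.append(
            {
                "term_id": gene_set.term_id,
                "description": gene_set.description,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold": fold,
                "p": p,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["term_id", "description", "k", "n", "K", "N", "fold", "p"]
    )
    if not frame.empty:
        frame["q"] = bh_adjust(frame["p"])
        frame = frame.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        frame["q"] = pd.Series(dtype=float)
    frame["significant"] = frame["p"] < alpha
    return frame
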