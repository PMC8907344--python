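"""Shared construction helpers for the test suite."""

from __future__ import annotations

import pandas as pd

from acetylome import KNOCKDOWN, OVEREXPRESSION


def make_changes(rows: list[tuple]) -> pd.DataFrame:
    """Build a normalized-change table from (record, gene, kd_ratio, oe_ratio).

    A ratio of None marks the pair as excluded in that arm.
    """
    out = []
    for record, gene, kd, oe in rows:
        for arm, ratio in ((KNOCKDOWN, kd), (OVEREXPRESSION, oe)):
            out.append(
                {
                    "record": record,
                    "accession": f"ACC{record}",
                    "gene": gene,
                    "peptide_key": f"PEP{record}@1",
                    "sites": (1,),
                    "arm": arm,
                    "raw_ratio": ratio,
                    "protein_ratio": 1.0 if ratio is not None else None,
                    "normalized_ratio": ratio,
                    "n_imputed_acetyl": 0,
                    "n_imputed_protein": 0,
                    "excluded": ratio is None,
                    "reason": None if ratio is not None else "both_missing",
                }
            )
    columns = [
        "record", "accession", "gene", "peptide_key", "sites", "arm",
        "raw_ratio", "protein_ratio", "normalized_ratio",
        "n_imputed_acetyl", "n_imputed_protein", "excluded", "reason",
    ]
    frame = pd.DataFrame(out, columns=columns)
    frame["arm"] = pd.Categorical(frame["arm"], categories=[KNOCKDOWN, OVEREXPRESSION])
    if frame.empty:
        frame["excluded"] = frame["excluded"].astype(bool)
    return frame
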