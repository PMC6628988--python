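"""Gene-level candidate calling with the replicate-consistency rule.

No multiple-testing correction is applied at the guide level; requiring at
least ``min_sgrnas`` guides below the significance threshold in every
biological replicate is the error control.  Under a null with 8 guides per
gene and alpha = 0.05, a gene passes one replicate with probability
P(Binom(8, 0.05) >= 3) ~ 5.8e-3, so two independent replicates push the
per-gene false-call rate to ~3e-5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import SgRNARecord

__all__ = ["GeneCallResult", "call_candidate_genes", "intersect_candidates"]

DEFAULT_MIN_SGRNAS = 3
DEFAULT_ALPHA_LEVEL = 0.05


@dataclass(frozen=True)
class GeneCallResult:
    gene_id: str
    is_control: bool
    n_sgrnas: int
    n_significant: dict  # replicate_id -> count of guides with p < alpha
    is_candidate: bool
    rank_score: float


def call_candidate_genes(
    scores: Mapping[str, pd.DataFrame],
    library: Sequence[SgRNARecord],
    min_sgrnas: int = DEFAULT_MIN_SGRNAS,
    alpha_level: float = DEFAULT_ALPHA_LEVEL,
    min_replicates: int | None = None,
) -> pd.DataFrame:
    """Call genes whose guides are consistently enriched across replicates.

    ``scores`` maps replicate_id to a per-sgRNA frame (indexed by
    sgrna_id, with a ``p`` column) as produced by the scoring module.  A
    gene is a candidate when at least ``min_sgrnas`` of its guides have
    p < ``alpha_level`` (strict) in at least ``min_replicates`` replicates
    (default: all of them).  Negative-control genes are called like any
    other and reported with their flag as a sanity channel.

    Returns a frame with one row per gene: gene_id, is_control, n_sgrnas,
    n_significant_<replicate> per replicate, is_candidate and a rank score
    (reported for convenience; the method itself defines no ranking).
    """
    if not (0 < alpha_level < 1):
        raise ValueError("alpha_level must be in (0, 1)")
    if min_sgrnas < 1:
        raise ValueError("min_sgrnas must be >= 1")
    if len(scores) < 2:
        raise ValueError("need scores for at least 2 replicates")
    replicate_ids = sorted(scores)
    if min_replicates is None:
        min_replicates = len(replicate_ids)
    if not (1 <= min_replicates <= len(replicate_ids)):
        raise ValueError("min_replicates out of range")

    ref_index = scores[replicate_ids[0]].index
    for rid in replicate_ids[1:]:
        if set(scores[rid].index) != set(ref_index):
            raise ValueError("replicate score sets cover different sgRNA sets")

    lib = pd.DataFrame(
        {
            "sgrna_id": [r.sgrna_id for r in library],
            "gene_id": [r.gene_id for r in library],
            "is_control": [r.is_negative_control for r in library],
        }
    ).set_index("sgrna_id")
    missing = ref_index.difference(lib.index)
    if len(missing):
        raise ValueError(f"scored sgRNAs absent from library: {list(missing)[:5]}")
    lib = lib.loc[ref_index]

    genes = lib.groupby("gene_id", sort=True)
    rows = []
    for gene_id, members in genes:
        if len(members) == 0:
            raise ValueError(f"gene {gene_id!r} has zero sgRNAs in scores")
        sig = {}
        neglogp_sums = []
        for rid in replicate_ids:
            p = scores[rid].loc[members.index, "p"].to_numpy(dtype=float)
            sig[rid] = int(np.sum(p < alpha_level))
            top = np.sort(p)[:min_sgrnas]
            neglogp_sums.append(float(np.sum(-np.log10(np.clip(top, 1e-300, None)))))
        n_pass = sum(1 for rid in replicate_ids if sig[rid] >= min_sgrnas)
        row = {
            "gene_id": gene_id,
            "is_control": bool(members["is_control"].iloc[0]),
            "n_sgrnas": len(members),
        }
        for rid in replicate_ids:
            row[f"n_significant_{rid}"] = sig[rid]
        row["is_candidate"] = n_pass >= min_replicates
        row["rank_score"] = min(sig.values()) + min(neglogp_sums) / 1e6
        rows.append(row)
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["rank_score", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return out


def intersect_candidates(set_a, set_b) -> list[str]:
    """Exact intersection of two candidate gene-id sets, sorted lexicographically."""
    return sorted(set(set_a) & set(set_b))
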