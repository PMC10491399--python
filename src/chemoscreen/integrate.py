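"""Multi-screen integration: Fisher-combined p-values, BH FDR, hit classes.

Per-screen gene results (signed score + empirical p) from independent
inhibitor screens on the same library are merged into one ranking: the
mean score across screens sets the direction (negative = enhancer,
positive = suppressor), Fisher's method (-2 sum ln p ~ chi2 with 2k df)
combines the per-screen p-values, and Benjamini-Hochberg step-up converts
combined p-values to FDR q-values. Hits are classified at a reporting
threshold (default FDR < 0.05); a stricter cut (FDR < 0.001) conventionally
feeds the network-connectivity test. Fisher's method assumes independence
across screens; three different inhibitors screened on one library are
treated as independent, an approximation documented in the methods note.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_HIT_FDR = 0.05
DEFAULT_NETWORK_FDR = 0.001

RESULT_COLUMNS = ("gene", "mean_score", "combined_p", "fdr", "hit_class",
                  "rank", "n_screens_scored", "discordant")


def fisher_combine(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's method: returns (chi2 statistic, combined upper-tail p).

    chi2 = -2 sum ln p_i on 2k degrees of freedom. p-values must lie in
    (0, 1]; empirical add-one p-values can never be 0.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("fisher_combine needs at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    res = stats.combine_pvalues(p, method="fisher")
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def combine_screens(
    results: Sequence[pd.DataFrame],
    fdr_threshold: float = DEFAULT_HIT_FDR,
) -> pd.DataFrame:
    """Merge per-screen gene tables into the final cross-screen ranking.

    Genes are aligned by symbol (outer union); a gene scored in a subset of
    screens is combined over the screens where it was scored (Fisher df =
    2 x available). Output columns: per-screen score_/p_ pairs, mean_score,
    combined_p, fdr, hit_class in {enhancer, suppressor, none}, within-class
    rank (1 = most extreme |mean_score|), n_screens_scored and a
    ``discordant`` flag for genes whose screens disagree on sign. Sorted by
    mean_score ascending; invariant to the order screens are supplied in.
    """
    if not results:
        raise ValidationError("combine_screens needs at least one screen")
    if not 0.0 < fdr_threshold < 1.0:
        raise ValidationError("fdr_threshold must lie in (0, 1)")
    per_screen = {}
    for res in results:
        missing = {"gene", "score", "p_value", "screen_id"} - set(res.columns)
        if missing:
            raise ValidationError(f"screen table missing column(s): {missing}")
        sid = res["screen_id"].iloc[0]
        if sid in per_screen:
            raise ValidationError(f"duplicate screen_id {sid!r}")
        per_screen[sid] = res.set_index("gene")
    screen_ids = sorted(per_screen)

    genes = sorted(set().union(*(df.index for df in per_screen.values())))
    scores = pd.DataFrame(
        {sid: per_screen[sid]["score"].reindex(genes) for sid in screen_ids}
    )
    pvals = pd.DataFrame(
        {sid: per_screen[sid]["p_value"].reindex(genes) for sid in screen_ids}
    )

    mean_score = scores.mean(axis=1, skipna=True)
    n_scored = scores.notna().sum(axis=1)
    combined = np.empty(len(genes))
    for i, g in enumerate(genes):
        avail = pvals.loc[g].dropna()
        combined[i] = fisher_combine(avail.to_numpy())[1]
    fdr = bh_fdr(combined)

    sign = np.sign(scores)
    discordant = ((sign.max(axis=1, skipna=True) > 0)
                  & (sign.min(axis=1, skipna=True) < 0))

    hit_class = np.where(
        fdr < fdr_threshold,
        np.where(mean_score < 0, "enhancer",
                 np.where(mean_score > 0, "suppressor", "none")),
        "none",
    )

    out = pd.DataFrame({"gene": genes, "mean_score": mean_score.to_numpy(),
                        "combined_p": combined, "fdr": fdr,
                        "hit_class": hit_class,
                        "n_screens_scored": n_scored.to_numpy(),
                        "discordant": discordant.to_numpy()})
    for sid in screen_ids:
        out[f"score_{sid}"] = scores[sid].to_numpy()
        out[f"p_{sid}"] = pvals[sid].to_numpy()

    out["rank"] = 0
    for cls in ("enhancer", "suppressor"):
        mask = out["hit_class"] == cls
        if mask.any():
            out.loc[mask, "rank"] = (
                (-out.loc[mask, "mean_score"].abs())
                .rank(method="first").astype(int)
            )
    return out.sort_values("mean_score", kind="mergesort").reset_index(drop=True)


def hit_genes(table: pd.DataFrame, fdr_threshold: float = DEFAULT_NETWORK_FDR) -> set[str]:
    """Genes (enhancers and suppressors) passing an FDR cut, for network tests."""
    mask = (table["fdr"] < fdr_threshold) & (table["hit_class"] != "none")
    return set(table.loc[mask, "gene"])
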