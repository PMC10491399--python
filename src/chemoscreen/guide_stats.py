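"""Per-guide treated-vs-control statistics and gene essentiality binning.

A screen's raw observable is the guide read-count matrix; the scoring
statistic consumes depth-normalized (counts-per-million) log2 ratios of the
treated over the pooled control sample, with a small pseudocount to keep
dropout guides finite. Essentiality — a gene's fitness cost in the
*untreated* condition — is summarized per gene and discretized into
contiguous quantile bins; the scoring module draws its control pseudo-genes
from guides targeting other genes in the same bin, so that genes are judged
against peers of similar essentiality rather than the whole library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import CountMatrix, GuideLibrary

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.5  # CPM
DEFAULT_N_BINS = 20


def normalize_cpm(cm: CountMatrix) -> pd.DataFrame:
    """Scale every column to 1e6 total (counts per million).

    Returns a float DataFrame indexed by guide_id with one column per
    sample. Raises on all-zero columns, which have no defined depth.
    """
    totals = cm.counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = [cm.samples[j].sample_id for j in np.flatnonzero(zero)]
        raise ValidationError(f"all-zero count column(s): {', '.join(bad)}")
    cpm = cm.counts / totals * 1e6
    return pd.DataFrame(cpm, index=pd.Index(cm.guides, name="guide_id"),
                        columns=cm.sample_ids)


def _single_sample(cm: CountMatrix, screen_id: str | None, arm: str) -> str:
    samples = cm.select(screen_id=screen_id, arm=arm)
    if len(samples) != 1:
        where = f"screen {screen_id!r}" if screen_id else "count matrix"
        raise ConfigurationError(
            f"{where} has {len(samples)} {arm} sample(s); pool to exactly one "
            f"before computing log-ratios"
        )
    return samples[0].sample_id


def guide_log_ratios(
    cm: CountMatrix,
    library: GuideLibrary,
    screen_id: str | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-guide log2((treated_cpm + eps) / (control_cpm + eps)) table.

    Requires exactly one pooled control and one treated sample for the
    screen. Columns: gene, control_norm, treated_norm, log_ratio; indexed
    by guide_id in library order.
    """
    control_id = _single_sample(cm, screen_id, "control")
    treated_id = _single_sample(cm, screen_id, "treated")
    cpm = normalize_cpm(cm)
    control = cpm[control_id].to_numpy()
    treated = cpm[treated_id].to_numpy()
    log_ratio = np.log2((treated + pseudocount) / (control + pseudocount))
    return pd.DataFrame(
        {
            "gene": library.gene_of.reindex(cpm.index).to_numpy(),
            "control_norm": control,
            "treated_norm": treated,
            "log_ratio": log_ratio,
        },
        index=cpm.index,
    )


@dataclass(frozen=True)
class EssentialityIndex:
    """Gene essentiality scores (lower = more essential) and quantile bins."""

    frame: pd.DataFrame  # index gene; columns: score, bin
    n_bins: int

    @cached_property
    def bin_of(self) -> pd.Series:
        return self.frame["bin"]

    def genes_in_bin(self, b: int) -> list[str]:
        return self.frame.index[self.frame["bin"] == b].tolist()

    @property
    def bins(self) -> list[int]:
        return sorted(self.frame["bin"].unique().tolist())


def _quantile_bins(scores: pd.Series, n_bins: int) -> pd.Series:
    if scores.nunique() == 1:
        logger.warning("all essentiality scores identical; using a single bin")
        return pd.Series(0, index=scores.index, dtype=int)
    binned = pd.qcut(scores, q=n_bins, labels=False, duplicates="drop")
    got = int(binned.nunique())
    if got < n_bins:
        logger.warning("ties reduced essentiality bins from %d to %d", n_bins, got)
    return binned.astype(int)


def essentiality_index(
    gene_scores: pd.Series | pd.DataFrame,
    n_bins: int = DEFAULT_N_BINS,
    external: pd.Series | None = None,
) -> EssentialityIndex:
    """Assign every gene an essentiality score and a contiguous quantile bin.

    ``gene_scores`` is either a per-gene score Series (lower = more
    essential, e.g. mean control-arm guide depletion) or a guide-level
    table with ``gene`` and ``log_ratio`` columns from a control-vs-
    reference comparison, which is averaged per gene. When an ``external``
    gene -> score table (e.g. a published essentiality ranking) is
    supplied, covered genes are binned by the external score and uncovered
    genes fall back to their internal depletion bin, with a log message.
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    if isinstance(gene_scores, pd.DataFrame):
        if not {"gene", "log_ratio"}.issubset(gene_scores.columns):
            raise ValidationError(
                "guide-level table must have 'gene' and 'log_ratio' columns"
            )
        scores = gene_scores.groupby("gene")["log_ratio"].mean()
    else:
        scores = gene_scores.astype(float).copy()
    if scores.isna().any():
        raise ValidationError("essentiality scores contain NaN")
    if len(scores) < n_bins:
        raise ConfigurationError(
            f"{len(scores)} genes cannot fill {n_bins} essentiality bins"
        )
    bins = _quantile_bins(scores, n_bins)
    if external is not None:
        covered = external.index.intersection(scores.index)
        uncovered = scores.index.difference(covered)
        if len(covered) >= n_bins:
            ext_bins = _quantile_bins(external.loc[covered].astype(float), n_bins)
            bins.loc[covered] = ext_bins
            scores.loc[covered] = external.loc[covered].astype(float)
            if len(uncovered):
                logger.info(
                    "%d gene(s) not covered by the external essentiality table; "
                    "using control-depletion fallback", len(uncovered),
                )
        else:
            logger.warning(
                "external essentiality table covers only %d genes (< %d bins); "
                "ignored", len(covered), n_bins,
            )
    frame = pd.DataFrame({"score": scores, "bin": bins})
    frame.index.name = "gene"
    return EssentialityIndex(frame, n_bins)


def essentiality_from_control(
    cm: CountMatrix,
    library: GuideLibrary,
    screen_id: str | None = None,
    n_bins: int = DEFAULT_N_BINS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    reference_sample: str | None = None,
    external: pd.Series | None = None,
) -> EssentialityIndex:
    """Essentiality bins from the screen's own pooled control arm.

    With a ``reference_sample`` (e.g. a pre-treatment timepoint) the score
    is the gene-mean log2(control/reference) depletion; without one, the
    log2 control abundance itself is used — in a library introduced at
    near-uniform representation, control abundance ranks genes by
    depletion, and binning depends only on ranks.
    """
    control_id = _single_sample(cm, screen_id, "control")
    cpm = normalize_cpm(cm)
    control = cpm[control_id].to_numpy()
    if reference_sample is not None:
        ref = cpm[reference_sample].to_numpy()
        guide_score = np.log2((control + pseudocount) / (ref + pseudocount))
    else:
        guide_score = np.log2(control + pseudocount)
    per_gene = pd.DataFrame(
        {"gene": library.gene_of.reindex(cpm.index).to_numpy(),
         "log_ratio": guide_score},
        index=cpm.index,
    )
    return essentiality_index(per_gene, n_bins=n_bins, external=external)
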