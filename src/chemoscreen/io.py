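"""File formats and count-pooling rules for pooled CRISPR screens.

This module defines the in-memory containers the rest of the pipeline
consumes — the guide library annotation, sample metadata, the guide × sample
read-count matrix, protein-interaction networks (as :class:`networkx.Graph`)
and gene-set collections — together with tab-separated readers/writers and
the two pooling operations applied to raw screen counts:

* **lane pooling** — read counts from different sequencing lanes of the same
  biological sample are summed;
* **control pooling** — all control-arm samples and timepoints of a screen
  (DMSO-treated or untreated alike) are summed into a single control column,
  which increases statistical power because solvent alone leaves no
  signature in the counts.

All TSVs are UTF-8 with a mandatory header row; gene symbols are treated as
case-sensitive opaque strings and never alias-resolved.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from collections.abc import Mapping
from dataclasses import dataclass, replace
from functools import cached_property
from pathlib import Path
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

ARMS = ("control", "treated")

#: sample-metadata fields that define one biological sample across lanes
POOL_KEY = ("screen_id", "arm", "compound", "concentration", "timepoint")

_LIBRARY_REQUIRED = ("guide_id", "spacer", "gene")
_TRUE_STRINGS = {"1", "true", "yes"}


# ---------------------------------------------------------------------------
# guide library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideLibrary:
    """Annotation of a pooled sgRNA library.

    One row per guide: unique ``guide_id``, nucleotide ``spacer``, target
    ``gene`` symbol and an ``is_control`` flag for neutral-locus guides
    (e.g. AAVS1- or Azami-green-targeting constructs).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _LIBRARY_REQUIRED if c not in self.frame.columns]
        if missing:
            raise FormatError(f"library is missing column(s): {', '.join(missing)}")
        f = self.frame.copy()
        if "is_control" not in f.columns:
            f["is_control"] = False
        f["is_control"] = f["is_control"].astype(bool)
        f = f.loc[:, ["guide_id", "spacer", "gene", "is_control"]].reset_index(drop=True)
        dup = f["guide_id"][f["guide_id"].duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate guide_id(s): {', '.join(map(str, dup))}")
        if (f["gene"].astype(str).str.len() == 0).any() or f["gene"].isna().any():
            raise ValidationError("every guide must map to exactly one non-empty gene")
        object.__setattr__(self, "frame", f)

    @property
    def n_guides(self) -> int:
        return len(self.frame)

    @cached_property
    def guide_ids(self) -> np.ndarray:
        return self.frame["guide_id"].to_numpy()

    @cached_property
    def gene_of(self) -> pd.Series:
        """gene symbol indexed by guide_id, in library order."""
        return pd.Series(
            self.frame["gene"].to_numpy(), index=self.frame["guide_id"].to_numpy()
        )

    @cached_property
    def genes(self) -> list[str]:
        """Unique gene symbols in first-occurrence order (controls included)."""
        return list(dict.fromkeys(self.frame["gene"]))

    @cached_property
    def control_genes(self) -> frozenset[str]:
        """Genes all of whose guides are flagged as controls."""
        by_gene = self.frame.groupby("gene", sort=False)["is_control"].all()
        return frozenset(by_gene.index[by_gene])

    @cached_property
    def target_genes(self) -> list[str]:
        return [g for g in self.genes if g not in self.control_genes]

    @cached_property
    def guide_indices(self) -> dict[str, np.ndarray]:
        """Row positions of each gene's guides within the library order."""
        return {
            g: idx.to_numpy()
            for g, idx in self.frame.groupby("gene", sort=False).groups.items()
        }


def read_library(path: str | Path) -> GuideLibrary:
    """Read a guide-library TSV (columns guide_id, spacer, gene[, is_control])."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"library file is empty: {path}") from None
    missing = [c for c in _LIBRARY_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(
            f"library file {path} is missing column(s): {', '.join(missing)}"
        )
    if "is_control" in df.columns:
        df["is_control"] = (
            df["is_control"].fillna("").str.strip().str.lower().isin(_TRUE_STRINGS)
        )
    return GuideLibrary(df)


def write_library(lib: GuideLibrary, path: str | Path) -> None:
    lib.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced sample (one column of a count matrix)."""

    sample_id: str
    screen_id: str
    arm: str
    compound: str = ""
    concentration: str = ""
    lane: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(
                f"sample {self.sample_id!r}: arm must be one of {ARMS}, got {self.arm!r}"
            )

    @property
    def pool_key(self) -> tuple[str, ...]:
        return tuple(getattr(self, k) for k in POOL_KEY)


_META_COLUMNS = ("sample_id", "screen_id", "arm", "compound", "concentration",
                 "lane", "timepoint")


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV; optional columns default to empty strings."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        raise FormatError(f"sample metadata file is empty: {path}") from None
    for col in ("sample_id", "screen_id", "arm"):
        if col not in df.columns:
            raise FormatError(f"sample metadata {path} is missing column: {col}")
    for col in _META_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    dup = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate sample_id(s): {', '.join(dup)}")
    return [SampleMeta(**{c: row[c] for c in _META_COLUMNS}) for _, row in df.iterrows()]


def write_sample_meta(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame([{c: getattr(s, c) for c in _META_COLUMNS} for s in samples]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Non-negative integer guide × sample read counts.

    Rows follow the library's guide order; columns follow ``samples``.
    """

    guides: np.ndarray
    samples: list[SampleMeta]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.guides = np.asarray(self.guides, dtype=object)
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.shape != (len(self.guides), len(self.samples)):
            raise ValidationError(
                f"count shape {self.counts.shape} does not match "
                f"{len(self.guides)} guides x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_ids in count matrix")

    # -- accessors ---------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        for j, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return j
        raise KeyError(sample_id)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample_id)]

    def select(self, screen_id: str | None = None, arm: str | None = None) -> list[SampleMeta]:
        out = self.samples
        if screen_id is not None:
            out = [s for s in out if s.screen_id == screen_id]
        if arm is not None:
            out = [s for s in out if s.arm == arm]
        return out

    def screen_ids(self) -> list[str]:
        return list(dict.fromkeys(s.screen_id for s in self.samples))

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        js = [self.sample_index(sid) for sid in sample_ids]
        return CountMatrix(self.guides, [self.samples[j] for j in js],
                           self.counts[:, js].copy())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "guide_id", self.guides)
        return df


def read_counts(
    path: str | Path, library: GuideLibrary, meta: Sequence[SampleMeta]
) -> CountMatrix:
    """Read a counts TSV and align rows to the library's guide order.

    Guides present in the library but absent from the file get zero counts
    (pooled-screen dropouts are expected) with a logged warning; guides or
    sample columns unknown to the library/metadata are rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise FormatError(f"counts file is empty: {path}") from None
    if df.columns[0] != "guide_id":
        raise FormatError(f"counts file {path}: first column must be guide_id")
    by_id = {m.sample_id: m for m in meta}
    unknown_samples = [c for c in df.columns[1:] if c not in by_id]
    if unknown_samples:
        raise ValidationError(
            f"sample column(s) absent from metadata: {', '.join(unknown_samples)}"
        )
    file_guides = df["guide_id"].astype(str)
    dup = file_guides[file_guides.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate guide rows: {', '.join(dup)}")
    lib_ids = set(library.guide_ids.tolist())
    unknown_guides = [g for g in file_guides if g not in lib_ids]
    if unknown_guides:
        raise ValidationError(
            f"guide(s) absent from library: {', '.join(unknown_guides[:10])}"
        )
    df = df.set_index("guide_id")
    for col in df.columns:
        vals = df[col]
        if not pd.api.types.is_numeric_dtype(vals):
            bad = vals.index[pd.to_numeric(vals, errors="coerce").isna()][0]
            raise ValidationError(
                f"non-numeric count at guide {bad!r}, sample {col!r}: {vals.loc[bad]!r}"
            )
        arr = vals.to_numpy()
        frac = np.mod(arr, 1) != 0
        if frac.any():
            bad = vals.index[frac][0]
            raise ValidationError(
                f"non-integer count at guide {bad!r}, sample {col!r}: {vals.loc[bad]}"
            )
        neg = arr < 0
        if neg.any():
            bad = vals.index[neg][0]
            raise ValidationError(
                f"negative count at guide {bad!r}, sample {col!r}: {vals.loc[bad]}"
            )
    aligned = df.reindex(library.guide_ids)
    n_missing = int(aligned.isna().any(axis=1).sum())
    if n_missing:
        logger.warning(
            "%d library guide(s) absent from %s; counts set to 0", n_missing, path
        )
        aligned = aligned.fillna(0)
    samples = [by_id[c] for c in df.columns]
    return CountMatrix(library.guide_ids.copy(), samples,
                       aligned.to_numpy().astype(np.int64))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def pool_lanes(cm: CountMatrix) -> CountMatrix:
    """Sum read counts across sequencing lanes of the same biological sample.

    Samples sharing (screen, arm, compound, concentration, timepoint) but
    differing in lane collapse to a single column whose counts are the
    element-wise sum; the grand total read count is conserved.
    """
    groups: OrderedDict[tuple, list[int]] = OrderedDict()
    for j, s in enumerate(cm.samples):
        groups.setdefault(s.pool_key, []).append(j)
    samples: list[SampleMeta] = []
    cols: list[np.ndarray] = []
    for js in groups.values():
        if len(js) == 1:
            samples.append(cm.samples[js[0]])
            cols.append(cm.counts[:, js[0]])
        else:
            members = [cm.samples[j] for j in js]
            pooled_id = "+".join(m.sample_id for m in members)
            logger.info("pooling lanes %s -> %s",
                        [m.sample_id for m in members], pooled_id)
            samples.append(replace(members[0], sample_id=pooled_id, lane="pooled"))
            cols.append(cm.counts[:, js].sum(axis=1))
    return CountMatrix(cm.guides.copy(), samples, np.column_stack(cols))


def pool_controls(cm: CountMatrix, screen_id: str) -> CountMatrix:
    """Sum all control-arm samples and timepoints of one screen into one column.

    DMSO-treated and untreated controls are pooled together; treated columns
    are untouched. Raises :class:`ConfigurationError` if the screen has no
    control sample.
    """
    ctrl = [j for j, s in enumerate(cm.samples)
            if s.screen_id == screen_id and s.arm == "control"]
    if not ctrl:
        raise ConfigurationError(f"screen {screen_id!r} has no control samples")
    if len(ctrl) == 1:
        return cm
    pooled = SampleMeta(
        sample_id=f"{screen_id}:control", screen_id=screen_id, arm="control",
        compound="", concentration="", lane="pooled", timepoint="pooled",
    )
    logger.info("pooling %d control samples of screen %s", len(ctrl), screen_id)
    samples: list[SampleMeta] = []
    cols: list[np.ndarray] = []
    first = ctrl[0]
    for j, s in enumerate(cm.samples):
        if j == first:
            samples.append(pooled)
            cols.append(cm.counts[:, ctrl].sum(axis=1))
        elif j in ctrl:
            continue
        else:
            samples.append(s)
            cols.append(cm.counts[:, j])
    return CountMatrix(cm.guides.copy(), samples, np.column_stack(cols))


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

def read_network(path: str | Path, keep_isolated: bool = True) -> nx.Graph:
    """Read an undirected protein-interaction network from an edge-list TSV.

    Self-loops are dropped with a warning (their node is retained as an
    isolated, degree-0 node when ``keep_isolated``); duplicate edges in
    either orientation collapse to one.
    """
    g: nx.Graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(
                    f"{path}: line {lineno}: expected two tab-separated gene symbols"
                )
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                logger.warning("%s: line %d: self-loop on %s dropped", path, lineno, a)
                if keep_isolated:
                    g.add_node(a)
                continue
            g.add_edge(a, b)
    return g


def write_network(g: nx.Graph, path: str | Path) -> None:
    """Write edges in canonical (lexicographically sorted) order."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]


class GeneSetCollection(Mapping):
    """Ordered mapping term_id -> :class:`GeneSet` with unique, non-empty sets."""

    def __init__(self, sets: Sequence[GeneSet]):
        self._sets: OrderedDict[str, GeneSet] = OrderedDict()
        for s in sets:
            if s.term_id in self._sets:
                raise ValidationError(f"duplicate term_id: {s.term_id}")
            if not s.members:
                raise ValidationError(f"term {s.term_id} has no members")
            self._sets[s.term_id] = s

    def __getitem__(self, term_id: str) -> GeneSet:
        return self._sets[term_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: term, description, members... (tab-separated)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need term, description "
                    f"and at least one member"
                )
            members = frozenset(p for p in parts[2:] if p)
            if not members:
                raise FormatError(f"{path}: line {lineno}: empty member list")
            sets.append(GeneSet(parts[0], parts[1], members))
    return GeneSetCollection(sets)
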