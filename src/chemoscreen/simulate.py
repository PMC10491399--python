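"""Generative model for pooled CRISPR knockout screen counts.

The simulator emulates the statistics of a drug-modifier screen: a library
of ~10 guides per gene is introduced into a cell pool at a fixed bottleneck
(default 100 cells per guide), the pool grows exponentially with periodic
passage bottlenecks (multinomial resampling — genetic drift), and terminal
guide abundances are read out by multinomial sequencing. Each guide's
per-doubling log2 growth deviation is

    phi_g = efficiency_g * (fitness_gene + interaction_effect_gene_in_arm)

so essential genes deplete in both arms, while planted enhancers (negative
interaction effect) deplete and suppressors (positive) enrich only under
drug. Crucially, the treated arm undergoes *fewer* population doublings
than the control arm (drug growth inhibition). Because essential-gene
guides lose ground in proportion to doublings elapsed, this inflates their
treated/control ratios by phi_g * (D_treated - D_control) even with no
drug interaction at all — the confound that essentiality-matched scoring
must remove.

Guide efficiencies follow a Beta distribution (default Beta(5, 1)),
reflecting frequent partial/heterozygous editing. With identical seeds the
simulator is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    CountMatrix,
    GuideLibrary,
    SampleMeta,
    read_counts,
    read_library,
    read_sample_meta,
    write_counts,
    write_library,
    write_sample_meta,
)

logger = logging.getLogger(__name__)

INTERACTION_CLASSES = ("enhancer", "suppressor", "none")
CONTROL_GENE = "CTRL"


@dataclass
class SimConfig:
    """Parameters of one simulated multi-screen experiment.

    Defaults encode the screen design the simulator emulates: 8 population
    doublings in the control arm (one per day over 8 days of drug
    exposure), reseeding every other day (4 passage intervals), a
    bottleneck of 100 cells per guide, and ~100 reads per guide of
    sequencing depth. ``treated_doublings`` below ``control_doublings``
    encodes drug growth inhibition; it may be a single value or one value
    per screen.
    """

    n_genes: int = 1000
    guides_per_gene: int = 10
    n_control_guides: int = 100
    frac_essential: float = 0.2
    essential_fitness: float = -0.3  # log2 per doubling, negative = cost
    n_enhancers: int = 0
    n_suppressors: int = 0
    interaction_effect: float = 0.3  # magnitude; sign set by class
    guide_efficiency_alpha: float = 5.0
    guide_efficiency_beta: float = 1.0  # beta == 0 -> all efficiencies 1.0
    essentiality_prior_sd: float = 0.05  # noise on the prior-screen ranking
    control_doublings: float = 8.0
    treated_doublings: float | tuple[float, ...] = 5.0
    bottleneck_cells: int | None = None  # default 100 * n_guides
    n_passages: int = 4
    reads_per_sample: int | None = None  # default 100 * n_guides
    n_screens: int = 1
    seed: int = 0

    @property
    def n_guides(self) -> int:
        return self.n_genes * self.guides_per_gene + self.n_control_guides

    def resolved_bottleneck(self) -> int:
        return self.bottleneck_cells if self.bottleneck_cells is not None else 100 * self.n_guides

    def resolved_reads(self) -> int:
        return self.reads_per_sample if self.reads_per_sample is not None else 100 * self.n_guides

    def treated_doublings_per_screen(self) -> list[float]:
        td = self.treated_doublings
        if isinstance(td, (int, float)):
            return [float(td)] * self.n_screens
        td = list(td)
        if len(td) != self.n_screens:
            raise ConfigurationError(
                f"treated_doublings has {len(td)} entries for {self.n_screens} screens"
            )
        return [float(x) for x in td]

    def validate(self) -> None:
        if self.n_genes <= 0 or self.guides_per_gene <= 0:
            raise ConfigurationError("n_genes and guides_per_gene must be positive")
        if not 0.0 <= self.frac_essential <= 1.0:
            raise ConfigurationError("frac_essential must lie in [0, 1]")
        n_ess = round(self.frac_essential * self.n_genes)
        if n_ess + self.n_enhancers + self.n_suppressors > self.n_genes:
            raise ConfigurationError(
                "essential + enhancer + suppressor genes exceed n_genes"
            )
        for td in self.treated_doublings_per_screen():
            if td > self.control_doublings:
                raise ConfigurationError(
                    "treated_doublings must not exceed control_doublings"
                )
        if self.resolved_bottleneck() < self.n_guides:
            raise ConfigurationError(
                f"bottleneck of {self.resolved_bottleneck()} cells cannot carry "
                f"{self.n_guides} guides without guaranteed dropout"
            )
        if self.n_passages < 1 or self.n_screens < 1:
            raise ConfigurationError("n_passages and n_screens must be >= 1")


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth: per-gene effects and per-guide efficiencies.

    ``genes`` also carries an ``essentiality_prior`` column emulating a
    published, screen-independent essentiality ranking for the cell line
    (as produced by an earlier genome-wide fitness screen): the gene's
    realized fitness effect plus measurement noise. The scoring pipeline
    uses it the way a real analysis uses a prior essentiality table — to
    build matched nulls without touching the current screen's counts.
    """

    genes: pd.DataFrame  # index gene; essential, fitness, interaction_class,
    #                      interaction_effect, essentiality_prior
    guide_efficiency: pd.Series  # index guide_id

    def genes_in_class(self, interaction_class: str) -> list[str]:
        mask = self.genes["interaction_class"] == interaction_class
        return self.genes.index[mask].tolist()

    @property
    def essentiality_prior(self) -> pd.Series:
        return self.genes["essentiality_prior"]


def _build_library(cfg: SimConfig, rng: np.random.Generator) -> GuideLibrary:
    bases = np.array(list("ACGT"))
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    rows = []
    for g in genes:
        for k in range(cfg.guides_per_gene):
            spacer = "".join(rng.choice(bases, size=20))
            rows.append((f"{g}_sg{k + 1}", spacer, g, False))
    for k in range(cfg.n_control_guides):
        spacer = "".join(rng.choice(bases, size=20))
        rows.append((f"{CONTROL_GENE}_sg{k + 1}", spacer, CONTROL_GENE, True))
    return GuideLibrary(
        pd.DataFrame(rows, columns=["guide_id", "spacer", "gene", "is_control"])
    )


def _plant_truth(cfg: SimConfig, lib: GuideLibrary, rng: np.random.Generator) -> SimTruth:
    genes = [g for g in lib.genes if g != CONTROL_GENE]
    n_ess = round(cfg.frac_essential * cfg.n_genes)
    order = rng.permutation(len(genes))
    essential = [genes[i] for i in order[:n_ess]]
    # interactions are planted on non-essential genes so recovery measures
    # drug-specific effects, not essentiality
    rest = order[n_ess:]
    enhancers = [genes[i] for i in rest[: cfg.n_enhancers]]
    suppressors = [genes[i] for i in rest[cfg.n_enhancers: cfg.n_enhancers + cfg.n_suppressors]]

    gt = pd.DataFrame(
        {
            "essential": False,
            "fitness": 0.0,
            "interaction_class": "none",
            "interaction_effect": 0.0,
        },
        index=pd.Index(genes + [CONTROL_GENE], name="gene"),
    )
    gt.loc[essential, "essential"] = True
    gt.loc[essential, "fitness"] = cfg.essential_fitness
    gt.loc[enhancers, "interaction_class"] = "enhancer"
    gt.loc[enhancers, "interaction_effect"] = -abs(cfg.interaction_effect)
    gt.loc[suppressors, "interaction_class"] = "suppressor"
    gt.loc[suppressors, "interaction_effect"] = abs(cfg.interaction_effect)

    if cfg.guide_efficiency_beta == 0:
        eff = np.ones(lib.n_guides)
    else:
        eff = rng.beta(cfg.guide_efficiency_alpha, cfg.guide_efficiency_beta,
                       size=lib.n_guides)
    efficiency = pd.Series(eff, index=lib.guide_ids, name="efficiency")

    # prior-screen essentiality: the fitness effect a previous independent
    # screen would have measured (fitness scaled by the gene's realized mean
    # guide efficiency), plus measurement noise — independent of this
    # screen's count noise
    mean_eff = efficiency.groupby(lib.gene_of.reindex(efficiency.index)).mean()
    gt["essentiality_prior"] = (
        gt["fitness"] * mean_eff.reindex(gt.index)
        + rng.normal(0.0, cfg.essentiality_prior_sd, size=len(gt))
    )
    return SimTruth(gt, efficiency)


def _grow_and_sample(
    phi: np.ndarray,
    doublings: float,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One arm's trajectory: exponential growth, passage bottlenecks, reads."""
    bottleneck = cfg.resolved_bottleneck()
    n = phi.size
    x = np.full(n, bottleneck / n)
    d = doublings / cfg.n_passages
    growth = np.power(2.0, (1.0 + phi) * d)
    for i in range(cfg.n_passages):
        x = x * growth
        if i < cfg.n_passages - 1:
            x = rng.multinomial(bottleneck, x / x.sum()).astype(float)
    return rng.multinomial(cfg.resolved_reads(), x / x.sum())


def simulate_screen(cfg: SimConfig) -> tuple[CountMatrix, GuideLibrary, SimTruth]:
    """Simulate count data for ``cfg.n_screens`` screens sharing one truth.

    Each screen contributes one pooled control and one treated sample.
    Identical configs (including seed) produce bit-identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lib = _build_library(cfg, rng)
    truth = _plant_truth(cfg, lib, rng)

    fitness = truth.genes["fitness"].loc[lib.gene_of.to_numpy()].to_numpy()
    interaction = truth.genes["interaction_effect"].loc[lib.gene_of.to_numpy()].to_numpy()
    eff = truth.guide_efficiency.to_numpy()

    phi_control = eff * fitness
    phi_treated = eff * (fitness + interaction)

    samples: list[SampleMeta] = []
    cols: list[np.ndarray] = []
    for s, td in enumerate(cfg.treated_doublings_per_screen(), start=1):
        sid = f"S{s}"
        cols.append(_grow_and_sample(phi_control, cfg.control_doublings, cfg, rng))
        samples.append(SampleMeta(f"{sid}_control", sid, "control",
                                  lane="pooled", timepoint="d8"))
        cols.append(_grow_and_sample(phi_treated, td, cfg, rng))
        samples.append(SampleMeta(f"{sid}_treated", sid, "treated",
                                  compound=f"cpd{s}", lane="pooled", timepoint="d8"))
    cm = CountMatrix(lib.guide_ids.copy(), samples, np.column_stack(cols))
    return cm, lib, truth


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

_FIXTURE_FILES = ("library.tsv", "counts.tsv", "samples.tsv",
                  "truth_genes.tsv", "guide_efficiency.tsv")


def write_fixture(
    cm: CountMatrix, lib: GuideLibrary, truth: SimTruth, outdir: str | Path
) -> list[Path]:
    """Write a simulated screen as TSVs readable by :mod:`chemoscreen.io`."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_library(lib, out / "library.tsv")
    write_counts(cm, out / "counts.tsv")
    write_sample_meta(cm.samples, out / "samples.tsv")
    truth.genes.reset_index().to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    truth.guide_efficiency.reset_index().rename(
        columns={"index": "guide_id"}
    ).to_csv(out / "guide_efficiency.tsv", sep="\t", index=False)
    return [out / f for f in _FIXTURE_FILES]


def read_fixture(fixdir: str | Path) -> tuple[CountMatrix, GuideLibrary, SimTruth]:
    fix = Path(fixdir)
    lib = read_library(fix / "library.tsv")
    meta = read_sample_meta(fix / "samples.tsv")
    cm = read_counts(fix / "counts.tsv", lib, meta)
    genes = pd.read_csv(fix / "truth_genes.tsv", sep="\t", index_col="gene")
    eff = pd.read_csv(fix / "guide_efficiency.tsv", sep="\t", index_col="guide_id")
    truth = SimTruth(genes, eff["efficiency"])
    return cm, lib, truth
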