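"""Seeded synthetic PhIP-seq datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without the deposited cohort data:

* a highly skewed phage-library background — per-gene bead-binding
  propensities are log-normal, split equally across each gene's peptides;
* mock-IP (bead-only) replicates that sample the background alone;
* per-serum **private** autoreactivities: every serum, case or control,
  enriches a few idiosyncratic genes at large multiplicative effects;
* **common** (public) autoreactivities: a small set of genes targeted by a
  moderate fraction of all sera regardless of disease status — these are
  what small control cohorts fail to filter;
* **disease** antigens: genes enriched only in cases, each carried with a
  configurable penetrance at a fixed multiplicative effect.

Counts are drawn Dirichlet-multinomial so per-sample totals are exact and
compositional competition (one strongly enriched clone suppresses the read
share of everything else) is represented.  The ``overdispersion`` field is
the Dirichlet concentration scale: larger values approach pure multinomial
sampling.

All randomness flows through one ``numpy`` Generator seeded from
``SimConfig.seed``; draws are consumed in a fixed, documented order
(background → common-gene choice → depths → per-sample effects → counts),
so identical configs give bit-identical datasets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .counts_io import CountMatrix, PeptideGeneMap, SampleSheet

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Generative-model parameters; defaults mirror a scaled human-peptidome
    screen (≈20k genes, cohort of 128 cases / 186 controls / 8 mock-IP,
    ~1M reads per sample)."""

    n_genes: int = 20_000
    peptides_per_gene: int = 2
    n_cases: int = 128
    n_controls: int = 186
    n_mock: int = 8
    depth_log_mean: float = math.log(1_000_000)
    depth_log_sd: float = 0.3
    background_log_sd: float = 2.0
    n_private: int = 5
    private_effect_range: tuple[float, float] = (10.0, 1000.0)
    n_common: int = 40
    common_reactivity: float = 0.10
    common_effect_range: tuple[float, float] | None = None  # defaults to private range
    disease_genes: tuple[str, ...] = ()
    penetrance: float = 0.0
    disease_effect: float = 100.0
    overdispersion: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.penetrance <= 1.0):
            raise ValueError("penetrance must lie in [0, 1]")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be > 0")
        if self.private_effect_range[0] < 1 or self.disease_effect < 1:
            raise ValueError("enrichment effects must be ≥ 1")
        if self.n_private > self.n_genes:
            raise ValueError("n_private cannot exceed n_genes")
        bad = set(self.disease_genes) - set(self.gene_ids())
        if bad:
            raise ValueError(f"disease_genes not in simulated gene set: {sorted(bad)}")
        if self.penetrance > 0 and not self.disease_genes:
            logger.warning("penetrance > 0 but no disease genes configured")

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]


@dataclass
class SimTruth:
    """Ground truth: per-sample spiked (gene, effect, origin) records."""

    table: pd.DataFrame  # columns: sample_id, gene_id, effect, origin
    config: SimConfig
    seed: int

    def spiked_disease_genes(self) -> list[str]:
        """Disease genes actually carried by at least one case."""
        t = self.table
        return sorted(t.loc[t["origin"] == "disease", "gene_id"].unique())

    def carriers(self, gene_id: str) -> list[str]:
        t = self.table
        m = (t["gene_id"] == gene_id) & (t["origin"] == "disease")
        return sorted(t.loc[m, "sample_id"].unique())


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    if lo == hi:
        return np.full(size, float(lo))
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size))


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[CountMatrix, PeptideGeneMap, SampleSheet, SimTruth]:
    """Draw one synthetic dataset (peptide counts, map, sample sheet, truth)."""
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids()
    k = cfg.peptides_per_gene
    peptides = [f"{g}_p{j}" for g in genes for j in range(1, k + 1)]
    pmap = PeptideGeneMap({p: p.rsplit("_p", 1)[0] for p in peptides})

    # 1) skewed background propensities, equal split across a gene's peptides.
    # Disease antigens are censored below at the library median propensity: a
    # spiked antigen must be adequately displayed to be a measurable spike
    # (otherwise its fold change is pseudocount-limited, not effect-limited).
    lam_gene = rng.lognormal(mean=0.0, sigma=cfg.background_log_sd, size=cfg.n_genes)
    if cfg.disease_genes:
        di = [i for i, g in enumerate(genes) if g in set(cfg.disease_genes)]
        lam_gene[di] = np.maximum(lam_gene[di], 1.0)
    lam_pep = np.repeat(lam_gene / k, k)

    # 2) commonly targeted (public) autoreactive genes, outside the disease set
    eligible = np.array([i for i, g in enumerate(genes) if g not in set(cfg.disease_genes)])
    n_common = min(cfg.n_common, len(eligible))
    common_idx = rng.choice(eligible, size=n_common, replace=False) if n_common else np.array([], dtype=int)

    sample_ids = (
        [f"case{i + 1:03d}" for i in range(cfg.n_cases)]
        + [f"ctrl{i + 1:03d}" for i in range(cfg.n_controls)]
        + [f"mock{i + 1:02d}" for i in range(cfg.n_mock)]
    )
    roles = (["case"] * cfg.n_cases + ["control"] * cfg.n_controls
             + ["mock_ip"] * cfg.n_mock)
    sheet = SampleSheet.from_roles(dict(zip(sample_ids, roles)), cohort="sim")

    # 3) per-sample sequencing depths
    depths = np.maximum(
        1, np.round(rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd, len(sample_ids)))
    ).astype(np.int64)

    common_range = cfg.common_effect_range or cfg.private_effect_range
    disease_idx = {g: genes.index(g) for g in cfg.disease_genes}

    counts = np.empty((len(peptides), len(sample_ids)), dtype=np.int64)
    truth_rows: list[tuple[str, str, float, str]] = []
    gene_effect = np.empty(cfg.n_genes)

    for s_i, (sid, role) in enumerate(zip(sample_ids, roles)):
        gene_effect.fill(1.0)
        if role != "mock_ip":
            priv_idx = rng.choice(cfg.n_genes, size=cfg.n_private, replace=False)
            priv_eff = _log_uniform(rng, *cfg.private_effect_range, cfg.n_private)
            for gi, eff in zip(priv_idx, priv_eff):
                gene_effect[gi] *= eff
                truth_rows.append((sid, genes[gi], float(eff), "private"))
            if n_common:
                hit = rng.random(n_common) < cfg.common_reactivity
                comm_eff = _log_uniform(rng, *common_range, int(hit.sum()))
                for gi, eff in zip(common_idx[hit], comm_eff):
                    gene_effect[gi] *= eff
                    truth_rows.append((sid, genes[gi], float(eff), "common"))
            if role == "case" and cfg.disease_genes:
                carried = rng.random(len(cfg.disease_genes)) < cfg.penetrance
                for g, c in zip(cfg.disease_genes, carried):
                    if c:
                        gene_effect[disease_idx[g]] *= cfg.disease_effect
                        truth_rows.append((sid, g, float(cfg.disease_effect), "disease"))
        prop = lam_pep * np.repeat(gene_effect, k)
        p = prop / prop.sum()
        w = rng.dirichlet(cfg.overdispersion * p)
        counts[:, s_i] = rng.multinomial(depths[s_i], w)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(peptides, name="peptide"),
                            columns=sample_ids),
        level="peptide",
    )
    truth = SimTruth(
        table=pd.DataFrame(truth_rows, columns=["sample_id", "gene_id", "effect", "origin"]),
        config=cfg,
        seed=cfg.seed,
    )
    return cm, pmap, sheet, truth


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("tiny", "aps1_like", "null")

_APS1_DISEASE_GENES = tuple(f"G{i:05d}" for i in range(10, 20))


def fixture_config(name: str, seed: int | None = None) -> SimConfig:
    """Configuration behind each named fixture (see :func:`make_fixture`)."""
    if name == "tiny":
        cfg = SimConfig(
            n_genes=8, peptides_per_gene=2, n_cases=1, n_controls=3, n_mock=2,
            depth_log_mean=math.log(2000), depth_log_sd=0.2, background_log_sd=1.0,
            n_private=1, private_effect_range=(10.0, 100.0), n_common=0,
            disease_genes=("G00000",), penetrance=1.0, disease_effect=50.0,
            overdispersion=1e4, seed=42,
        )
    elif name == "aps1_like":
        cfg = SimConfig(disease_genes=_APS1_DISEASE_GENES, penetrance=0.35,
                        disease_effect=100.0, seed=0)
    elif name == "null":
        cfg = SimConfig(disease_genes=(), penetrance=0.0, seed=1)
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg


def make_fixture(
    name: str, seed: int | None = None
) -> tuple[CountMatrix, PeptideGeneMap, SampleSheet, SimTruth]:
    """Named, seeded dataset presets.

    ``tiny`` is hand-checkable (8 genes, 6 samples); ``aps1_like`` mirrors a
    large monogenic-autoimmunity screen (128 cases / 186 controls / 8 mock-IP,
    10 disease antigens at 35% penetrance, 100× enrichment); ``null`` is the
    same cohort with no disease antigens.
    """
    return simulate_dataset(fixture_config(name, seed))


def config_echo(cfg: SimConfig) -> dict:
    """JSON-serializable echo of a simulation config."""
    d = asdict(cfg)
    d["disease_genes"] = list(cfg.disease_genes)
    return d
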